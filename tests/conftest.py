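import numpy as np
import pytest

from fci.phantom import (
    PhantomSpec,
    TissueDispersionTruth,
    TissueLabel,
    breast_phantom_labels,
    default_tissue_truths,
    simulate_acquisition,
)
from fci.protocol import AcquisitionProtocol, default_protocol


def make_protocol(fields_times, matrix_shape=(16, 16), **kwargs):
    """Small custom protocol from {field: times} for targeted tests."""
    return AcquisitionProtocol(
        polarisation_field_mT=kwargs.pop("polarisation_field_mT", 200.0),
        polarisation_duration_ms=300.0,
        evolution_fields_mT=tuple(fields_times),
        evolution_times_ms={f: tuple(t) for f, t in fields_times.items()},
        detection_field_mT=193.0,
        matrix_shape=matrix_shape,
        **kwargs,
    )


@pytest.fixture(scope="session")
def truths():
    return default_tissue_truths()


@pytest.fixture(scope="session")
def small_labels():
    return breast_phantom_labels((24, 48))


@pytest.fixture(scope="session")
def noiseless_images(truths, small_labels):
    spec = PhantomSpec(
        label_map=small_labels, tissue_truths=truths, noise_sigma=0.0, rng_seed=0
    )
    return simulate_acquisition(spec)


@pytest.fixture(scope="session")
def noisy_images(truths, small_labels):
    spec = PhantomSpec(label_map=small_labels, tissue_truths=truths, rng_seed=7)
    return simulate_acquisition(spec)
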