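"""Digital breast phantom and field-cycling acquisition forward model.

Tissue classes carry a generative R1 dispersion (power law plus an optional
quadrupolar enhancement centred at 65.8 mT).  The simulator evaluates the
field-cycling signal equation on a label map and adds complex Gaussian noise
before taking magnitudes, so tissue voxels are Rician and background voxels
Rayleigh distributed.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from fci.protocol import AcquisitionProtocol, default_protocol

__all__ = [
    "TissueLabel",
    "TissueDispersionTruth",
    "PhantomSpec",
    "FciImageSet",
    "truth_r1",
    "forward_signal",
    "polarised_magnetisation",
    "simulate_acquisition",
    "make_cohort",
    "default_tissue_truths",
    "breast_phantom_labels",
    "QP_CENTER_MT",
    "DEFAULT_NOISE_SIGMA",
]

#: Field at which the quadrupolar (14N-1H cross-relaxation) peak sits, mT.
QP_CENTER_MT = 65.8

#: Default complex-channel noise level (arbitrary units).  Chosen so the
#: default phantom's per-field SNR falls inside the clinically observed
#: ranges (highest at 200 mT, lowest at 2.3 mT).
DEFAULT_NOISE_SIGMA = 1.05

# Class-median R1 levels (s^-1) at 2.3 / 22 / 200 mT used to tune the
# default generative truths, and median QP amplitudes (s^-1).
_MEDIAN_R1 = {
    "glandular": {2.3: 10.3, 22.0: 8.1, 200.0: 5.7},
    "adipose": {2.3: 10.6, 22.0: 9.1, 200.0: 7.3},
    "tumour": {2.3: 8.3, 22.0: 6.8, 200.0: 4.8},
}
_MEDIAN_QP = {"glandular": 0.76, "adipose": 0.0, "tumour": 0.83}
# Median dispersion exponents of invasive / non-invasive tumours and their
# median QP amplitudes.
_BETA_INVASIVE = 0.05
_BETA_NONINVASIVE = 0.19
_QP_INVASIVE = 0.5
_QP_NONINVASIVE = 0.9


class TissueLabel(enum.IntEnum):
    """Integer labels used in phantom label maps."""

    background = 0
    adipose = 1
    glandular = 2
    tumour_noninvasive = 3
    tumour_invasive = 4


@dataclass(frozen=True)
class TissueDispersionTruth:
    """Ground-truth generative dispersion for one tissue class.

    R1(B) = alpha * B^(-beta) + qp_amplitude * L(B) where L is a unit-peak
    Lorentzian centred at ``qp_center_mT`` with half-width ``qp_width_mT``.
    ``alpha`` is the R1 level at 1 mT (s^-1); ``beta`` the dimensionless
    dispersion exponent; ``proton_density_scale`` enters the signal amplitude.
    """

    tissue_label: TissueLabel
    alpha: float
    beta: float
    qp_amplitude: float = 0.0
    qp_center_mT: float = QP_CENTER_MT
    qp_width_mT: float = 10.0
    proton_density_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.qp_amplitude < 0:
            raise ValueError("qp_amplitude must be non-negative")
        if self.tissue_label == TissueLabel.adipose and self.qp_amplitude != 0:
            raise ValueError("adipose tissue carries no quadrupolar peak")
        if self.qp_width_mT <= 0:
            raise ValueError("qp_width_mT must be positive")
        if self.proton_density_scale < 0:
            raise ValueError("proton_density_scale must be non-negative")


def truth_r1(truth: TissueDispersionTruth, field_mT: float) -> float:
    """Ground-truth R1 (s^-1) of a tissue class at an evolution field (mT).

    Power law ``alpha * field^(-beta)`` plus a unit-peak Lorentzian
    quadrupolar term scaled by ``qp_amplitude`` (exactly ``qp_amplitude`` at
    the peak centre).
    """
    field_mT = float(field_mT)
    if field_mT <= 0:
        raise ValueError("field must be positive")
    w = truth.qp_width_mT
    lorentz = w * w / ((field_mT - truth.qp_center_mT) ** 2 + w * w)
    return truth.alpha * field_mT ** (-truth.beta) + truth.qp_amplitude * lorentz


def polarised_magnetisation(truth: TissueDispersionTruth, protocol: AcquisitionProtocol) -> float:
    """Magnetisation at the end of the polarisation interval (field units).

    Finite build-up M0_P = B0_P * (1 - exp(-t_pol / T1(B0_P))): a 300 ms
    polarisation at 0.2 T is partial for breast-tissue T1 of 140-220 ms.
    This is what leaves the evolution-field decay identifiable even when
    the evolution field equals the polarisation field.
    """
    t1_pol = 1000.0 / truth_r1(truth, protocol.polarisation_field_mT)
    frac = 1.0 - np.exp(-protocol.polarisation_duration_ms / t1_pol)
    return protocol.polarisation_field_mT * float(frac)


def forward_signal(
    truth: TissueDispersionTruth,
    protocol: AcquisitionProtocol,
    field_mT: float,
    t_evo_ms: float,
) -> float:
    """Noiseless field-cycling signal for one tissue at one grid point.

    S = A * [(M0_P - M0_E) * exp(-t_E / T1(B_E)) + M0_E] with M0_P the
    (partially) polarised magnetisation and M0_E proportional to the
    evolution field (Curie-law scaling).  The scale A absorbs proton density
    and readout efficiency; spin-echo T2 weighting is folded into A and not
    modelled.  At evolution fields near the polarisation field M0_E exceeds
    M0_P and the signal recovers upward instead of decaying.
    """
    if field_mT not in protocol.evolution_times_ms:
        raise ValueError(f"field {field_mT} mT not in protocol")
    if t_evo_ms not in protocol.evolution_times_ms[field_mT]:
        raise ValueError(f"evolution time {t_evo_ms} ms not in protocol grid at {field_mT} mT")
    t1_ms = 1000.0 / truth_r1(truth, field_mT)
    m0_p = polarised_magnetisation(truth, protocol)
    m0_e = field_mT
    a = truth.proton_density_scale
    return a * ((m0_p - m0_e) * np.exp(-t_evo_ms / t1_ms) + m0_e)


@dataclass(frozen=True)
class PhantomSpec:
    """A single-subject phantom: label map, tissue truths, noise, seed."""

    label_map: np.ndarray
    tissue_truths: Mapping[TissueLabel, TissueDispersionTruth]
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    rng_seed: int = 0
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        lm = np.asarray(self.label_map)
        if lm.ndim != 2:
            raise ValueError("label_map must be 2-D")
        object.__setattr__(self, "label_map", lm.astype(np.int32))
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        n_bg = int(np.sum(lm == TissueLabel.background))
        if n_bg < 100:
            raise ValueError("label_map needs a background region of >= 100 voxels")
        present = set(np.unique(lm)) - {int(TissueLabel.background)}
        missing = [int(p) for p in present if TissueLabel(p) not in self.tissue_truths]
        if missing:
            raise ValueError(f"missing tissue truth for labels {missing}")

    @property
    def tumour_label(self) -> TissueLabel | None:
        for lab in (TissueLabel.tumour_invasive, TissueLabel.tumour_noninvasive):
            if np.any(self.label_map == lab):
                return lab
        return None


@dataclass
class FciImageSet:
    """Magnitude images indexed by (evolution_field_mT, evolution_time_ms)."""

    volumes: dict[tuple[float, float], np.ndarray]
    protocol: AcquisitionProtocol
    label_map: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        grid = set(self.protocol.grid())
        if set(self.volumes) != grid:
            raise ValueError("volume index set does not match the protocol grid")
        for key, vol in self.volumes.items():
            vol = np.asarray(vol, dtype=float)
            if np.any(vol < 0):
                raise ValueError(f"negative magnitudes in volume {key}")
            self.volumes[key] = vol

    def volume(self, field_mT: float, t_evo_ms: float) -> np.ndarray:
        return self.volumes[(field_mT, t_evo_ms)]


def _power_law_fit(fields: Sequence[float], r1: Sequence[float]) -> tuple[float, float]:
    """Log-log least-squares (alpha, beta) through (field, R1) points."""
    x = np.log(np.asarray(fields, dtype=float))
    y = np.log(np.asarray(r1, dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    return float(np.exp(intercept)), float(-slope)


def default_tissue_truths() -> dict[TissueLabel, TissueDispersionTruth]:
    """Default truths tuned to the clinical class medians.

    Glandular and adipose take their dispersion exponent from a log-log fit
    through the class-median R1 at 2.3/22/200 mT; tumour classes take the
    median invasive (0.05) / non-invasive (0.19) exponents.  Every class is
    anchored so that R1(22 mT) equals its median exactly, and quadrupolar
    amplitudes equal the class medians (zero for adipose).
    """

    def anchored(beta: float, r1_at_22: float) -> float:
        return r1_at_22 * 22.0**beta

    truths = {}
    for name, label in (("glandular", TissueLabel.glandular), ("adipose", TissueLabel.adipose)):
        med = _MEDIAN_R1[name]
        fields = sorted(med)
        _, beta = _power_law_fit(fields, [med[f] for f in fields])
        truths[label] = TissueDispersionTruth(
            tissue_label=label,
            alpha=anchored(beta, med[22.0]),
            beta=beta,
            qp_amplitude=_MEDIAN_QP[name],
        )
    r1_22 = _MEDIAN_R1["tumour"][22.0]
    truths[TissueLabel.tumour_invasive] = TissueDispersionTruth(
        tissue_label=TissueLabel.tumour_invasive,
        alpha=anchored(_BETA_INVASIVE, r1_22),
        beta=_BETA_INVASIVE,
        qp_amplitude=_QP_INVASIVE,
    )
    truths[TissueLabel.tumour_noninvasive] = TissueDispersionTruth(
        tissue_label=TissueLabel.tumour_noninvasive,
        alpha=anchored(_BETA_NONINVASIVE, r1_22),
        beta=_BETA_NONINVASIVE,
        qp_amplitude=_QP_NONINVASIVE,
    )
    return truths


def breast_phantom_labels(
    shape: tuple[int, int] = (64, 128),
    tumour_label: TissueLabel = TissueLabel.tumour_noninvasive,
    tumour_radius_frac: float = 0.14,
) -> np.ndarray:
    """Deterministic breast label map.

    An elliptical breast of adipose tissue with an inner glandular core; a
    circular tumour straddles the glandular/adipose boundary so that the
    surrounding ring is a glandular/adipose mix.  Everything outside the
    breast is background.
    """
    ny, nx = int(shape[0]), int(shape[1])
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ay, ax = 0.42 * ny, 0.42 * nx
    breast = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    gy, gx = 0.55 * ay, 0.55 * ax
    gland = ((yy - cy) / gy) ** 2 + ((xx - cx) / gx) ** 2 <= 1.0
    labels = np.zeros(shape, dtype=np.int32)
    labels[breast] = TissueLabel.adipose
    labels[gland & breast] = TissueLabel.glandular
    # tumour centred on the glandular boundary, towards +x
    tr = max(2.0, tumour_radius_frac * min(ny, nx))
    ty, tx = cy, cx + gx
    tumour = (yy - ty) ** 2 + (xx - tx) ** 2 <= tr**2
    labels[tumour & breast] = tumour_label
    return labels


def simulate_acquisition(
    spec: PhantomSpec, protocol: AcquisitionProtocol | None = None
) -> FciImageSet:
    """Simulate the full field-cycling acquisition for one phantom.

    Each voxel's magnitude is |forward_signal + complex Gaussian noise|:
    Rician in tissue, Rayleigh in the (zero-signal) background.  Fully
    deterministic given ``spec.rng_seed``.
    """
    if protocol is None:
        protocol = default_protocol(spec.tissue_truths, matrix_shape=spec.label_map.shape)
    if tuple(protocol.matrix_shape) != spec.label_map.shape:
        raise ValueError("protocol matrix_shape does not match the label map")
    rng = np.random.default_rng(spec.rng_seed)
    labels_present = [int(v) for v in np.unique(spec.label_map)]
    volumes: dict[tuple[float, float], np.ndarray] = {}
    for f, t in protocol.grid():
        signal = np.zeros(spec.label_map.shape, dtype=float)
        for lab in labels_present:
            if lab == TissueLabel.background:
                continue
            s = forward_signal(spec.tissue_truths[TissueLabel(lab)], protocol, f, t)
            signal[spec.label_map == lab] = s
        if spec.noise_sigma > 0:
            re = signal + rng.normal(0.0, spec.noise_sigma, signal.shape)
            im = rng.normal(0.0, spec.noise_sigma, signal.shape)
            mag = np.hypot(re, im)
        else:
            mag = signal
        volumes[(f, t)] = mag
    return FciImageSet(
        volumes=volumes,
        protocol=protocol,
        label_map=spec.label_map.copy(),
        provenance=f"simulated subject={spec.subject_id} seed={spec.rng_seed}",
    )


def make_cohort(
    n_invasive: int,
    n_noninvasive: int,
    variability: float = 0.15,
    rng_seed: int = 0,
    shape: tuple[int, int] = (64, 128),
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
) -> list[PhantomSpec]:
    """Draw a cohort of per-subject phantoms around the class-mean truths.

    ``variability`` is the relative (log-normal) spread applied to alpha,
    beta and the QP amplitude of every tissue; 0 makes all subjects of a
    class identical.  Reproducible by seed.
    """
    if n_invasive < 0 or n_noninvasive < 0:
        raise ValueError("cohort counts must be non-negative")
    if variability < 0:
        raise ValueError("variability must be non-negative")
    rng = np.random.default_rng(rng_seed)
    base = default_tissue_truths()
    cohort: list[PhantomSpec] = []

    def jitter(value: float) -> float:
        if variability == 0 or value == 0:
            return value
        return float(value * np.exp(variability * rng.standard_normal()))

    groups = [(TissueLabel.tumour_invasive, "inv", n_invasive), (
        TissueLabel.tumour_noninvasive, "noninv", n_noninvasive)]
    idx = 0
    for tumour_label, tag, count in groups:
        for _ in range(count):
            idx += 1
            truths = {}
            for lab in (TissueLabel.adipose, TissueLabel.glandular, tumour_label):
                t = base[lab]
                truths[lab] = replace(
                    t,
                    alpha=jitter(t.alpha),
                    beta=jitter(t.beta),
                    qp_amplitude=jitter(t.qp_amplitude),
                )
            cohort.append(
                PhantomSpec(
                    label_map=breast_phantom_labels(shape, tumour_label),
                    tissue_truths=truths,
                    noise_sigma=noise_sigma,
                    rng_seed=int(rng.integers(0, 2**31 - 1)),
                    subject_id=f"S{idx:02d}_{tag}",
                )
            )
    return cohort
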