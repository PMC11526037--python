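import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fci.phantom import (
    DEFAULT_NOISE_SIGMA,
    PhantomSpec,
    TissueDispersionTruth,
    TissueLabel,
    breast_phantom_labels,
    default_tissue_truths,
    forward_signal,
    make_cohort,
    simulate_acquisition,
    truth_r1,
)
from fci.protocol import default_protocol

from conftest import make_protocol


def flat_truth(**kw):
    defaults = dict(tissue_label=TissueLabel.glandular, alpha=10.0, beta=0.0, qp_amplitude=0.0)
    defaults.update(kw)
    return TissueDispersionTruth(**defaults)


class TestTruthR1:
    def test_flat_profile(self):
        t = flat_truth()
        for f in (1.0, 22.0, 500.0):
            assert truth_r1(t, f) == pytest.approx(10.0)

    def test_alpha_is_1mT_intercept(self):
        t = flat_truth(beta=0.1)
        assert truth_r1(t, 1.0) == pytest.approx(10.0)

    def test_qp_peak_centre_adds_amplitude(self):
        t = flat_truth(qp_amplitude=0.8)
        assert truth_r1(t, 65.8) == pytest.approx(10.8)

    def test_nonpositive_field_rejected(self):
        with pytest.raises(ValueError):
            truth_r1(flat_truth(), 0.0)
        with pytest.raises(ValueError):
            truth_r1(flat_truth(), -3.0)

    @given(
        alpha=st.floats(0.5, 50),
        beta=st.floats(0, 1),
        f1=st.floats(1, 300),
        f2=st.floats(1, 300),
    )
    @settings(max_examples=100, deadline=None)
    def test_loglog_slope_is_minus_beta(self, alpha, beta, f1, f2):
        # without a QP term, ln R1 vs ln B is a line of slope exactly -beta
        if abs(np.log(f2) - np.log(f1)) < 1e-3:
            return
        t = flat_truth(alpha=alpha, beta=beta)
        slope = (np.log(truth_r1(t, f2)) - np.log(truth_r1(t, f1))) / (np.log(f2) - np.log(f1))
        assert slope == pytest.approx(-beta, abs=1e-9)


class TestForwardSignal:
    def setup_method(self):
        self.protocol = make_protocol({22.0: (1e-9, 50.0, 150.0, 1e9)})
        self.truth = flat_truth()

    def test_short_time_limit_is_polarised_magnetisation(self):
        from fci.phantom import polarised_magnetisation

        s = forward_signal(self.truth, self.protocol, 22.0, 1e-9)
        m0_p = polarised_magnetisation(self.truth, self.protocol)
        assert s == pytest.approx(m0_p, rel=1e-6)
        # 300 ms at B0_P is a partial polarisation: below full equilibrium
        assert 0 < m0_p < self.protocol.polarisation_field_mT

    def test_long_time_limit_is_evolution_equilibrium(self):
        s = forward_signal(self.truth, self.protocol, 22.0, 1e9)
        assert s == pytest.approx(22.0, rel=1e-6)

    def test_field_at_polarisation_recovers_upward(self):
        # partial polarisation leaves M0_E > M0_P at B0_E = B0_P, so the
        # signal rises toward equilibrium instead of being flat
        protocol = make_protocol({200.0: (10.0, 100.0, 500.0, 1e9)})
        vals = [forward_signal(self.truth, protocol, 200.0, t) for t in (10.0, 100.0, 500.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert forward_signal(self.truth, protocol, 200.0, 1e9) == pytest.approx(200.0, rel=1e-6)

    def test_monotone_decreasing_in_time(self):
        protocol = make_protocol({22.0: tuple(np.linspace(5, 600, 12))})
        vals = [forward_signal(self.truth, protocol, 22.0, t) for t in protocol.evolution_times_ms[22.0]]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_off_grid_point_rejected(self):
        with pytest.raises(ValueError):
            forward_signal(self.truth, self.protocol, 99.0, 50.0)
        with pytest.raises(ValueError):
            forward_signal(self.truth, self.protocol, 22.0, 42.0)


class TestSimulateAcquisition:
    def test_noiseless_equals_forward_signal(self, truths, small_labels, noiseless_images):
        protocol = noiseless_images.protocol
        for (f, t), vol in noiseless_images.volumes.items():
            for lab in (TissueLabel.adipose, TissueLabel.glandular):
                expected = forward_signal(truths[lab], protocol, f, t)
                assert np.allclose(vol[small_labels == lab], expected)
            assert np.all(vol[small_labels == 0] == 0.0)

    def test_determinism_under_seed(self, truths, small_labels):
        spec = PhantomSpec(label_map=small_labels, tissue_truths=truths, rng_seed=11)
        a = simulate_acquisition(spec)
        b = simulate_acquisition(spec)
        for key in a.volumes:
            assert np.array_equal(a.volumes[key], b.volumes[key])

    def test_magnitudes_nonnegative(self, noisy_images):
        for vol in noisy_images.volumes.values():
            assert np.all(vol >= 0)

    def test_missing_truth_is_configuration_error(self, truths):
        labels = breast_phantom_labels((24, 48))
        incomplete = {k: v for k, v in truths.items() if k != TissueLabel.glandular}
        with pytest.raises(ValueError, match="missing tissue truth"):
            PhantomSpec(label_map=labels, tissue_truths=incomplete)

    def test_background_rayleigh_mean(self, truths):
        # background magnitude mean -> sigma * sqrt(pi/2) for >= 1e4 voxels
        labels = np.zeros((128, 128), dtype=np.int32)
        labels[60:68, 60:68] = TissueLabel.adipose
        sigma = 2.0
        spec = PhantomSpec(
            label_map=labels, tissue_truths=truths, noise_sigma=sigma, rng_seed=5
        )
        protocol = make_protocol({22.0: (50.0, 150.0, 400.0)}, matrix_shape=(128, 128))
        images = simulate_acquisition(spec, protocol)
        bg = images.volumes[(22.0, 50.0)][labels == 0]
        assert bg.size >= 10_000
        assert bg.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)


class TestMakeCohort:
    def test_zero_variability_gives_identical_subjects(self):
        cohort = make_cohort(0, 3, variability=0.0, rng_seed=1, shape=(24, 48))
        t0 = cohort[0].tissue_truths[TissueLabel.tumour_noninvasive]
        for spec in cohort[1:]:
            t = spec.tissue_truths[TissueLabel.tumour_noninvasive]
            assert (t.alpha, t.beta, t.qp_amplitude) == (t0.alpha, t0.beta, t0.qp_amplitude)

    def test_empty_cohort(self):
        assert make_cohort(0, 0, rng_seed=0) == []

    def test_negative_variability_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(1, 1, variability=-0.1)

    def test_reproducible_by_seed(self):
        a = make_cohort(2, 2, variability=0.2, rng_seed=42, shape=(24, 48))
        b = make_cohort(2, 2, variability=0.2, rng_seed=42, shape=(24, 48))
        for sa, sb in zip(a, b):
            assert sa.rng_seed == sb.rng_seed
            for lab in sa.tissue_truths:
                assert sa.tissue_truths[lab].beta == sb.tissue_truths[lab].beta

    def test_group_sizes_and_labels(self):
        cohort = make_cohort(2, 3, rng_seed=0, shape=(24, 48))
        labels = [spec.tumour_label for spec in cohort]
        assert labels.count(TissueLabel.tumour_invasive) == 2
        assert labels.count(TissueLabel.tumour_noninvasive) == 3


class TestInvariants:
    def test_adipose_must_have_zero_qp(self):
        with pytest.raises(ValueError, match="adipose"):
            TissueDispersionTruth(
                tissue_label=TissueLabel.adipose, alpha=10.0, beta=0.1, qp_amplitude=0.5
            )

    def test_background_minimum_size_enforced(self, truths):
        labels = np.full((10, 10), int(TissueLabel.adipose), dtype=np.int32)
        labels[0, 0] = 0
        with pytest.raises(ValueError, match="background"):
            PhantomSpec(label_map=labels, tissue_truths=truths)

    def test_default_truths_anchored_at_class_medians(self, truths):
        # the power-law component at 22 mT equals the class-median R1 level
        t = truths[TissueLabel.tumour_noninvasive]
        assert t.alpha * 22.0 ** (-t.beta) == pytest.approx(6.8, rel=1e-12)
        g = truths[TissueLabel.glandular]
        assert g.alpha * 22.0 ** (-g.beta) == pytest.approx(8.1, rel=1e-12)

    def test_default_protocol_grid(self):
        p = default_protocol()
        assert set(p.evolution_fields_mT) == {2.3, 22.0, 65.8, 200.0}
        assert all(len(p.evolution_times_ms[f]) == 5 for f in p.evolution_fields_mT)
        assert p.echo_time_ms == 16.0 and p.repetition_time_ms == 2000.0
        assert p.polarisation_field_mT == 200.0 and p.polarisation_duration_ms == 300.0
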