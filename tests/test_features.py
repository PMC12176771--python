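"""The 48 glottal parameters: fixed points, hand oracles, recovery, and
invariance properties."""

import numpy as np
import pytest

import gawlab
from gawlab.extraction import CycleSegmentation, GAWRecord, detect_cycles
from gawlab.features import (
    FEATURE_NAMES,
    FeatureConfig,
    FeatureExtractionError,
    GlottalFeatureVector,
    compute_dynamics,
    compute_f0_stats,
    compute_mechanical,
    compute_noise,
    compute_nyquist,
    compute_perturbation,
    compute_symmetry,
    extract_all,
)
from gawlab.synth import GAWSynthesisParams, generate_gaw

from conftest import sinusoid_cycles, sinusoid_gaw

CONFIG = FeatureConfig(glottal_length=50.0)


def _cycles_from_periods(periods_s, fs=4000.0, amplitude=100.0, gap=0.0):
    """Build a GAW with exact per-cycle sample counts from given periods."""
    counts = [int(round(p * fs)) for p in periods_s]
    boundaries = np.concatenate([[0], np.cumsum(counts)])
    total = []
    for c in counts:
        u = np.arange(c) / c
        total.append(gap + (amplitude - gap) * np.sin(np.pi * u) ** 2)
    total = np.concatenate(total)
    gaw = GAWRecord(total=total, left=total / 2, right=total / 2, fs=fs)
    cyc = CycleSegmentation(boundaries=boundaries, fs=fs)
    return gaw, cyc


class TestF0Stats:
    def test_constant_periods(self):
        gaw, cyc = _cycles_from_periods([0.01] * 5)
        out = compute_f0_stats(gaw, cyc)
        assert out["F0_mean"] == 100.0
        assert out["F0_std"] == 0.0

    def test_mean_of_cycle_rates(self):
        gaw, cyc = _cycles_from_periods([0.010, 0.0125])
        out = compute_f0_stats(gaw, cyc)
        assert out["F0_mean"] == pytest.approx(90.0)  # mean of 100 and 80 Hz

    def test_requires_two_cycles(self):
        gaw, cyc = _cycles_from_periods([0.01])
        with pytest.raises(FeatureExtractionError):
            compute_f0_stats(gaw, cyc)

    def test_matches_generator_truth(self):
        sg = generate_gaw(GAWSynthesisParams(f0=110.0, duration=0.3, jitter=0.015, seed=3))
        out = compute_f0_stats(sg.gaw, sg.cycle_segmentation())
        f = 1.0 / sg.periods
        assert out["F0_mean"] == pytest.approx(f.mean(), rel=1e-12)
        assert out["F0_std"] == pytest.approx(np.std(f, ddof=1), rel=1e-12)


class TestPerturbation:
    def test_zero_perturbation_fixed_point(self, clean_gaw, clean_cycles):
        out = compute_perturbation(clean_gaw.gaw, clean_cycles)
        assert out["mJit"] == 0.0
        assert out["PVI"] == 0.0
        assert out["mShim"] == 0.0
        assert out["AVI"] == 0.0
        assert out["EPF"] == 0.0
        assert out["TP_mean"] == 1.0 and out["TP_std"] == 0.0
        assert out["AP_mean"] == 1.0 and out["AP_std"] == 0.0

    def test_hand_arithmetic(self):
        gaw, cyc = _cycles_from_periods([0.010, 0.010, 0.012])
        out = compute_perturbation(gaw, cyc)
        assert out["mJit"] == pytest.approx(0.001)  # mean of {0, 2 ms}
        assert out["TP_mean"] == pytest.approx(np.mean([1.0, 10.0 / 12.0]))
        assert out["PVI"] == pytest.approx(100.0 * 0.001 / np.mean([0.010, 0.010, 0.012]))

    def test_matches_double_loop_oracle(self):
        """Every consecutive-pair statistic equals a naive double-loop
        implementation on random 10-cycle inputs."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            periods = 0.01 * (1 + 0.05 * rng.standard_normal(10))
            gaw, cyc = _cycles_from_periods(periods, amplitude=100.0)
            # perturb amplitudes by scaling each cycle
            scale = 1 + 0.1 * rng.standard_normal(10)
            total = gaw.total.copy()
            for i, sl in enumerate(cyc.slices()):
                total[sl] *= scale[i]
            gaw = GAWRecord(total=total, left=total / 2, right=total / 2, fs=gaw.fs)
            cyc = CycleSegmentation(boundaries=cyc.boundaries, fs=gaw.fs)
            out = compute_perturbation(gaw, cyc)

            t = np.diff(cyc.boundaries) / gaw.fs
            a = np.array([total[sl].max() - total[sl].min() for sl in cyc.slices()])
            e = np.array([np.sum(total[sl] ** 2) for sl in cyc.slices()])
            mjit = sum(abs(t[i + 1] - t[i]) for i in range(9)) / 9
            mshim = (sum(abs(a[i + 1] - a[i]) for i in range(9)) / 9) / np.mean(a)
            tp = [min(t[i], t[i + 1]) / max(t[i], t[i + 1]) for i in range(9)]
            ap = [min(a[i], a[i + 1]) / max(a[i], a[i + 1]) for i in range(9)]
            epf = (sum(abs(e[i + 1] - e[i]) for i in range(9)) / 9) / np.mean(e)
            assert out["mJit"] == pytest.approx(mjit, abs=1e-12)
            assert out["mShim"] == pytest.approx(mshim, abs=1e-12)
            assert out["TP_mean"] == pytest.approx(np.mean(tp), abs=1e-12)
            assert out["AP_mean"] == pytest.approx(np.mean(ap), abs=1e-12)
            assert out["TP_std"] == pytest.approx(np.std(tp, ddof=1), abs=1e-12)
            assert out["EPF"] == pytest.approx(epf, abs=1e-12)


class TestDynamics:
    def test_full_closure_zero_ggi(self, clean_gaw, clean_cycles):
        out = compute_dynamics(clean_gaw.gaw, clean_cycles)
        assert out["GGI_mean"] == 0.0

    def test_gap_recovery(self):
        sg = generate_gaw(GAWSynthesisParams(f0=100.0, duration=0.25, gap=0.3))
        cyc = detect_cycles(sg.gaw)
        out = compute_dynamics(sg.gaw, cyc)
        assert out["GGI_mean"] == pytest.approx(0.3, abs=0.02)
        assert out["GGI_std"] == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_triangle_hand_enumeration(self):
        """A symmetric triangular pulse occupying the whole cycle: SQ = 1 and
        OQ equals the hand-counted fraction above the 5% baseline."""
        c = 42  # no sample lands exactly on the 5% baseline
        u = np.arange(c) / c
        tri = np.minimum(u, 1 - u) * 200.0
        total = np.tile(tri, 4)
        gaw = GAWRecord(total=total, left=total / 2, right=total / 2, fs=4000.0)
        cyc = CycleSegmentation(boundaries=np.arange(0, 4 * c + 1, c), fs=4000.0)
        out = compute_dynamics(gaw, cyc)
        assert out["SQ_mean"] == pytest.approx(1.0)
        baseline = 0.05 * tri.max()
        open_idx = np.flatnonzero(tri > baseline)
        expected_oq = (open_idx[-1] - open_idx[0] + 1) / c
        assert out["OQ_mean"] == pytest.approx(expected_oq)

    def test_zero_range_cycle_raises(self):
        total = np.zeros(100)
        gaw = GAWRecord(total=total, left=total, right=total, fs=4000.0)
        cyc = CycleSegmentation(boundaries=np.array([0, 50, 100]), fs=4000.0)
        with pytest.raises(FeatureExtractionError):
            compute_dynamics(gaw, cyc)


class TestMechanical:
    def test_alr_scaling_law(self, clean_gaw, clean_cycles):
        out1 = compute_mechanical(clean_gaw.gaw, clean_cycles, glottal_length=50.0)
        out2 = compute_mechanical(clean_gaw.gaw, clean_cycles, glottal_length=100.0)
        assert out2["ALR_mean"] == pytest.approx(out1["ALR_mean"] / 2.0)

    def test_amplitude_homogeneity(self, clean_gaw, clean_cycles):
        """Scaling the GAW by c leaves STF and AQ unchanged (both ratios of
        amplitude-scaled quantities)."""
        g = clean_gaw.gaw
        scaled = GAWRecord(total=3.0 * g.total, left=3.0 * g.left, right=3.0 * g.right, fs=g.fs)
        cyc = CycleSegmentation(boundaries=clean_cycles.boundaries, fs=g.fs)
        out1 = compute_mechanical(g, CycleSegmentation(boundaries=clean_cycles.boundaries, fs=g.fs), 50.0)
        out2 = compute_mechanical(scaled, cyc, 50.0)
        assert out2["STF_mean"] == pytest.approx(out1["STF_mean"], rel=1e-9)
        assert out2["AQ_mean"] == pytest.approx(out1["AQ_mean"], rel=1e-9)
        assert out2["ALR_mean"] == pytest.approx(3.0 * out1["ALR_mean"], rel=1e-9)

    def test_sinusoid_closed_form(self):
        """For a sinusoidal cycle the amplitude quotient approaches
        (peak-to-peak amplitude) / max |dA/dt| = 2/omega."""
        gaw = sinusoid_gaw(f0=100.0, n_cycles=10)
        cyc = sinusoid_cycles(gaw)
        out = compute_mechanical(gaw, cyc, glottal_length=50.0)
        omega = 2 * np.pi * 100.0
        assert out["AQ_mean"] == pytest.approx(2.0 / omega, rel=0.05)

    def test_requires_positive_length(self, clean_gaw, clean_cycles):
        with pytest.raises(FeatureExtractionError):
            compute_mechanical(clean_gaw.gaw, clean_cycles, glottal_length=0.0)


class TestSymmetry:
    def test_identical_halves(self, clean_gaw, clean_cycles):
        out = compute_symmetry(clean_gaw.gaw, clean_cycles)
        assert out["PA_mean"] == 0.0 and out["PA_std"] == 0.0
        assert out["PAI_mean"] == 0.0 and out["PAI_std"] == 0.0

    def test_phase_lag_recovery(self):
        sg = generate_gaw(GAWSynthesisParams(f0=100.0, duration=0.25, phase_lag=0.1))
        cyc = detect_cycles(sg.gaw)
        out = compute_symmetry(sg.gaw, cyc)
        one_sample = 1.0 / (4000.0 * 0.01)  # one sample as a fraction of T
        assert abs(out["PA_mean"] - 0.1) <= one_sample

    def test_swap_antisymmetry(self):
        sg = generate_gaw(GAWSynthesisParams(f0=100.0, duration=0.25, phase_lag=0.12, seed=2))
        cyc = detect_cycles(sg.gaw)
        out = compute_symmetry(sg.gaw, cyc)
        swapped = GAWRecord(
            total=sg.gaw.total, left=sg.gaw.right, right=sg.gaw.left, fs=sg.gaw.fs
        )
        out2 = compute_symmetry(swapped, cyc)
        assert out2["PA_mean"] == pytest.approx(-out["PA_mean"], abs=1e-12)
        assert out2["PAI_mean"] == pytest.approx(out["PAI_mean"], abs=1e-12)

    def test_constant_halves_raise(self):
        total = np.tile(np.sin(np.linspace(0, 2 * np.pi, 40)) ** 2, 5)
        gaw = GAWRecord(total=total, left=np.full_like(total, 0.5), right=total - 0.5, fs=4000.0)
        cyc = CycleSegmentation(boundaries=np.arange(0, 201, 40), fs=4000.0)
        with pytest.raises(FeatureExtractionError):
            compute_symmetry(gaw, cyc)


class TestNoise:
    def test_harmonic_limit(self):
        """A pure sinusoid is all harmonic energy: HI ~ 1, SF ~ 0, WMC = 1."""
        gaw = sinusoid_gaw(f0=100.0, n_cycles=25)
        cyc = sinusoid_cycles(gaw)
        out = compute_noise(gaw, cyc)
        assert out["HI"] > 0.99
        assert out["WMC_mean"] > 0.999
        assert out["SF"] < 0.01
        assert out["NNE_mean"] < -20.0

    def test_noise_limit(self):
        """White noise: spectral flatness near 1, low harmonic fraction."""
        rng = np.random.default_rng(0)
        total = rng.standard_normal(1000) + 10.0
        gaw = GAWRecord(total=total, left=total / 2, right=total / 2, fs=4000.0)
        cyc = CycleSegmentation(boundaries=np.arange(0, 1001, 40), fs=4000.0)
        out = compute_noise(gaw, cyc)
        assert out["SF"] > 0.9
        assert out["HI"] < 0.5

    def test_nne_monotone_in_snr(self):
        """Less SNR means more noise energy: NNE strictly increases as the
        configured SNR drops (common random numbers)."""
        nne = []
        for snr in [40.0, 20.0, 10.0]:
            sg = generate_gaw(
                GAWSynthesisParams(f0=100.0, duration=0.25, snr_db=snr, seed=12)
            )
            cyc = detect_cycles(sg.gaw)
            nne.append(compute_noise(sg.gaw, cyc)["NNE_mean"])
        assert nne[0] < nne[1] < nne[2]

    def test_window_longer_than_signal_raises(self):
        gaw = sinusoid_gaw(n_cycles=4)
        cyc = sinusoid_cycles(gaw)
        with pytest.raises(FeatureExtractionError):
            compute_noise(gaw, cyc)


class TestNyquist:
    def test_identical_cycles_unit_consistency(self, clean_gaw, clean_cycles):
        out = compute_nyquist(clean_gaw.gaw, clean_cycles)
        assert out["TC_mean"] > 0.99
        assert out["TC_std"] == pytest.approx(0.0, abs=1e-3)

    def test_circle_trajectory_zero_wtv(self):
        """A pure sinusoid's analytic-signal orbit is a circle: WTV = 0."""
        gaw = sinusoid_gaw(f0=100.0, n_cycles=20, offset=0.0)
        cyc = sinusoid_cycles(gaw)
        out = compute_nyquist(gaw, cyc)
        assert out["WTV_mean"] == pytest.approx(0.0, abs=1e-6)

    def test_wtv_monotone_in_noise(self):
        """Within-trajectory variability rises strictly with its injected
        driver, the additive noise contaminating the orbit."""
        wtv = []
        for snr in [np.inf, 40.0, 30.0, 20.0, 10.0]:
            sg = generate_gaw(
                GAWSynthesisParams(f0=100.0, duration=0.25, snr_db=snr, seed=21)
            )
            cyc = sg.cycle_segmentation()
            wtv.append(compute_nyquist(sg.gaw, cyc)["WTV_mean"])
        assert all(np.diff(wtv) > 0)


class TestExtractAll:
    def test_48_entries_in_canonical_order(self, clean_gaw, clean_cycles):
        fv = extract_all(clean_gaw.gaw, clean_cycles, CONFIG)
        assert fv.values.shape == (48,)
        assert list(fv.to_dict().keys()) == list(FEATURE_NAMES)
        assert not np.isnan(fv.values).any()

    def test_zero_perturbation_fixed_points_simultaneously(self, clean_gaw, clean_cycles):
        fv = extract_all(clean_gaw.gaw, clean_cycles, CONFIG)
        for name in ["mJit", "PVI", "mShim", "AVI", "EPF", "F0_std", "PA_std"]:
            assert fv[name] == 0.0, name
        for name in ["TP_mean", "AP_mean", "WMC_mean"]:
            assert fv[name] == 1.0, name

    def test_missing_glottal_length_is_annotated(self, clean_gaw, clean_cycles):
        with pytest.raises(FeatureExtractionError, match="mechanical"):
            extract_all(clean_gaw.gaw, clean_cycles, FeatureConfig())

    def test_feature_vector_round_trip(self, clean_gaw, clean_cycles):
        fv = extract_all(clean_gaw.gaw, clean_cycles, CONFIG)
        again = GlottalFeatureVector.from_dict(fv.to_dict())
        np.testing.assert_array_equal(fv.values, again.values)


RATIO_FEATURES = [
    "TP_mean", "TP_std", "AP_mean", "AP_std", "OQ_mean", "CQ_mean", "PQ_mean",
    "SQ_mean", "GAI_mean", "GGI_mean", "PA_mean", "PAI_mean", "WMC_mean",
    "HI", "SF", "TC_mean", "WTV_mean", "STF_mean",
]


def test_scale_invariance_of_ratio_features(perturbed_gaw, perturbed_cycles):
    """Multiplying the GAW by c > 0 leaves all dimensionless ratio features
    unchanged to 1e-9."""
    g = perturbed_gaw.gaw
    fv1 = extract_all(g, perturbed_cycles, CONFIG)
    c = 7.3
    scaled = GAWRecord(total=c * g.total, left=c * g.left, right=c * g.right, fs=g.fs)
    cyc = CycleSegmentation(boundaries=perturbed_cycles.boundaries, fs=g.fs)
    fv2 = extract_all(scaled, cyc, CONFIG)
    for name in RATIO_FEATURES:
        assert fv2[name] == pytest.approx(fv1[name], abs=1e-9), name


def test_perturbation_features_monotone_in_drivers():
    """mJit/PVI/mShim/AVI/EPF are nondecreasing across a 5-level jitter and
    shimmer sweep with common random numbers."""
    feats = []
    for level in [0.0, 0.01, 0.02, 0.04, 0.08]:
        sg = generate_gaw(
            GAWSynthesisParams(
                f0=100.0, duration=0.25, jitter=level, shimmer=level, seed=17
            )
        )
        feats.append(compute_perturbation(sg.gaw, sg.cycle_segmentation()))
    for name in ["mJit", "PVI", "mShim", "AVI", "EPF"]:
        vals = [f[name] for f in feats]
        assert all(np.diff(vals) >= 0), (name, vals)
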