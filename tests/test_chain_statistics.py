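"""Profiles and persistence-length fits: hand oracles, recovery, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanorodmech import (
    ChainEnsemble,
    FiberContour,
    WlcParams,
    bond_correlation_profile,
    bootstrap_persistence,
    eval_wlc_msed,
    filter_fibers,
    fit_persistence_bcf,
    fit_persistence_msmd,
    fit_persistence_wlc,
    generate_contour_ensemble,
    ms_end_to_end_profile,
    msmd_profile,
)
from nanorodmech.chain_statistics import DistanceProfile, MODE_MSED
from nanorodmech.errors import (
    EmptyEnsembleError,
    FitError,
    ModeError,
    ParameterError,
)

from conftest import RECOVERY_LAMBDA


def brute_force_msed(ensemble, n_bins, l_max):
    """Independent oracle: explicit double loop over all point pairs."""
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for c in ensemble.contours:
        n = c.n_points
        for i in range(n):
            for j in range(i + 1, n):
                l = c.arc[j] - c.arc[i]
                if l > l_max:
                    continue
                r2 = float(np.sum((c.points[j] - c.points[i]) ** 2))
                b = min(int(l / l_max * n_bins), n_bins - 1)
                sums[b] += r2
                counts[b] += 1
    centers, means, cts = [], [], []
    width = l_max / n_bins
    for b in range(n_bins):
        if counts[b]:
            centers.append((b + 0.5) * width)
            means.append(sums[b] / counts[b])
            cts.append(counts[b])
    return np.array(centers), np.array(means), np.array(cts)


class TestFiberContour:
    def test_arc_lengths_computed_on_build(self, elbow_contour):
        assert np.allclose(elbow_contour.arc, [0, 1, 2, 3])
        assert elbow_contour.length == pytest.approx(3.0)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ParameterError):
            FiberContour.from_points([[0.0, 0.0]])
        with pytest.raises(ParameterError):
            FiberContour.from_points([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ParameterError):
            FiberContour(points=np.array([[0.0, 0.0], [1.0, 0.0]]),
                         arc=np.array([0.0, 2.0]))


class TestFilterFibers:
    def _ensemble(self, lengths):
        contours = [
            FiberContour.from_points(
                np.column_stack([np.linspace(0, ln, 5), np.zeros(5)])
            )
            for ln in lengths
        ]
        return ChainEnsemble(contours=contours)

    def test_length_threshold(self):
        ens = filter_fibers(self._ensemble([40.0, 60.0, 300.0]), 50.0)
        assert len(ens) == 2
        assert ens.metadata["n_before_filter"] == 3
        assert ens.metadata["n_after_filter"] == 2

    def test_zero_threshold_is_identity(self):
        ens = filter_fibers(self._ensemble([40.0, 60.0]), 0.0)
        assert len(ens) == 2

    def test_empty_result_raises(self):
        with pytest.raises(EmptyEnsembleError):
            filter_fibers(self._ensemble([45.0] * 10), 50.0)


class TestMsEndToEndProfile:
    def test_straight_contour_identity(self, straight_contour):
        ens = ChainEnsemble(contours=[straight_contour])
        prof = ms_end_to_end_profile(ens, n_bins=4)
        # on a straight line every pair satisfies R^2 = l^2 exactly
        centers, means, counts = brute_force_msed(ens, 4, straight_contour.length)
        assert np.allclose(prof.values, means)
        pair_l = np.sqrt(prof.values)  # recover each bin's pair arc length
        assert np.allclose(prof.values, pair_l**2)

    def test_hand_enumerated_elbow(self, elbow_contour):
        # pairs: (1,1)x3, (2,4),(2,2),(3,5); two bins on [0,3]
        ens = ChainEnsemble(contours=[elbow_contour])
        prof = ms_end_to_end_profile(ens, n_bins=2, l_max=3.0)
        assert np.allclose(prof.counts, [3, 3])
        assert prof.values[0] == pytest.approx(1.0)
        assert prof.values[1] == pytest.approx((4 + 2 + 5) / 3)

    def test_matches_brute_force_on_small_contours(self, small_random_contours):
        l_max = max(c.length for c in small_random_contours.contours)
        prof = ms_end_to_end_profile(small_random_contours, n_bins=10)
        centers, means, counts = brute_force_msed(small_random_contours, 10, l_max)
        assert np.allclose(prof.l, centers, rtol=1e-12)
        assert np.allclose(prof.values, means, rtol=1e-12)
        assert np.array_equal(prof.counts, counts)

    def test_default_binning_is_100(self, recovery_ensemble):
        prof = ms_end_to_end_profile(recovery_ensemble)
        assert prof.l.size <= 100
        width = prof.l[1] - prof.l[0]
        assert width == pytest.approx(500.0 / 100)

    def test_rejects_bad_inputs(self):
        with pytest.raises(EmptyEnsembleError):
            ms_end_to_end_profile(ChainEnsemble(contours=[]))
        ens = ChainEnsemble(contours=[
            FiberContour.from_points([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        ])
        with pytest.raises(ParameterError):
            ms_end_to_end_profile(ens, n_bins=1)


class TestWlcModel:
    def test_zero_length(self):
        assert eval_wlc_msed(0.0, 50.0) == 0.0

    def test_direct_arithmetic(self):
        # 4*100*[200 - 200*(1 - e^-1)] = 80000/e
        assert eval_wlc_msed(200.0, 100.0) == pytest.approx(80000.0 / np.e,
                                                            rel=1e-12)

    def test_rigid_and_flexible_limits(self):
        lam = 100.0
        l_stiff = lam * 1e-3
        assert eval_wlc_msed(l_stiff, lam) / l_stiff**2 == pytest.approx(
            1.0, abs=5e-3
        )
        l_floppy = lam * 1e3
        assert eval_wlc_msed(l_floppy, lam) / (4 * lam * l_floppy) == \
            pytest.approx(1.0, abs=5e-3)

    def test_rejects_invalid(self):
        with pytest.raises(ParameterError):
            eval_wlc_msed(10.0, 0.0)
        with pytest.raises(ParameterError):
            eval_wlc_msed(-1.0, 10.0)

    @given(
        lam=st.floats(min_value=1.0, max_value=1e5),
        l=st.floats(min_value=1e-3, max_value=1e4),
        factor=st.floats(min_value=1.01, max_value=10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_increasing(self, lam, l, factor):
        assert eval_wlc_msed(l * factor, lam) > eval_wlc_msed(l, lam)
        assert eval_wlc_msed(l, lam * factor) > eval_wlc_msed(l, lam)


class TestWlcFit:
    def test_self_consistency_exact_profile(self):
        lam = 50.0
        l = np.linspace(5.0, 400.0, 60)
        prof = DistanceProfile(l=l, values=eval_wlc_msed(l, lam),
                               counts=np.full(l.size, 100), mode=MODE_MSED)
        fit = fit_persistence_wlc(prof)
        assert fit.lam == pytest.approx(lam, rel=1e-6)
        assert fit.estimator == "wlc_msed"

    def test_recovery_on_synthetic_ensemble(self, recovery_profiles):
        fit = fit_persistence_wlc(recovery_profiles["msed"])
        assert fit.lam == pytest.approx(RECOVERY_LAMBDA, rel=0.10)
        assert fit.lam_sd >= 0

    def test_near_rigid_regime_converges(self):
        # lambda >> L with tracing noise: biased low but must converge
        params = WlcParams(persistence_length=1e4, contour_length=200.0,
                           step=2.0, seed=3)
        ens = generate_contour_ensemble(params, 200, (200.0, 200.0),
                                        noise_sd=0.5, seed=3)
        fit = fit_persistence_wlc(ms_end_to_end_profile(ens, n_bins=50))
        assert fit.lam > 0
        assert fit.lam < 1e4  # noise-induced downward bias
        assert fit.lam_sd >= 0

    def test_wrong_mode_rejected(self, recovery_profiles):
        with pytest.raises(ModeError):
            fit_persistence_wlc(recovery_profiles["correlation"])

    def test_too_few_bins_rejected(self):
        prof = DistanceProfile(l=np.array([1.0, 2.0]),
                               values=np.array([1.0, 4.0]),
                               counts=np.array([10, 10]), mode=MODE_MSED)
        with pytest.raises(FitError):
            fit_persistence_wlc(prof)

    def test_rotation_translation_invariance(self):
        params = WlcParams(persistence_length=100.0, contour_length=300.0,
                           step=2.0, seed=17)
        ens = generate_contour_ensemble(params, 100, (150, 300),
                                        noise_sd=0.0, seed=17)
        angle = 0.7
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = ChainEnsemble(
            contours=[
                FiberContour.from_points(c.points @ rot.T + [13.0, -40.0])
                for c in ens.contours
            ],
            metadata=dict(ens.metadata),
        )
        f1 = fit_persistence_wlc(ms_end_to_end_profile(ens))
        f2 = fit_persistence_wlc(ms_end_to_end_profile(moved))
        assert f2.lam == pytest.approx(f1.lam, rel=1e-6)


class TestBondCorrelation:
    def test_straight_contour_full_correlation(self, straight_contour):
        prof = bond_correlation_profile(
            ChainEnsemble(contours=[straight_contour]), n_bins=3
        )
        assert np.allclose(prof.values, 1.0)

    def test_right_angle_single_pair(self):
        contour = FiberContour.from_points([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        prof = bond_correlation_profile(ChainEnsemble(contours=[contour]),
                                        n_bins=2)
        assert prof.counts.sum() == 1
        assert prof.values[-1] == pytest.approx(0.0, abs=1e-12)

    def test_profile_matches_exponential(self, recovery_profiles):
        prof = recovery_profiles["correlation"]
        expected = np.exp(-prof.l / (2 * RECOVERY_LAMBDA))
        # Monte-Carlo scatter: generous absolute band on binned means
        assert np.max(np.abs(prof.values - expected)[prof.l < 300]) < 0.05

    def test_self_consistency_exact_profile(self):
        l = np.linspace(2.0, 300.0, 50)
        prof = DistanceProfile(l=l, values=np.exp(-l / 100.0),
                               counts=np.full(l.size, 50),
                               mode="correlation")
        fit = fit_persistence_bcf(prof)
        assert fit.lam == pytest.approx(50.0, rel=1e-6)

    def test_recovery_on_synthetic_ensemble(self, recovery_profiles):
        fit = fit_persistence_bcf(recovery_profiles["correlation"])
        assert fit.lam == pytest.approx(RECOVERY_LAMBDA, rel=0.15)


class TestMidpointDisplacement:
    def test_straight_contour_zero_deviation(self, straight_contour):
        prof = msmd_profile(ChainEnsemble(contours=[straight_contour]),
                            n_bins=2)
        assert np.allclose(prof.values, 0.0)

    def test_circular_arc_sagitta(self):
        # symmetric 3-point arc: chord 2 nm, sagitta 0.1 nm => u^2 = 0.01
        contour = FiberContour.from_points([[0.0, 0.0], [1.0, 0.1], [2.0, 0.0]])
        prof = msmd_profile(ChainEnsemble(contours=[contour]), n_bins=2)
        assert prof.counts.sum() == 1
        assert prof.values[-1] == pytest.approx(0.01, rel=1e-9)

    def test_recovery_on_synthetic_ensemble(self, recovery_profiles):
        fit = fit_persistence_msmd(recovery_profiles["midpoint"])
        assert fit.lam == pytest.approx(RECOVERY_LAMBDA, rel=0.15)
        assert fit.estimator == "msmd"


class TestEstimatorConsistency:
    def test_three_estimators_agree(self, recovery_profiles):
        wlc = fit_persistence_wlc(recovery_profiles["msed"]).lam
        bcf = fit_persistence_bcf(recovery_profiles["correlation"]).lam
        msmd = fit_persistence_msmd(recovery_profiles["midpoint"]).lam
        assert bcf == pytest.approx(wlc, rel=0.15)
        assert msmd == pytest.approx(wlc, rel=0.15)


class TestBootstrap:
    def test_seeded_and_positive_spread(self):
        params = WlcParams(persistence_length=100.0, contour_length=200.0,
                           step=2.0, seed=23)
        ens = generate_contour_ensemble(params, 60, (150, 200),
                                        noise_sd=0.0, seed=23)
        m1, sd1, s1 = bootstrap_persistence(ens, n_boot=20, n_bins=40, seed=5)
        m2, sd2, s2 = bootstrap_persistence(ens, n_boot=20, n_bins=40, seed=5)
        assert np.array_equal(s1, s2)
        assert sd1 > 0
        assert m1 == pytest.approx(100.0, rel=0.35)
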