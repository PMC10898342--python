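"""Segment planning, segment-averaged MI, and profile comparison metrics."""

import numpy as np
import pytest

from dyncorr.convergence import (
    MIProfile,
    averaged_mi,
    convergence_curve,
    plan_segments,
    profile_correlation,
    profile_rmsd,
)
from dyncorr.gaussian_estimators import multivariate_gaussian_mi, pair_covariance
from dyncorr.synthetic_data import (
    analytic_mi_profile,
    make_random_spec,
    sample_gaussian_trajectory,
)
from dyncorr.trajectory_io import FluctuationTrajectory


class TestPlanSegments:
    def test_exact_tiling(self):
        scheme = plan_segments(1000, 200, 5)
        assert scheme.offsets == (0, 200, 400, 600, 800)
        assert not scheme.overlap_allowed

    def test_overlapping_even_spread(self):
        scheme = plan_segments(1000, 400, 3)
        assert scheme.offsets == (0, 300, 600)
        assert scheme.overlap_allowed

    def test_single_full_segment(self):
        scheme = plan_segments(100, 100, 1)
        assert scheme.offsets == (0,)

    def test_oversized_segment_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            plan_segments(100, 101, 1)

    def test_deterministic(self):
        assert plan_segments(977, 100, 7) == plan_segments(977, 100, 7)

    def test_disjoint_when_they_fit(self):
        scheme = plan_segments(1050, 100, 10)
        assert not scheme.overlap_allowed
        for a, b in zip(scheme.offsets, scheme.offsets[1:]):
            assert b - a >= 100


class TestAveragedMI:
    def test_single_segment_equals_plain_estimator(self):
        spec = make_random_spec(4, seed=31)
        fluct = sample_gaussian_trajectory(spec, 2000)
        scheme = plan_segments(2000, 2000, 1)
        profile = averaged_mi(fluct, scheme, "gauss_multi", anchor=0)
        for other, value in zip(profile.others, profile.values):
            direct = multivariate_gaussian_mi(pair_covariance(fluct, 0, int(other))).value
            assert value == pytest.approx(direct, abs=1e-12)

    def test_arithmetic_mean_of_segment_values(self):
        spec = make_random_spec(3, seed=32)
        fluct = sample_gaussian_trajectory(spec, 1000)
        scheme = plan_segments(1000, 500, 2)
        profile = averaged_mi(fluct, scheme, "gauss_multi", anchor=0)
        # recompute per segment by hand, with per-segment mean removal
        manual = []
        for offset in scheme.offsets:
            block = fluct.deltas[offset : offset + 500]
            seg = FluctuationTrajectory(block - block.mean(axis=0, keepdims=True))
            manual.append(
                [multivariate_gaussian_mi(pair_covariance(seg, 0, j)).value for j in (1, 2)]
            )
        np.testing.assert_allclose(profile.values, np.mean(manual, axis=0), atol=1e-12)

    def test_segment_averaging_reduces_variance(self):
        # averaged short segments scatter less across seeds than one segment
        spec_master = make_random_spec(3, seed=33)
        single, averaged = [], []
        for seed in range(20):
            spec = make_random_spec(3, seed=400 + seed)
            spec.covariance = spec_master.covariance  # same truth, new noise
            fluct = sample_gaussian_trajectory(spec, 5000)
            one = averaged_mi(fluct, plan_segments(5000, 500, 1), "gauss_multi", anchor=0)
            ten = averaged_mi(fluct, plan_segments(5000, 500, 10), "gauss_multi", anchor=0)
            single.append(one.values[0])
            averaged.append(ten.values[0])
        assert np.var(averaged) < np.var(single)

    def test_full_map_mode(self):
        spec = make_random_spec(3, seed=34)
        fluct = sample_gaussian_trajectory(spec, 1000)
        mat = averaged_mi(fluct, plan_segments(1000, 1000, 1), "gauss_multi", anchor="all")
        assert mat.values.shape == (3, 3)
        np.testing.assert_array_equal(mat.values, mat.values.T)


def _profile(values, anchor=0):
    values = np.asarray(values, dtype=float)
    others = np.arange(1, len(values) + 1)
    return MIProfile(anchor, others, values)


class TestProfileRMSD:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([0.3, 0.1, 0.7], [0.3, 0.1, 0.7], 0.0),
            ([0.0, 1.0], [1.0, 0.0], 1.0),
            ([0.1, 0.2, 0.3], [0.2, 0.4, 0.1], np.sqrt(0.09 / 3)),
        ],
    )
    def test_hand_values(self, a, b, expected):
        assert profile_rmsd(_profile(a), _profile(b)) == pytest.approx(expected, abs=1e-12)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(35)
        for _ in range(20):
            a, b, c = (_profile(rng.normal(size=6)) for _ in range(3))
            assert profile_rmsd(a, b) == pytest.approx(profile_rmsd(b, a), abs=1e-15)
            assert profile_rmsd(a, a) == 0.0
            assert profile_rmsd(a, c) <= profile_rmsd(a, b) + profile_rmsd(b, c) + 1e-12

    def test_flagged_entries_excluded_pairwise(self):
        a = _profile([0.1, np.nan, 0.3])
        b = _profile([0.1, 0.2, 0.5])
        assert profile_rmsd(a, b) == pytest.approx(np.sqrt(0.04 / 2), abs=1e-12)

    def test_mismatched_profiles_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            profile_rmsd(_profile([0.1, 0.2]), _profile([0.1, 0.2], anchor=3))


class TestProfileCorrelation:
    def test_affine_image_has_unit_correlation(self):
        a = _profile([1.0, 2.0, 5.0, 3.0])
        b = _profile(2.0 * np.asarray([1.0, 2.0, 5.0, 3.0]) + 1.0)
        assert profile_correlation(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_negated_profile_anticorrelates(self):
        a = _profile([1.0, 2.0, 5.0])
        b = _profile([-1.0, -2.0, -5.0])
        assert profile_correlation(a, b) == pytest.approx(-1.0, abs=1e-12)

    def test_three_point_closed_form(self):
        assert profile_correlation(
            _profile([1.0, 2.0, 3.0]), _profile([1.0, 3.0, 2.0])
        ) == pytest.approx(0.5, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(36)
        a = _profile(rng.normal(size=8))
        b = _profile(rng.normal(size=8))
        r = profile_correlation(a, b)
        scaled = MIProfile(a.anchor, a.others, 3.5 * a.values - 2.0)
        assert profile_correlation(scaled, b) == pytest.approx(r, abs=1e-12)

    def test_zero_variance_flagged(self):
        assert np.isnan(profile_correlation(_profile([1.0, 1.0, 1.0]), _profile([1.0, 2.0, 3.0])))


class TestConvergenceCurve:
    def test_self_reference_last_row_is_exact(self):
        spec = make_random_spec(4, seed=37)
        fluct = sample_gaussian_trajectory(spec, 2000)
        reference = averaged_mi(fluct, plan_segments(2000, 2000, 1), "gauss_multi", anchor=0)
        curve = convergence_curve(fluct, [500, 2000], "gauss_multi", reference, anchor=0)
        length, rmsd, r, n_seg = curve.rows[-1]
        assert length == 2000 and n_seg == 1
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_rmsd_shrinks_toward_analytic_reference(self):
        rmsds = []
        for seed in range(5):
            spec = make_random_spec(4, seed=500 + seed)
            fluct = sample_gaussian_trajectory(spec, 20_000)
            reference = analytic_mi_profile(spec, 0)
            curve = convergence_curve(fluct, [100, 1000, 20_000], "gauss_multi", reference, 0)
            rmsds.append(curve.as_arrays()[1])
        mean = np.mean(rmsds, axis=0)
        assert np.all(np.diff(mean) < 0)

    def test_empty_lengths_give_empty_curve(self):
        spec = make_random_spec(3, seed=38)
        fluct = sample_gaussian_trajectory(spec, 100)
        reference = analytic_mi_profile(spec, 0)
        curve = convergence_curve(fluct, [], "gauss_multi", reference, 0)
        assert curve.rows == []

    def test_unsorted_lengths_rejected(self):
        spec = make_random_spec(3, seed=39)
        fluct = sample_gaussian_trajectory(spec, 100)
        reference = analytic_mi_profile(spec, 0)
        with pytest.raises(ValueError, match="sorted"):
            convergence_curve(fluct, [50, 20], "gauss_multi", reference, 0)
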