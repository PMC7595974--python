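"""Neighborhood assignment and the C/D/S/P diagnostic scores."""

import numpy as np
import pytest

from analogscope.chemspace import StandardizedSpace, fit_standardizer
from analogscope.nbh import (
    NeighborhoodAssignment,
    assign_neighborhoods,
    calibrate_radius,
    coverage_score,
    density_score,
    progression_score,
    saturation_score,
    score_with_resampling,
)
from analogscope.records import RunConfig


def _identity_space(dim):
    return StandardizedSpace(center=np.zeros(dim), scale=np.ones(dim))


def _assignment(membership, n_vas):
    return NeighborhoodAssignment(
        radius=1.0, membership=membership, va_count_total=n_vas
    )


class TestAssignment:
    def test_radius_zero_only_coincident_points(self):
        space = _identity_space(2)
        eas = np.array([[0.0, 0.0]])
        vas = np.array([[0.0, 1.0], [1.0, 0.0]])
        a = assign_neighborhoods(eas, vas, 0.0, space)
        assert a.membership == {"ea0": set()}

    def test_single_ea_closed_ball(self):
        space = _identity_space(1)
        eas = np.array([[0.0]])
        vas = np.array([[0.5], [1.5], [1.0]])
        a = assign_neighborhoods(eas, vas, 1.0, space)
        # closed ball: the VA exactly at the radius is included
        assert a.membership["ea0"] == {"va0", "va2"}

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        eas = rng.normal(size=(20, 5))
        vas = rng.normal(size=(200, 5))
        space = fit_standardizer(np.vstack([eas, vas]))
        radius = 1.7
        a = assign_neighborhoods(eas, vas, radius, space)
        ze, zv = space.transform(eas), space.transform(vas)
        for i in range(20):
            expected = {
                f"va{j}"
                for j in range(200)
                if np.linalg.norm(ze[i] - zv[j]) <= radius
            }
            assert a.membership[f"ea{i}"] == expected

    def test_empty_inputs_raise(self):
        space = _identity_space(2)
        with pytest.raises(ValueError):
            assign_neighborhoods(np.empty((0, 2)), np.ones((1, 2)), 1.0, space)


class TestScores:
    def test_coverage_counts_covered_fraction(self):
        a = _assignment({"e1": {"v0", "v1"}, "e2": {"v1", "v2", "v3"}}, 10)
        assert coverage_score(a) == pytest.approx(0.4)

    def test_coverage_extremes(self):
        assert coverage_score(_assignment({"e": set()}, 5)) == 0.0
        assert coverage_score(_assignment({"e": {"v0", "v1"}}, 2)) == 1.0

    def test_density_no_overlap_is_zero(self):
        a = _assignment({"e1": {"v0"}, "e2": {"v1"}}, 5)
        assert density_score(a) == 0.0

    def test_density_multiplicities_one_two_three(self):
        # covered VAs with multiplicities {1,2,3}: d_mean = 2, D = 0.5
        a = _assignment(
            {"e1": {"v0", "v1", "v2"}, "e2": {"v1", "v2"}, "e3": {"v2"}}, 10
        )
        assert density_score(a) == pytest.approx(0.5)

    def test_density_degenerate_no_covered_va(self):
        assert density_score(_assignment({"e": set()}, 5)) == 0.0

    @pytest.mark.parametrize(
        "c,d,expected",
        [(0.5, 0.5, 0.5), (0.0, 0.9, 0.0), (1.0, 0.0, 0.0)],
    )
    def test_saturation_identities(self, c, d, expected):
        assert saturation_score(c, d) == pytest.approx(expected)

    def test_saturation_between_min_and_max_and_below_geometric(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            c, d = rng.random(2)
            s = saturation_score(c, d)
            assert min(c, d) - 1e-12 <= s <= max(c, d) + 1e-12
            assert s <= np.sqrt(c * d) + 1e-12

    def test_progression_equal_potencies_is_zero(self):
        a = _assignment({"e1": {"v0"}, "e2": {"v0"}}, 2)
        assert progression_score(a, {"e1": 6.0, "e2": 6.0}) == 0.0

    def test_progression_single_shared_pair(self):
        a = _assignment(
            {"e1": {"v0", "v1"}, "e2": {"v0", "v2"}}, 4
        )  # v1, v2 have multiplicity 1 and weight 0
        assert progression_score(a, {"e1": 5.0, "e2": 7.0}) == pytest.approx(2.0)

    def test_progression_three_way_overlap(self):
        a = _assignment({"e1": {"v0"}, "e2": {"v0"}, "e3": {"v0"}}, 1)
        pots = {"e1": 5.0, "e2": 6.0, "e3": 9.0}
        # pairs |5-6|, |5-9|, |6-9| -> mean 8/3
        assert progression_score(a, pots) == pytest.approx(8.0 / 3.0)

    def test_progression_missing_potency_names_ea(self):
        a = _assignment({"e1": {"v0"}, "e2": {"v0"}}, 1)
        with pytest.raises(ValueError, match="e2"):
            progression_score(a, {"e1": 5.0})

    def test_progression_shift_invariant_and_scales_linearly(self):
        rng = np.random.default_rng(2)
        membership = {
            f"e{i}": {f"v{j}" for j in rng.choice(30, size=8, replace=False)}
            for i in range(6)
        }
        a = _assignment(membership, 30)
        pots = {f"e{i}": float(rng.normal(6, 1)) for i in range(6)}
        p0 = progression_score(a, pots)
        shifted = {k: v + 3.7 for k, v in pots.items()}
        scaled = {k: 2.5 * v for k, v in pots.items()}
        assert progression_score(a, shifted) == pytest.approx(p0)
        assert progression_score(a, scaled) == pytest.approx(2.5 * p0)


class TestMonotonicity:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.eas = rng.normal(size=(12, 4))
        self.vas = rng.normal(size=(120, 4))
        self.space = fit_standardizer(np.vstack([self.eas, self.vas]))

    def test_coverage_nondecreasing_in_radius(self):
        values = []
        for radius in np.linspace(0.1, 4.0, 12):
            a = assign_neighborhoods(self.eas, self.vas, radius, self.space)
            values.append((coverage_score(a), density_score(a)))
        cs, ds = zip(*values)
        assert all(cs[i] <= cs[i + 1] + 1e-12 for i in range(len(cs) - 1))
        assert all(ds[i] <= ds[i + 1] + 1e-12 for i in range(len(ds) - 1))

    def test_coverage_nondecreasing_under_ea_addition(self):
        rng = np.random.default_rng(4)
        extra = rng.normal(size=(6, 4))
        a = assign_neighborhoods(self.eas, self.vas, 1.5, self.space)
        b = assign_neighborhoods(
            np.vstack([self.eas, extra]), self.vas, 1.5, self.space
        )
        assert coverage_score(b) >= coverage_score(a)


class TestResampling:
    def test_same_seed_gives_identical_report(self, noisy_series, va_pool):
        cfg = RunConfig(radius=1.0, n_resamples=4, sample_size=80, seed=9)
        a = score_with_resampling(noisy_series.series.analogs, va_pool, cfg)
        b = score_with_resampling(noisy_series.series.analogs, va_pool, cfg)
        assert a.as_dict() == b.as_dict()

    def test_sample_size_equal_to_pool_gives_zero_sd(self, noisy_series, va_pool):
        cfg = RunConfig(
            radius=1.0, n_resamples=5, sample_size=len(va_pool), seed=1
        )
        rep = score_with_resampling(noisy_series.series.analogs, va_pool, cfg)
        for sd in (rep.c_sd, rep.d_sd, rep.s_sd, rep.p_sd):
            assert sd == pytest.approx(0.0, abs=1e-12)

    def test_pool_smaller_than_sample_size_raises(self, noisy_series, va_pool):
        cfg = RunConfig(radius=1.0, n_resamples=2, sample_size=10**6, seed=0)
        with pytest.raises(ValueError, match="smaller"):
            score_with_resampling(noisy_series.series.analogs, va_pool, cfg)

    def test_undersized_sample_warns(self, noisy_series, va_pool):
        cfg = RunConfig(radius=1.0, n_resamples=1, sample_size=10, seed=0)
        with pytest.warns(UserWarning, match="below twice"):
            score_with_resampling(noisy_series.series.analogs, va_pool, cfg)


class TestRadiusCalibration:
    def test_quantile_matches_sorted_distance_oracle(self):
        rng = np.random.default_rng(5)
        eas = rng.normal(size=(15, 3))
        vas = rng.normal(size=(60, 3))
        space = fit_standardizer(np.vstack([eas, vas]))
        from analogscope.chemspace import pairwise_distances

        all_d = np.sort(pairwise_distances(eas, vas, space).ravel())
        for q in (0.01, 0.25, 0.5, 0.9):
            assert calibrate_radius(eas, vas, space, q) == pytest.approx(
                np.quantile(all_d, q)
            )

    def test_monotone_in_quantile_and_full_coverage_at_one(self):
        rng = np.random.default_rng(6)
        eas = rng.normal(size=(10, 3))
        vas = rng.normal(size=(50, 3))
        space = fit_standardizer(np.vstack([eas, vas]))
        radii = [calibrate_radius(eas, vas, space, q) for q in (0.1, 0.5, 0.9, 1.0)]
        assert radii == sorted(radii)
        a = assign_neighborhoods(eas, vas, radii[-1], space)
        assert coverage_score(a) == 1.0

    def test_invalid_quantile_raises(self):
        space = _identity_space(2)
        with pytest.raises(ValueError):
            calibrate_radius(np.zeros((2, 2)), np.ones((2, 2)), space, 0.0)
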