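import numpy as np
import pytest
from scipy import stats

from suvseg import (
    AgreementSummary,
    CohortConfig,
    MethodGrid,
    backwards_summary,
    bland_altman,
    choose_correlation_type,
    coefficient_of_variation,
    correlate,
    default_grids,
    generate_cohort,
    kruskal_wallis,
    rank_methods,
    results_frame,
    solve_backwards,
    summaries_frame,
    sweep,
)


class TestCorrelationGate:
    def test_normal_samples_use_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 2, 200)
        y = rng.normal(5, 1, 200)
        assert choose_correlation_type(x, y) == "pearson"

    def test_lognormal_sample_forces_spearman(self):
        rng = np.random.default_rng(2)
        x = rng.normal(10, 2, 200)
        y = np.exp(rng.normal(0, 1, 200))
        assert choose_correlation_type(x, y) == "spearman"

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            choose_correlation_type([1.0] * 10, [1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            choose_correlation_type([1, 2, 3], [4, 5, 6])


class TestCorrelate:
    def test_perfect_linearity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 50)
        kind, r, r2, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_strictly_decreasing_gives_spearman_minus_one(self):
        x = np.arange(1.0, 21.0)
        y = np.exp(-x)  # non-normal, strictly decreasing
        kind, r, r2, p = correlate(x, y)
        assert kind == "spearman"
        assert r == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "r,expected_r2", [(0.807, 0.651), (0.762, 0.581), (0.715, 0.511), (0.764, 0.584)]
    )
    def test_r_squared_is_square_of_r_at_3_decimals(self, r, expected_r2):
        assert round(r * r, 3) == expected_r2


class TestCoV:
    def test_mean_5_4_sd_2_4_gives_44_4_percent(self):
        values = [3.0, 5.4, 7.8]  # mean 5.4, sample sd 2.4
        assert np.mean(values) == pytest.approx(5.4)
        assert np.std(values, ddof=1) == pytest.approx(2.4)
        assert coefficient_of_variation(values) == pytest.approx(44.4, abs=0.05)

    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation([7.0, 7.0, 7.0]) == 0.0

    def test_hand_computed_example(self):
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 10, 30)
        for c in (0.1, 3.7, 100.0):
            assert coefficient_of_variation(c * x) == pytest.approx(
                coefficient_of_variation(x)
            )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestBlandAltman:
    def test_identical_measures(self):
        a = [1.0, 2.0, 3.0]
        mean_diff, (lo, hi) = bland_altman(a, a)
        assert mean_diff == 0.0 and lo == 0.0 and hi == 0.0

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0])
        mean_diff, (lo, hi) = bland_altman(a + 2, a)
        assert mean_diff == pytest.approx(2.0)
        assert (lo, hi) == pytest.approx((2.0, 2.0))

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(10, 3, 50), rng.normal(9, 2, 50)
        mean_diff, (lo, hi) = bland_altman(a, b)
        d = a - b
        assert mean_diff == pytest.approx(d.mean())
        assert lo == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert hi == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        assert bland_altman(a, b)[0] == pytest.approx(-bland_altman(b, a)[0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestKruskalWallis:
    def test_identical_constant_groups(self):
        h, p = kruskal_wallis([[5.0, 5.0], [5.0, 5.0], [5.0]])
        assert h == 0.0 and p == 1.0

    def test_hand_rank_computation(self):
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [101.0, 102.0, 103.0]])
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_type_one_error_under_permutation(self):
        rng = np.random.default_rng(7)
        pooled = rng.normal(0, 1, 15)
        rejections = 0
        n_draws = 2000
        for _ in range(n_draws):
            perm = rng.permutation(pooled)
            _, p = kruskal_wallis([perm[:5], perm[5:10], perm[10:]])
            rejections += p < 0.05
        assert abs(rejections / n_draws - 0.05) <= 0.02

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestSweep:
    def test_single_case_fixed_grid_has_nine_results(self, default_cohort):
        from suvseg import delineate_cases

        grid = [g for g in default_grids() if g.family == "fixed"]
        results = delineate_cases(default_cohort[:1], grid)
        assert len(results) == 9

    def test_default_grids_yield_43_summaries(self, default_cohort):
        results, summaries = sweep(default_cohort, default_grids())
        assert len(results) == 50 * 43
        assert len(summaries) == 43
        frame = summaries_frame(summaries)
        assert np.allclose(frame["r_squared"], frame["r"] ** 2)

    def test_sweep_rows_match_single_segmentations(self, default_cohort):
        from suvseg import delineate_cases, segment_fixed, segment_isocontour

        case = default_cohort[0]
        results = delineate_cases(default_cohort[:2], default_grids())
        frame = results_frame(results)
        row = frame[
            (frame.case_id == case.case_id)
            & (frame.method == "fixed")
            & (frame.level == 4.0)
        ].iloc[0]
        assert row.n_voxels == segment_fixed(case.pet, case.voi, 4.0).n_voxels
        iso = frame[
            (frame.case_id == case.case_id)
            & (frame.method == "isocontour")
            & (frame.level == 0.55)
        ].iloc[0]
        assert iso.n_voxels == segment_isocontour(case.pet, case.voi, 0.55).n_voxels

    def test_sweep_is_deterministic(self, default_cohort):
        r1, s1 = sweep(default_cohort[:6], default_grids())
        r2, s2 = sweep(default_cohort[:6], default_grids())
        assert results_frame(r1).equals(results_frame(r2))
        assert summaries_frame(s1).equals(summaries_frame(s2))

    def test_grid_levels_must_increase(self):
        with pytest.raises(ValueError):
            MethodGrid("fixed", (4.0, 3.0))


def _summary(method, level, r):
    return AgreementSummary(method, level, "spearman", r, r * r, 0.001, 0.0, (0.0, 0.0), 50)


class TestRanking:
    def test_single_summary_is_its_own_best(self):
        s = _summary("fixed", 4.0, 0.8)
        ranking = rank_methods([s])
        assert ranking["fixed"] is s and ranking["overall"] is s

    def test_argmax_r(self):
        summaries = [
            _summary("fixed", 2.5, 0.3),
            _summary("fixed", 4.0, 0.9),
            _summary("fixed", 5.0, 0.5),
        ]
        assert rank_methods(summaries)["fixed"].level == 4.0

    def test_ties_break_toward_lower_level(self):
        summaries = [_summary("fixed", 3.0, 0.9), _summary("fixed", 4.0, 0.9)]
        assert rank_methods(summaries)["fixed"].level == 3.0


class TestBackwardsSummary:
    def test_hand_computed_spread(self, default_cohort):
        from suvseg import backwards_summary_from_volumes

        rng = np.random.default_rng(8)
        reapplied = rng.uniform(1, 20, 10)
        ref = reapplied + rng.normal(0, 1, 10)
        summary = backwards_summary_from_volumes([4.0, 6.0], reapplied, ref)
        assert summary.mean_threshold == pytest.approx(5.0)
        assert summary.sd_threshold == pytest.approx(np.sqrt(2.0))
        assert summary.cov_percent == pytest.approx(28.28, abs=0.01)

    def test_achieved_volumes_within_one_voxel_of_target(self, default_cohort):
        results = solve_backwards(default_cohort[:10])
        for case, res in zip(default_cohort[:10], results):
            vv = case.pet.voxel_volume_ml
            assert abs(res.achieved_volume_ml - res.target_volume_ml) <= vv

    def test_degenerate_identical_cases_flagged(self, default_cohort):
        from suvseg import backwards_summary_from_volumes

        ref = [c.ct_reference_volume_ml for c in default_cohort[:6]]
        summary = backwards_summary_from_volumes([5.0] * 6, [2.0] * 6, ref)
        assert summary.reapplied_agreement is None
        assert "undefined" in summary.error

    def test_reapplied_mean_threshold_not_better_than_best_fixed(self, default_cohort):
        _, summaries = sweep(default_cohort, default_grids())
        fixed = [s for s in summaries if s.method == "fixed"]
        best_fixed_r = max(s.r for s in fixed)
        summary = backwards_summary(default_cohort, solve_backwards(default_cohort))
        grid_levels = [s.level for s in fixed]
        if min(grid_levels) <= summary.mean_threshold <= max(grid_levels):
            assert summary.reapplied_agreement.r <= best_fixed_r
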