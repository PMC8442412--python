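import math

import numpy as np
import pytest

from kickcut.cutpoint import (
    DegenerateGroupError,
    GroupStats,
    IndexBasis,
    InseparableGroupsError,
    IntersectionMethod,
    LevelDecision,
    ValidityIndices,
    candidate_levels,
    empirical_validity,
    fit_group_stats,
    gaussian_intersection,
    intersection_oracle,
    model_validity,
    round_half_up,
    select_level,
)
from kickcut.data import AthleteRole, Gender, HitType, WeightClass
from kickcut.simulate import SimulationSpec, StratumSpec, generate_dataset

# frozen by the grid-search oracle (step 1e-4) before the closed form was
# built: intersection of N(24.6, 7.17) and N(13.6, 1.88) between the means
MEN_U58_GROUPWISE_CROSSING = 17.2324
PHI_2_5 = 0.9937903346742238  # standard normal CDF at 2.5


def vi(accuracy, sensitivity=0.0, specificity=0.0):
    return ValidityIndices(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        basis=IndexBasis.MODEL,
    )


class TestFitGroupStats:
    def test_hand_computable(self):
        stats = fit_group_stats([10, 12, 14])
        assert stats.n == 3
        assert stats.mean == 12
        assert stats.sd == pytest.approx(2.0)

    def test_closed_form(self):
        stats = fit_group_stats([13, 15, 17, 19, 21])
        assert stats.mean == 17
        assert stats.sd == pytest.approx(math.sqrt(10))

    def test_too_few_values(self):
        with pytest.raises(DegenerateGroupError):
            fit_group_stats([5.0])

    def test_zero_variance(self):
        with pytest.raises(DegenerateGroupError):
            fit_group_stats([7.0, 7.0, 7.0])

    def test_simulation_consistency(self):
        # 10k draws from the bundled men's U58 scoring stratum parameters
        stratum = StratumSpec(
            gender=Gender.MEN,
            weight_class=WeightClass.U58,
            athlete_role=AthleteRole.WINNER,
            hit_type=HitType.SCORING,
            n=10_000,
            mean=24.6,
            sd=7.17,
        )
        spec = SimulationSpec(strata=(stratum,), winner_shift=0.0, seed=1)
        ds = generate_dataset(spec)
        stats = fit_group_stats([ev.impact for ev in ds])
        assert abs(stats.mean - 24.6) < 0.2


class TestGaussianIntersection:
    def test_equal_sd_midpoint(self):
        sol = gaussian_intersection(GroupStats(10, 20.0, 2.0), GroupStats(10, 10.0, 2.0))
        assert sol.cutoff == 15.0
        assert sol.method is IntersectionMethod.EQUAL_VARIANCE_MIDPOINT

    def test_groupwise_crossing_matches_frozen_oracle(self):
        sol = gaussian_intersection(
            GroupStats(100, 24.6, 7.17), GroupStats(100, 13.6, 1.88)
        )
        assert sol.method is IntersectionMethod.QUADRATIC
        assert sol.cutoff == pytest.approx(MEN_U58_GROUPWISE_CROSSING, abs=1e-4)
        assert 13.6 < sol.cutoff < 24.6

    def test_equal_means_not_separable(self):
        with pytest.raises(InseparableGroupsError):
            gaussian_intersection(GroupStats(10, 15.0, 2.0), GroupStats(10, 15.0, 4.0))

    def test_density_equality_at_cutoff(self):
        hi, lo = GroupStats(50, 22.0, 5.0), GroupStats(80, 14.0, 2.5)
        sol = gaussian_intersection(hi, lo)
        assert hi.pdf(sol.cutoff) == pytest.approx(lo.pdf(sol.cutoff), rel=1e-9)

    def test_label_swap_symmetry(self):
        hi, lo = GroupStats(50, 22.0, 5.0), GroupStats(80, 14.0, 2.5)
        assert gaussian_intersection(hi, lo).cutoff == pytest.approx(
            gaussian_intersection(lo, hi).cutoff, rel=1e-12
        )

    def test_both_roots_reported(self):
        sol = gaussian_intersection(GroupStats(50, 22.0, 5.0), GroupStats(80, 14.0, 2.5))
        assert len(sol.all_roots) == 2
        assert sol.cutoff in sol.all_roots

    def test_no_between_root_raises_without_fallback(self):
        # narrow lo density dominates over the whole (10, 10.5) interval
        hi, lo = GroupStats(50, 10.5, 5.0), GroupStats(50, 10.0, 1.0)
        with pytest.raises(InseparableGroupsError):
            gaussian_intersection(hi, lo)

    def test_midpoint_fallback(self):
        hi, lo = GroupStats(50, 10.5, 5.0), GroupStats(50, 10.0, 1.0)
        sol = gaussian_intersection(hi, lo, midpoint_fallback=True)
        assert sol.method is IntersectionMethod.MIDPOINT_FALLBACK
        assert sol.cutoff == pytest.approx(10.25)


class TestIntersectionOracle:
    def test_equal_sd_pair(self):
        cut = intersection_oracle(
            GroupStats(10, 20.0, 2.0), GroupStats(10, 10.0, 2.0), step=1e-4
        )
        assert cut == pytest.approx(15.0, abs=1e-4)

    def test_matches_closed_form(self):
        hi, lo = GroupStats(100, 24.6, 7.17), GroupStats(100, 13.6, 1.88)
        oracle = intersection_oracle(hi, lo, step=1e-4)
        assert abs(oracle - gaussian_intersection(hi, lo).cutoff) <= 1e-4

    def test_step_larger_than_gap(self):
        with pytest.raises(ValueError):
            intersection_oracle(GroupStats(10, 20.0, 2.0), GroupStats(10, 19.5, 2.0), step=1.0)

    def test_non_positive_step(self):
        with pytest.raises(ValueError):
            intersection_oracle(GroupStats(10, 20.0, 2.0), GroupStats(10, 10.0, 2.0), step=0)


class TestEmpiricalValidity:
    def test_perfect_separation(self):
        idx = empirical_validity([20, 22], [10, 12], 15.0)
        assert (idx.accuracy, idx.sensitivity, idx.specificity) == (1.0, 1.0, 1.0)
        assert idx.counts == (2, 0, 2, 0)

    def test_exhaustive_count(self):
        idx = empirical_validity([20, 14], [10, 16], 15.0)
        assert (idx.accuracy, idx.sensitivity, idx.specificity) == (0.5, 0.5, 0.5)
        assert idx.counts == (1, 1, 1, 1)

    def test_cutoff_below_everything(self):
        idx = empirical_validity([20, 22], [10, 12], 5.0)
        assert idx.sensitivity == 1.0
        assert idx.specificity == 0.0

    def test_accuracy_identity(self):
        idx = empirical_validity([18, 19, 25, 14], [12, 13, 21], 16.5)
        tp, fp, tn, fn = idx.counts
        assert idx.accuracy == (tp + tn) / (tp + fp + tn + fn)
        assert idx.sensitivity == tp / (tp + fn)
        assert idx.specificity == tn / (tn + fp)
        assert idx.basis is IndexBasis.EMPIRICAL

    def test_empty_group(self):
        with pytest.raises(ValueError):
            empirical_validity([], [10.0], 5.0)


class TestModelValidity:
    def test_sensitivity_half_at_hi_mean(self):
        idx = model_validity(GroupStats(10, 20.0, 2.0), GroupStats(10, 10.0, 2.0), 20.0)
        assert idx.sensitivity == 0.5

    def test_symmetric_equal_sd_case(self):
        idx = model_validity(GroupStats(7, 20.0, 2.0), GroupStats(7, 10.0, 2.0), 15.0)
        assert idx.sensitivity == pytest.approx(PHI_2_5, rel=1e-12)
        assert idx.specificity == pytest.approx(PHI_2_5, rel=1e-12)
        assert idx.accuracy == pytest.approx(PHI_2_5, rel=1e-12)
        assert idx.basis is IndexBasis.MODEL

    def test_accuracy_symmetric_about_midpoint(self):
        # equal sd, equal n: reflecting the cutoff about the mean midpoint
        # swaps sensitivity and specificity, leaving accuracy unchanged
        hi, lo = GroupStats(5, 20.0, 2.0), GroupStats(5, 10.0, 2.0)
        a1 = model_validity(hi, lo, 14.0)
        a2 = model_validity(hi, lo, 16.0)
        assert a1.accuracy == pytest.approx(a2.accuracy, rel=1e-12)
        assert a1.sensitivity == pytest.approx(a2.specificity, rel=1e-12)

    def test_n_weighting(self):
        hi, lo = GroupStats(30, 20.0, 2.0), GroupStats(10, 10.0, 3.0),
        idx = model_validity(hi, lo, 15.0)
        assert idx.accuracy == pytest.approx(
            (30 * idx.sensitivity + 10 * idx.specificity) / 40
        )


class TestCandidateLevels:
    def test_centered_window_around_18_8(self):
        assert candidate_levels(18.8, 1) == [18, 19, 20]

    def test_centered_window_around_16(self):
        assert candidate_levels(16.0, 1) == [15, 16, 17]

    def test_clipped_at_level_one(self):
        assert candidate_levels(1.2, 3) == [1, 2, 3, 4]

    def test_half_up_center(self):
        assert candidate_levels(18.5, 1) == [18, 19, 20]

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            candidate_levels(18.8, 0)

    @pytest.mark.parametrize("x, expected", [(2.5, 3), (18.8, 19), (16.0, 16), (1.2, 1)])
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected


class TestSelectLevel:
    def test_sensitivity_tie_break(self):
        # printed tied accuracies with differing sensitivities
        result = select_level(
            [(19, vi(0.496, 0.674)), (20, vi(0.496, 0.689))]
        )
        assert result.selected_level == 20
        assert result.tie_broken is True

    def test_plain_argmax(self):
        result = select_level(
            [(15, vi(0.525)), (16, vi(0.499)), (17, vi(0.485))]
        )
        assert result.selected_level == 15
        assert result.tie_broken is False

    def test_single_candidate(self):
        result = select_level([(17, vi(0.3))])
        assert result.selected_level == 17
        assert result.tie_broken is False

    def test_full_tie_picks_lower_level(self):
        result = select_level([(18, vi(0.5, 0.6)), (19, vi(0.5, 0.6))])
        assert result.selected_level == 18
        assert result.tie_broken is True

    def test_empty_candidates(self):
        with pytest.raises(ValueError):
            select_level([])


class TestLevelDecision:
    def test_selected_must_be_candidate(self):
        with pytest.raises(ValueError):
            LevelDecision(
                continuous_cutoff=18.8,
                candidates=((18, vi(0.5)),),
                selected_level=19,
                tie_broken=False,
            )
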