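"""Adaptive-capacity search-space analysis on the condition lines."""

import numpy as np
import pytest

from scnsync.search_space import (
    CONDITIONS,
    SearchSpaceConfig,
    adaptive_capacity,
    age_difference,
    build_point_sets,
    check_constraints,
    constrained_fractions,
    enumerate_line_points,
    unconstrained_fractions,
)
from scnsync.two_community import ConditionLines, all_condition_lines


def _line(intercept, r=0.8, D=1.0, condition="x", c2_offset=0.4):
    """ConditionLines with slope -1 and the given intercept for community 1
    (and intercept - c2_offset for community 2)."""
    return ConditionLines(
        condition=condition, r1=r, r2=r, D=D,
        C1=intercept * r, C2=(intercept - c2_offset) * r,
    )


class TestEnumerateLinePoints:
    def test_full_grid_retained_when_line_fits_window(self):
        K, L = enumerate_line_points(_line(5.0), 1)
        assert len(K) == 101
        assert np.allclose(L, 5.0 - K)

    def test_boundary_keeps_single_point(self):
        K, L = enumerate_line_points(_line(20.0), 1)
        assert len(K) == 1
        assert K[0] == pytest.approx(10.0)
        assert L[0] == pytest.approx(10.0)

    def test_points_satisfy_line_equation(self):
        lines = all_condition_lines()["young_LP"]
        for c in (1, 2):
            K, L = enumerate_line_points(lines, c)
            a, b = lines.slope(c), lines.intercept(c)
            assert np.allclose(K, a * L + b, atol=1e-9)
            assert np.all((L >= -5.0) & (L <= 10.0))

    def test_window_miss_raises(self):
        with pytest.raises(ValueError):
            enumerate_line_points(_line(200.0), 1)


class TestCapacityStatistics:
    def test_identical_points_zero_capacity(self):
        pts = {1: (2.0, 1.0), 2: (1.0, 0.0)}
        assert adaptive_capacity(pts, pts) == 0.0

    def test_hand_example_magnitude_convention(self):
        lp = {1: (2.0, 1.0), 2: (1.0, 0.0)}
        sp = {1: (5.0, -2.0), 2: (1.0, 0.0)}
        assert adaptive_capacity(lp, sp, "magnitude") == pytest.approx(4.0)

    def test_hand_example_plain_convention(self):
        lp = {1: (2.0, 1.0), 2: (1.0, 0.0)}
        sp = {1: (5.0, -2.0), 2: (1.0, 0.0)}
        assert adaptive_capacity(lp, sp, "plain") == pytest.approx(6.0)

    def test_symmetric_in_photoperiod_swap(self):
        lp = {1: (2.0, 1.0), 2: (0.5, -1.0)}
        sp = {1: (5.0, -2.0), 2: (3.0, 2.0)}
        for conv in ("plain", "magnitude"):
            assert adaptive_capacity(lp, sp, conv) == pytest.approx(
                adaptive_capacity(sp, lp, conv)
            )

    def test_age_difference_mirrors_capacity_formula(self):
        young = {1: (4.0, -1.0), 2: (3.0, 0.5)}
        old = {1: (2.5, -0.2), 2: (2.0, 0.1)}
        assert age_difference(young, old, "plain") == pytest.approx(
            1.5 + 0.8 + 1.0 + 0.4
        )


class TestCheckConstraints:
    def _config(self):
        cfg = {}
        for c in (1, 2):
            base = 0.2 if c == 1 else 0.0  # keeps community ordering consistent
            cfg[("young_SP", c)] = (6.0 + base, -3.0 - base)
            cfg[("young_LP", c)] = (4.0 + base, -2.0 - base)
            cfg[("old_SP", c)] = (5.0 + base, -2.5 - base)
            cfg[("old_LP", c)] = (3.0 + base, -1.5 - base)
        return cfg

    def test_satisfying_configuration_passes(self):
        flags = check_constraints(self._config())
        assert flags["young_above_old"] and flags["sp_above_lp"]
        assert flags["consistent_ordering"] and flags["all"]

    def test_inconsistent_community_ordering_fails_third_constraint(self):
        cfg = self._config()
        k, l = cfg[("old_LP", 1)]
        cfg[("old_LP", 1)] = (cfg[("old_LP", 2)][0] - 0.5, l)  # K1 < K2 here only
        flags = check_constraints(cfg)
        assert not flags["consistent_ordering"]
        assert not flags["all"]

    def test_equality_fails_strict_comparison(self):
        cfg = self._config()
        cfg[("young_SP", 1)] = cfg[("old_SP", 1)]
        assert not check_constraints(cfg)["young_above_old"]

    def test_missing_point_rejected(self):
        cfg = self._config()
        del cfg[("old_LP", 2)]
        with pytest.raises(ValueError):
            check_constraints(cfg)


class TestUnconstrainedFractions:
    def test_identical_ages_give_half_minus_ties(self):
        lines = {
            "young_LP": _line(4.0, condition="young_LP"),
            "young_SP": _line(8.0, condition="young_SP"),
            "old_LP": _line(4.0, condition="old_LP"),
            "old_SP": _line(8.0, condition="old_SP"),
        }
        cfg = SearchSpaceConfig(method="monte_carlo", mc_samples=200_000, seed=0)
        rep = unconstrained_fractions(lines, cfg)
        # ties broken as "not greater": fraction sits just below 1/2
        assert 0.40 < rep.fraction_old_exceeds_young <= 0.5

    def test_single_point_lines_are_deterministic(self):
        lines = {cond: _line(20.0, condition=cond, c2_offset=0.0) for cond in CONDITIONS}
        cfg = SearchSpaceConfig(method="monte_carlo", mc_samples=1000, seed=1)
        rep = unconstrained_fractions(lines, cfg)
        assert rep.fraction_old_exceeds_young in (0.0, 1.0)
        assert rep.fraction_diff_larger_LP in (0.0, 1.0)

    def test_enumeration_matches_monte_carlo_on_coarse_grid(self):
        cfg_mc = SearchSpaceConfig(
            method="monte_carlo", mc_samples=400_000, K_step=0.5, seed=3
        )
        cfg_enum = SearchSpaceConfig(method="enumerate", K_step=0.5)
        mc = unconstrained_fractions(config=cfg_mc)
        exact = unconstrained_fractions(config=cfg_enum)
        se = 3.0 / np.sqrt(cfg_mc.mc_samples)  # 3 binomial standard errors
        assert abs(mc.fraction_old_exceeds_young - exact.fraction_old_exceeds_young) < 3 * se
        assert abs(mc.fraction_diff_larger_LP - exact.fraction_diff_larger_LP) < 3 * se

    def test_community_swap_invariance_exact(self):
        # swapping community labels in every condition swaps (r1, r2)
        cfg = SearchSpaceConfig(method="enumerate", K_step=0.5)
        swapped = {
            cond: ConditionLines(
                condition=cond, r1=ln.r2, r2=ln.r1, D=ln.D, C1=ln.C2, C2=ln.C1
            )
            for cond, ln in all_condition_lines().items()
        }
        a = unconstrained_fractions(config=cfg)
        b = unconstrained_fractions(swapped, cfg)
        assert a.fraction_old_exceeds_young == pytest.approx(
            b.fraction_old_exceeds_young, abs=1e-12
        )
        assert a.fraction_diff_larger_LP == pytest.approx(
            b.fraction_diff_larger_LP, abs=1e-12
        )


class TestConstrainedFractions:
    def _loose_lines(self):
        """Synthetic condition geometry with a high constraint pass rate."""
        return {
            "young_SP": _line(8.0, condition="young_SP"),
            "young_LP": _line(4.0, condition="young_LP"),
            "old_SP": _line(6.0, condition="old_SP"),
            "old_LP": _line(2.0, condition="old_LP"),
        }

    def test_factorized_sampler_matches_naive_rejection(self):
        lines = self._loose_lines()
        cfg = SearchSpaceConfig(
            K_step=0.5, mc_samples=400_000, survivor_target=20_000, seed=7
        )
        fac = constrained_fractions(lines, cfg, method="factorized")
        naive = constrained_fractions(lines, cfg, method="rejection")
        assert fac.n_survivors >= 1000 and naive.n_survivors >= 1000
        for attr in (
            "constrained_fraction_old_exceeds_young",
            "constrained_fraction_diff_larger_LP",
        ):
            a, b = getattr(fac, attr), getattr(naive, attr)
            se = np.sqrt(max(a * (1 - a), 0.01) / min(fac.n_survivors, naive.n_survivors))
            assert abs(a - b) < 4 * se
        assert fac.constraint_pass_rate == pytest.approx(
            naive.constraint_pass_rate, rel=0.5
        )

    def test_forced_constraints_make_old_capacity_never_win(self):
        # old lines far below young, SP far above LP: survivors exist and the
        # young capacity dominates by construction
        lines = {
            "young_SP": _line(9.5, condition="young_SP"),
            "young_LP": _line(2.5, condition="young_LP"),
            "old_SP": _line(5.5, condition="old_SP"),
            "old_LP": _line(4.5, condition="old_LP"),
        }
        cfg = SearchSpaceConfig(K_step=0.5, survivor_target=5_000, seed=2)
        rep = constrained_fractions(lines, cfg)
        assert rep.n_survivors > 0
        assert rep.constrained_fraction_old_exceeds_young == 0.0

    def test_fraction_and_complement_sum_to_one_up_to_ties(self):
        lines = self._loose_lines()
        cfg = SearchSpaceConfig(K_step=0.5, survivor_target=20_000, seed=11)
        rep = constrained_fractions(lines, cfg)
        assert 0.0 <= rep.constrained_fraction_diff_larger_LP <= 1.0
        assert rep.constraint_pass_rate <= 1.0

    def test_empty_admissible_set_raises(self):
        # young lines far below old lines: K_young > K_old and
        # |L|_young > |L|_old can never hold simultaneously on these segments
        lines = {
            "young_SP": _line(2.0, condition="young_SP", c2_offset=0.0),
            "young_LP": _line(1.5, condition="young_LP", c2_offset=0.0),
            "old_SP": _line(12.0, condition="old_SP", c2_offset=0.0),
            "old_LP": _line(11.0, condition="old_LP", c2_offset=0.0),
        }
        with pytest.raises(ValueError):
            constrained_fractions(lines, SearchSpaceConfig(K_step=0.5, seed=0))
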