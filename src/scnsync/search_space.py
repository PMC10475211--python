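"""Search-space analysis of adaptive capacity on the condition K–L lines.

The data pin each experimental condition (age × photoperiod) down to a line
of admissible couplings per community, not a point. This module asks what
follows for *any* choice of points on those lines. A solution configuration
picks one (K, L) per condition per community, with K on a regular grid over
[0, 10] (step 0.1) and the implied L kept inside [−5, 10].

Two summary statistics are compared across configurations:

* Total adaptive capacity of an age group — how far its couplings move
  between photoperiods: ΔK1 + ΔL1 + ΔK2 + ΔL2 with ΔX = |X_SP − X_LP|.
* Young–old coupling difference within a photoperiod:
  Σ_c |K_young − K_old| + |L_young − L_old|.

Reported fractions: (1) how often the old capacity strictly exceeds the
young capacity, and (2) how often the young–old difference is larger in long
than in short photoperiod — first over all configurations, then over the
subset surviving three biological constraints: couplings (K and |L|) higher
in young than old, higher in SP than LP, and a consistent ordering of
community 1 versus community 2 across all four conditions.

The constrained set is vanishingly rare under the product measure (~4·10⁻⁶ %
of configurations), so it is sampled by an exact factorization instead of
naive rejection: constraints 1 and 2 couple conditions only *within* a
community, so each community's admissible 4-tuples of grid points are
enumerated exhaustively, and uniform pairing of the two communities' tuples
with rejection on the cross-community constraint 3 reproduces the
conditional distribution exactly.

The difference convention for L is configurable: ``"plain"`` (default)
compares signed couplings, ΔL = |L_a − L_b|; ``"magnitude"`` compares
strengths, ΔL = ||L_a| − |L_b||. The constraints always compare |L|
magnitudes — the signed variant is infeasible on negatively sloped lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scnsync.two_community import ConditionLines, all_condition_lines, point_on_line

__all__ = [
    "CONDITIONS",
    "SearchSpaceConfig",
    "LinePointSets",
    "CapacityReport",
    "enumerate_line_points",
    "build_point_sets",
    "adaptive_capacity",
    "age_difference",
    "unconstrained_fractions",
    "check_constraints",
    "constrained_fractions",
    "analyze_search_space",
]

#: Condition order: (age, photoperiod) as young/old × LP/SP.
CONDITIONS = ("young_LP", "young_SP", "old_LP", "old_SP")
_COMMUNITIES = (1, 2)


@dataclass(frozen=True)
class SearchSpaceConfig:
    """Grid, sampling and convention choices for the search-space analysis."""

    K_min: float = 0.0
    K_max: float = 10.0
    K_step: float = 0.1
    L_min: float = -5.0
    L_max: float = 10.0
    method: str = "monte_carlo"  # or "enumerate" (exact, small grids only)
    mc_samples: int = 10_000_000
    survivor_target: int = 1_000_000
    max_constrained_draws: int = 200_000_000
    seed: int = 0
    delta_convention: str = "plain"  # or "magnitude"

    def __post_init__(self):
        if self.K_step <= 0:
            raise ValueError("K_step must be positive")
        if self.method not in ("monte_carlo", "enumerate"):
            raise ValueError("method must be 'monte_carlo' or 'enumerate'")
        if self.delta_convention not in ("plain", "magnitude"):
            raise ValueError("delta_convention must be 'plain' or 'magnitude'")

    @property
    def K_grid(self) -> np.ndarray:
        n = int(round((self.K_max - self.K_min) / self.K_step))
        return np.round(self.K_min + self.K_step * np.arange(n + 1), 10)


@dataclass(frozen=True)
class CapacityReport:
    """Headline fractions of the search-space analysis (all in [0, 1])."""

    fraction_old_exceeds_young: float | None = None
    fraction_diff_larger_LP: float | None = None
    constrained_fraction_old_exceeds_young: float | None = None
    constrained_fraction_diff_larger_LP: float | None = None
    constraint_pass_rate: float | None = None
    n_samples: int = 0
    n_survivors: int = 0
    method: str = ""
    seed: int | None = None
    delta_convention: str = "plain"

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def enumerate_line_points(
    lines: ConditionLines, community: int, config: SearchSpaceConfig = SearchSpaceConfig()
) -> tuple:
    """Grid points (K, L) on one community's line inside the search window.

    K runs over the grid; L follows from the line equation; points with L
    outside [L_min, L_max] are discarded. Returns ascending-K arrays.
    """
    K = config.K_grid
    _, L0 = point_on_line(lines, community, K=0.0)
    slope_inv = lines.slope(community)
    # L(K) from the line: K = a·L + b  =>  L = (b − K)/(−a)·(−1)... use direct form
    r_self = lines.r1 if community == 1 else lines.r2
    r_other = lines.r2 if community == 1 else lines.r1
    C = lines.C1 if community == 1 else lines.C2
    L = (C * lines.D - K * r_self) / r_other
    keep = (L >= config.L_min) & (L <= config.L_max)
    if not keep.any():
        raise ValueError(
            f"line {lines.condition!r} community {community} misses the search window"
        )
    return K[keep], L[keep]


@dataclass(frozen=True)
class LinePointSets:
    """Grid points for every (condition, community) line."""

    points: dict  # (condition, community) -> (K array, L array)
    config: SearchSpaceConfig

    def n_points(self, condition: str, community: int) -> int:
        return len(self.points[(condition, community)][0])


def build_point_sets(
    lines_by_condition: dict | None = None,
    config: SearchSpaceConfig = SearchSpaceConfig(),
) -> LinePointSets:
    """Enumerate grid points on all eight condition × community lines."""
    if lines_by_condition is None:
        lines_by_condition = all_condition_lines()
    missing = set(CONDITIONS) - set(lines_by_condition)
    if missing:
        raise ValueError(f"missing condition lines: {sorted(missing)}")
    pts = {
        (cond, c): enumerate_line_points(lines_by_condition[cond], c, config)
        for cond in CONDITIONS
        for c in _COMMUNITIES
    }
    return LinePointSets(points=pts, config=config)


# ---------------------------------------------------------------------------
# Difference statistics
# ---------------------------------------------------------------------------

def _delta_L(La, Lb, convention: str):
    if convention == "magnitude":
        return np.abs(np.abs(La) - np.abs(Lb))
    return np.abs(La - Lb)


def _pair_difference(Ka, La, Kb, Lb, convention: str):
    return np.abs(Ka - Kb) + _delta_L(La, Lb, convention)


def adaptive_capacity(points_LP: dict, points_SP: dict, convention: str = "plain"):
    """Total adaptive capacity between photoperiods for one age group.

    ``points_LP`` / ``points_SP`` map community -> (K, L) (scalars or
    aligned arrays). Capacity = Σ_c ΔK_c + ΔL_c, symmetric in LP ↔ SP.
    """
    if set(points_LP) != set(points_SP):
        raise ValueError("LP and SP configurations must cover the same communities")
    total = 0.0
    for c in points_LP:
        K_lp, L_lp = points_LP[c]
        K_sp, L_sp = points_SP[c]
        total = total + _pair_difference(K_sp, L_sp, K_lp, L_lp, convention)
    return total


def age_difference(points_young: dict, points_old: dict, convention: str = "plain"):
    """Summed young-vs-old coupling difference within one photoperiod."""
    if set(points_young) != set(points_old):
        raise ValueError("young and old configurations must cover the same communities")
    total = 0.0
    for c in points_young:
        Ky, Ly = points_young[c]
        Ko, Lo = points_old[c]
        total = total + _pair_difference(Ky, Ly, Ko, Lo, convention)
    return total


# ---------------------------------------------------------------------------
# Unconstrained fractions
# ---------------------------------------------------------------------------

def _draw_indices(point_sets: LinePointSets, n: int, rng) -> dict:
    draws = {}
    for key, (K, L) in point_sets.points.items():
        idx = rng.integers(0, len(K), n)
        draws[key] = (K[idx], L[idx])
    return draws


def _capacity_arrays(draws, convention):
    capY = adaptive_capacity(
        {c: draws[("young_LP", c)] for c in _COMMUNITIES},
        {c: draws[("young_SP", c)] for c in _COMMUNITIES},
        convention,
    )
    capO = adaptive_capacity(
        {c: draws[("old_LP", c)] for c in _COMMUNITIES},
        {c: draws[("old_SP", c)] for c in _COMMUNITIES},
        convention,
    )
    dLP = age_difference(
        {c: draws[("young_LP", c)] for c in _COMMUNITIES},
        {c: draws[("old_LP", c)] for c in _COMMUNITIES},
        convention,
    )
    dSP = age_difference(
        {c: draws[("young_SP", c)] for c in _COMMUNITIES},
        {c: draws[("old_SP", c)] for c in _COMMUNITIES},
        convention,
    )
    return capY, capO, dLP, dSP


def _pairwise_component(point_sets, cond_a, cond_b, community, convention):
    """All |ΔK| + ΔL values between two conditions' grids for one community."""
    Ka, La = point_sets.points[(cond_a, community)]
    Kb, Lb = point_sets.points[(cond_b, community)]
    return _pair_difference(
        Ka[:, None], La[:, None], Kb[None, :], Lb[None, :], convention
    ).ravel()


_ENUM_LIMIT = 40_000_000  # max joint-array length for exact enumeration


def _exact_exceedance(a_parts, b_parts):
    """P(sum(A) > sum(B)) for independent uniform component choices.

    a_parts/b_parts are the per-community component value arrays; the joint
    sums are formed as full cross products, so this is exact but only
    tractable on reduced grids.
    """
    a = (a_parts[0][:, None] + a_parts[1][None, :]).ravel()
    b = (b_parts[0][:, None] + b_parts[1][None, :]).ravel()
    if len(a) * 1.0 * len(b) > 1e18:  # pragma: no cover - guarded earlier
        raise MemoryError
    b_sorted = np.sort(b)
    counts = np.searchsorted(b_sorted, a, side="left")
    return float(counts.sum() / (len(a) * len(b)))


def unconstrained_fractions(
    lines_by_condition: dict | None = None,
    config: SearchSpaceConfig = SearchSpaceConfig(),
) -> CapacityReport:
    """Fractions over all solution configurations (no constraints).

    ``method="monte_carlo"`` draws ``mc_samples`` independent 8-point
    configurations. ``method="enumerate"`` computes both fractions exactly
    from the per-community component distributions and their cross products;
    it refuses grids whose joint enumeration would exceed memory — use it on
    reduced grids (e.g. K_step = 0.5) as an oracle for the sampler.
    """
    point_sets = build_point_sets(lines_by_condition, config)
    conv = config.delta_convention
    if config.method == "enumerate":
        cap_parts = {}
        for age in ("young", "old"):
            parts = [
                _pairwise_component(point_sets, f"{age}_LP", f"{age}_SP", c, conv)
                for c in _COMMUNITIES
            ]
            if len(parts[0]) * len(parts[1]) > _ENUM_LIMIT:
                raise ValueError(
                    "grid too fine for exact enumeration; use method='monte_carlo' "
                    "or a coarser K_step"
                )
            cap_parts[age] = parts
        f1 = _exact_exceedance(cap_parts["old"], cap_parts["young"])
        diff_parts = {}
        for pp in ("LP", "SP"):
            parts = [
                _pairwise_component(point_sets, f"young_{pp}", f"old_{pp}", c, conv)
                for c in _COMMUNITIES
            ]
            if len(parts[0]) * len(parts[1]) > _ENUM_LIMIT:
                raise ValueError(
                    "grid too fine for exact enumeration; use method='monte_carlo' "
                    "or a coarser K_step"
                )
            diff_parts[pp] = parts
        f2 = _exact_exceedance(diff_parts["LP"], diff_parts["SP"])
        n = 0
    else:
        rng = np.random.default_rng(config.seed)
        n = config.mc_samples
        draws = _draw_indices(point_sets, n, rng)
        capY, capO, dLP, dSP = _capacity_arrays(draws, conv)
        f1 = float(np.mean(capO > capY))
        f2 = float(np.mean(dLP > dSP))
    return CapacityReport(
        fraction_old_exceeds_young=f1,
        fraction_diff_larger_LP=f2,
        n_samples=n,
        method=config.method,
        seed=config.seed,
        delta_convention=conv,
    )


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------

def check_constraints(configuration: dict) -> dict:
    """Evaluate the three biological constraints on one 8-point configuration.

    ``configuration`` maps (condition, community) -> (K, L). All inequalities
    are strict; L enters constraints 1 and 2 through its magnitude |L|.
    Returns per-constraint flags and the conjunction under ``"all"``.
    """
    missing = {
        (cond, c) for cond in CONDITIONS for c in _COMMUNITIES
    } - set(configuration)
    if missing:
        raise ValueError(f"configuration missing points: {sorted(missing)}")
    K = {k: np.asarray(v[0], float) for k, v in configuration.items()}
    Labs = {k: np.abs(np.asarray(v[1], float)) for k, v in configuration.items()}
    L = {k: np.asarray(v[1], float) for k, v in configuration.items()}

    young_above_old = True
    for c in _COMMUNITIES:
        for pp in ("LP", "SP"):
            young_above_old = young_above_old & (
                (K[(f"young_{pp}", c)] > K[(f"old_{pp}", c)])
                & (Labs[(f"young_{pp}", c)] > Labs[(f"old_{pp}", c)])
            )
    sp_above_lp = True
    for c in _COMMUNITIES:
        for age in ("young", "old"):
            sp_above_lp = sp_above_lp & (
                (K[(f"{age}_SP", c)] > K[(f"{age}_LP", c)])
                & (Labs[(f"{age}_SP", c)] > Labs[(f"{age}_LP", c)])
            )
    consistent = True
    ref_K = ref_L = None
    for cond in CONDITIONS:
        sK = np.sign(K[(cond, 1)] - K[(cond, 2)])
        sL = np.sign(L[(cond, 1)] - L[(cond, 2)])
        if ref_K is None:
            ref_K, ref_L = sK, sL
        consistent = consistent & (sK == ref_K) & (sL == ref_L) & (ref_K != 0) & (ref_L != 0)
    return {
        "young_above_old": young_above_old,
        "sp_above_lp": sp_above_lp,
        "consistent_ordering": consistent,
        "all": young_above_old & sp_above_lp & consistent,
    }


def _admissible_tuples(point_sets: LinePointSets, community: int) -> np.ndarray:
    """Exhaustively enumerate 4-tuples satisfying constraints 1 & 2 within a community.

    Index order follows CONDITIONS. Constraints 1 and 2 compare only points
    of the same community, so this enumeration is exact and independent of
    the other community.
    """
    K = [point_sets.points[(cond, community)][0] for cond in CONDITIONS]
    A = [np.abs(point_sets.points[(cond, community)][1]) for cond in CONDITIONS]

    def bx(i, arr):
        shape = [1, 1, 1, 1]
        shape[i] = -1
        return arr.reshape(shape)

    # indices: 0=young_LP, 1=young_SP, 2=old_LP, 3=old_SP
    ok = (
        (bx(0, K[0]) > bx(2, K[2])) & (bx(0, A[0]) > bx(2, A[2]))  # young > old, LP
        & (bx(1, K[1]) > bx(3, K[3])) & (bx(1, A[1]) > bx(3, A[3]))  # young > old, SP
        & (bx(1, K[1]) > bx(0, K[0])) & (bx(1, A[1]) > bx(0, A[0]))  # SP > LP, young
        & (bx(3, K[3]) > bx(2, K[2])) & (bx(3, A[3]) > bx(2, A[2]))  # SP > LP, old
    )
    return np.argwhere(ok)


def constrained_fractions(
    lines_by_condition: dict | None = None,
    config: SearchSpaceConfig = SearchSpaceConfig(),
    method: str = "factorized",
) -> CapacityReport:
    """Fractions over constraint-surviving configurations.

    ``method="factorized"`` (default): enumerate each community's admissible
    4-tuples under constraints 1–2 exactly, then draw uniform tuple pairs and
    reject on constraint 3 until ``survivor_target`` survivors are collected
    (or ``max_constrained_draws`` pairings are exhausted, with the achieved
    survivor count reported). Statistically identical to naive rejection from
    the full product measure, because constraints 1–2 factorize by community.

    ``method="rejection"``: naive rejection from full 8-point draws — orders
    of magnitude slower, retained as the oracle for equivalence tests on
    coarse grids.
    """
    point_sets = build_point_sets(lines_by_condition, config)
    conv = config.delta_convention
    rng = np.random.default_rng(config.seed)

    if method == "rejection":
        survivors_needed = config.survivor_target
        batch = max(min(config.mc_samples, 2_000_000), 1000)
        n_drawn = 0
        surv_capY, surv_capO, surv_dLP, surv_dSP = [], [], [], []
        n_surv = 0
        while n_surv < survivors_needed and n_drawn < config.max_constrained_draws:
            draws = _draw_indices(point_sets, batch, rng)
            flags = check_constraints(draws)
            mask = flags["all"]
            n_drawn += batch
            if mask.any():
                capY, capO, dLP, dSP = _capacity_arrays(draws, conv)
                surv_capY.append(capY[mask])
                surv_capO.append(capO[mask])
                surv_dLP.append(dLP[mask])
                surv_dSP.append(dSP[mask])
                n_surv += int(mask.sum())
        if n_surv == 0:
            raise ValueError(
                f"no constraint-surviving configurations in {n_drawn} draws"
            )
        capY = np.concatenate(surv_capY)
        capO = np.concatenate(surv_capO)
        dLP = np.concatenate(surv_dLP)
        dSP = np.concatenate(surv_dSP)
        pass_rate = n_surv / n_drawn
        n_samples = n_drawn
    elif method == "factorized":
        tup = {c: _admissible_tuples(point_sets, c) for c in _COMMUNITIES}
        for c in _COMMUNITIES:
            if len(tup[c]) == 0:
                raise ValueError(
                    f"community {c}: no 4-tuples satisfy constraints 1-2 on this grid"
                )
        # per-community (K, L) arrays aligned with the tuple lists
        vals = {
            c: {
                cond: (
                    point_sets.points[(cond, c)][0][tup[c][:, i]],
                    point_sets.points[(cond, c)][1][tup[c][:, i]],
                )
                for i, cond in enumerate(CONDITIONS)
            }
            for c in _COMMUNITIES
        }
        n1, n2 = len(tup[1]), len(tup[2])
        surv = {"capY": [], "capO": [], "dLP": [], "dSP": []}
        n_surv = 0
        n_drawn = 0
        batch = 2_000_000
        while n_surv < config.survivor_target and n_drawn < config.max_constrained_draws:
            i1 = rng.integers(0, n1, batch)
            i2 = rng.integers(0, n2, batch)
            n_drawn += batch
            ok = np.ones(batch, dtype=bool)
            ref_K = ref_L = None
            for cond in CONDITIONS:
                K1, L1 = vals[1][cond][0][i1], vals[1][cond][1][i1]
                K2, L2 = vals[2][cond][0][i2], vals[2][cond][1][i2]
                sK, sL = np.sign(K1 - K2), np.sign(L1 - L2)
                if ref_K is None:
                    ref_K, ref_L = sK, sL
                ok &= (sK == ref_K) & (sL == ref_L) & (ref_K != 0) & (ref_L != 0)
            i1s, i2s = i1[ok], i2[ok]
            if len(i1s) == 0:
                continue
            draws = {}
            for cond in CONDITIONS:
                draws[(cond, 1)] = (vals[1][cond][0][i1s], vals[1][cond][1][i1s])
                draws[(cond, 2)] = (vals[2][cond][0][i2s], vals[2][cond][1][i2s])
            capY, capO, dLP, dSP = _capacity_arrays(draws, conv)
            surv["capY"].append(capY)
            surv["capO"].append(capO)
            surv["dLP"].append(dLP)
            surv["dSP"].append(dSP)
            n_surv += len(i1s)
        if n_surv == 0:
            raise ValueError(
                f"no survivors after {n_drawn} tuple pairings "
                f"(admissible tuples: {n1} and {n2})"
            )
        capY = np.concatenate(surv["capY"])
        capO = np.concatenate(surv["capO"])
        dLP = np.concatenate(surv["dLP"])
        dSP = np.concatenate(surv["dSP"])
        # pass rate relative to the unconstrained product measure
        n_grid = {
            c: np.prod([point_sets.n_points(cond, c) for cond in CONDITIONS])
            for c in _COMMUNITIES
        }
        tuple_rate = (n1 / n_grid[1]) * (n2 / n_grid[2])
        pass_rate = tuple_rate * (n_surv / n_drawn)
        n_samples = n_drawn
    else:
        raise ValueError("method must be 'factorized' or 'rejection'")

    return CapacityReport(
        constrained_fraction_old_exceeds_young=float(np.mean(capO > capY)),
        constrained_fraction_diff_larger_LP=float(np.mean(dLP > dSP)),
        constraint_pass_rate=float(pass_rate),
        n_samples=int(n_samples),
        n_survivors=int(n_surv),
        method=f"constrained_{method}",
        seed=config.seed,
        delta_convention=conv,
    )


def analyze_search_space(
    lines_by_condition: dict | None = None,
    config: SearchSpaceConfig = SearchSpaceConfig(),
) -> CapacityReport:
    """Unconstrained and constrained fractions in one report."""
    unc = unconstrained_fractions(lines_by_condition, config)
    con = constrained_fractions(lines_by_condition, config)
    return CapacityReport(
        fraction_old_exceeds_young=unc.fraction_old_exceeds_young,
        fraction_diff_larger_LP=unc.fraction_diff_larger_LP,
        constrained_fraction_old_exceeds_young=con.constrained_fraction_old_exceeds_young,
        constrained_fraction_diff_larger_LP=con.constrained_fraction_diff_larger_LP,
        constraint_pass_rate=con.constraint_pass_rate,
        n_samples=unc.n_samples,
        n_survivors=con.n_survivors,
        method=f"{unc.method}+{con.method}",
        seed=config.seed,
        delta_convention=config.delta_convention,
    )
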