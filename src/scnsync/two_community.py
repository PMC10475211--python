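"""Two-community self-consistency: the linear K–L relation per condition.

In the two-community noisy Kuramoto model at stationarity, each community's
order parameter satisfies

    r1 = V(C1),   C1 = (K1·r1 + L1·r2)/D,
    r2 = V(C2),   C2 = (K2·r2 + L2·r1)/D,

with V(x) = I₁(x)/I₀(x). Since C_c is fixed by the measured r_c alone, the
admissible couplings of community c form a straight line in the (L, K) plane:

    K_c = a_c·L_c + b_c,   a_c = −r_other/r_c,   b_c = C_c·D/r_c.

The slope is strictly negative: stronger between-community input must be
traded against weaker within-community coupling to hold coherence fixed. The
data determine the line, not a point on it — the search-space analysis in
:mod:`scnsync.search_space` quantifies what can still be concluded.

The noise strength is fixed at D = 1, the value the one-community analysis
recovers across all experimental conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scnsync.one_community import bessel_ratio, solve_coherence_concentration

__all__ = [
    "ConditionLines",
    "SCN_ORDER_PARAMETERS",
    "condition_lines",
    "point_on_line",
    "all_condition_lines",
    "average_order_parameters",
]

#: Averaged order parameters (medial r1, lateral r2) per experimental
#: condition: young/old mice under long/short photoperiod, anterior and
#: posterior slices pooled.
SCN_ORDER_PARAMETERS = {
    "young_LP": (0.77, 0.81),
    "young_SP": (0.94, 0.94),
    "old_LP": (0.84, 0.77),
    "old_SP": (0.91, 0.90),
}


@dataclass(frozen=True)
class ConditionLines:
    """The two K–L lines implied by one condition's (r1, r2)."""

    condition: str
    r1: float
    r2: float
    D: float
    C1: float
    C2: float

    @property
    def slope1(self) -> float:
        return -self.r2 / self.r1

    @property
    def intercept1(self) -> float:
        return self.C1 * self.D / self.r1

    @property
    def slope2(self) -> float:
        return -self.r1 / self.r2

    @property
    def intercept2(self) -> float:
        return self.C2 * self.D / self.r2

    def slope(self, community: int) -> float:
        return self.slope1 if community == 1 else self.slope2

    def intercept(self, community: int) -> float:
        return self.intercept1 if community == 1 else self.intercept2

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "r1": self.r1,
            "r2": self.r2,
            "D": self.D,
            "C1": self.C1,
            "C2": self.C2,
            "slope1": self.slope1,
            "intercept1": self.intercept1,
            "slope2": self.slope2,
            "intercept2": self.intercept2,
        }


def condition_lines(
    r1: float, r2: float, D: float = 1.0, condition: str = ""
) -> ConditionLines:
    """Build both communities' K–L lines from measured (r1, r2).

    C_c solves V(C_c) = r_c to high precision; the lines follow analytically.
    """
    for name, r in (("r1", r1), ("r2", r2)):
        if not (0.0 < r < 1.0):
            raise ValueError(f"{name} must lie strictly in (0, 1), got {r}")
    if D <= 0:
        raise ValueError("D must be positive")
    C1 = solve_coherence_concentration(r1)
    C2 = solve_coherence_concentration(r2)
    return ConditionLines(condition=condition, r1=r1, r2=r2, D=D, C1=C1, C2=C2)


def point_on_line(
    lines: ConditionLines,
    community: int,
    K: float | None = None,
    L: float | None = None,
) -> tuple:
    """Complete a (K, L) pair on one community's line.

    Given K, returns the L with V((K·r_self + L·r_other)/D) = r_self, and
    vice versa. Exactly one of K, L must be provided.
    """
    if community not in (1, 2):
        raise ValueError("community must be 1 or 2")
    if (K is None) == (L is None):
        raise ValueError("provide exactly one of K or L")
    r_self = lines.r1 if community == 1 else lines.r2
    r_other = lines.r2 if community == 1 else lines.r1
    C = lines.C1 if community == 1 else lines.C2
    if L is None:
        L = (C * lines.D - K * r_self) / r_other
    else:
        K = (C * lines.D - L * r_other) / r_self
    return float(K), float(L)


def all_condition_lines(
    order_parameters: dict | None = None, D: float = 1.0
) -> dict:
    """ConditionLines for every condition in an order-parameter table."""
    table = SCN_ORDER_PARAMETERS if order_parameters is None else order_parameters
    return {
        cond: condition_lines(r1, r2, D=D, condition=cond)
        for cond, (r1, r2) in table.items()
    }


def average_order_parameters(slice_results, weights: str = "uniform") -> tuple:
    """Pool per-slice (r1, r2) pairs into one condition-level pair.

    Anterior and posterior slices of a condition are averaged together, since
    the two-community model admits exactly two communities. ``weights`` is
    ``"uniform"`` (arithmetic mean of slice values, the default) or
    ``"none"`` reserved for future weighting schemes.
    """
    if weights != "uniform":
        raise ValueError("only uniform slice averaging is implemented")
    arr = np.asarray(list(slice_results), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) == 0:
        raise ValueError("expected a non-empty sequence of (r1, r2) pairs")
    return tuple(arr.mean(axis=0))
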