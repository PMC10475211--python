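"""Coupling and noise bounds from a one-community noisy Kuramoto model.

A single community of N phase oscillators with all-to-all attractive coupling
of strength K and phase noise of strength D, observed in the rotating frame of
its own mean phase, obeys the mean-field Langevin equation

    dθ(t) = −K r sin θ(t) dt + D dW_t,

where r is the stationary order parameter. Two facts make K and D estimable
from sparse phase observations:

1. Self-consistency. The stationary phase density is von Mises with
   concentration C r, where C = 2K/D, and r must satisfy V(C r) = r with
   V(x) = I₁(x)/I₀(x) the ratio of modified Bessel functions. Given a measured
   r ∈ (0, 1), the unique positive root C pins down the ratio of coupling to
   noise.

2. Moment bounds. Integrating the SDE over one period T and applying Itô's
   lemma, a Taylor expansion of sin truncated at alternating orders brackets
   the second moment of the one-cycle phase increment Δ_T between expressions
   in D, K, r and T. Solving the resulting quadratics with unbiased moment
   estimates (h-statistics) of Δ_T yields closed-form bounds K− ≤ K ≤ K+ and,
   through D = 2K/C, D− ≤ D ≤ D+.

The bounds are approximate by construction — they rest on the truncated Taylor
expansion and on stationarity of the observed cycles — so perfect bracketing
of the true K in every finite sample is not expected, only in a clear majority
of replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from scnsync.traces import PeakSeries

__all__ = [
    "PhaseIncrementSamples",
    "MomentEstimates",
    "OneCommunityBounds",
    "bessel_ratio",
    "solve_concentration",
    "solve_coherence_concentration",
    "phase_increments",
    "h_statistics",
    "coupling_and_noise_bounds",
    "one_community_bounds_from_series",
]


# ---------------------------------------------------------------------------
# Bessel-ratio self-consistency
# ---------------------------------------------------------------------------

def bessel_ratio(x):
    """V(x) = I₁(x)/I₀(x), the von Mises mean resultant length.

    Properties: V(0) = 0, V is strictly increasing, and V(x) → 1 as x → ∞
    (asymptotically 1 − 1/(2x)). Computed with exponentially scaled Bessel
    functions so it is stable for arbitrarily large arguments.

    Parameters
    ----------
    x : float or array_like
        Non-negative argument(s). Negative input is rejected: the
        self-consistency problems this package solves only ever evaluate V on
        non-negative concentrations.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("bessel_ratio requires x >= 0")
    out = i1e(x) / i0e(x)
    return out if out.ndim else float(out)


def solve_concentration(r: float, tol: float = 1e-12) -> float:
    """Solve V(C·r) = r for the unique concentration C > 0.

    For 0 < r < 1 the equation has exactly one positive root; as r → 0⁺ the
    small-argument expansion V(x) ≈ x/2 gives C → 2, and C grows without bound
    as r → 1. In the one-community model C = 2K/D links the root to the
    coupling-to-noise ratio.

    Raises
    ------
    ValueError
        If r is outside (0, 1). r = 0 is degenerate (every C solves it) and
        r = 1 would require infinite concentration.
    """
    if not (0.0 < r < 1.0):
        raise ValueError(f"solve_concentration requires 0 < r < 1, got {r!r}")
    f = lambda C: bessel_ratio(C * r) - r
    lo = 1e-12
    hi = 4.0
    # V(Cr) < r at small C; expand the bracket until the sign flips.
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for r < 1
            raise RuntimeError("failed to bracket concentration root")
    c = brentq(f, lo, hi, xtol=tol)
    return float(c)


def solve_coherence_concentration(r: float, tol: float = 1e-12) -> float:
    """Solve V(C) = r for C > 0 (the two-community line form).

    In the two-community model the stationary order parameter of community c
    satisfies r_c = V(C_c) where the concentration C_c = K_c·r_c + L_c·r_other
    is linear in the couplings; this root is the constant the K–L lines share.
    Related to :func:`solve_concentration` by C_here = C_there · r.
    """
    if not (0.0 < r < 1.0):
        raise ValueError(f"solve_coherence_concentration requires 0 < r < 1, got {r!r}")
    f = lambda C: bessel_ratio(C) - r
    hi = 4.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover
            raise RuntimeError("failed to bracket concentration root")
    return float(brentq(f, 1e-12, hi, xtol=tol))


# ---------------------------------------------------------------------------
# Phase increments and h-statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseIncrementSamples:
    """Pooled one-cycle phase increments Δ_T.

    For each retained cell and each consecutive pair of cycles, Δ_T is the
    change in the cell's relative phase from one cycle to the next. In the
    rotating frame E[Δ_T] = 0; the spread of Δ_T carries the noise signal.

    Attributes
    ----------
    samples : ndarray
        Pooled increments in radians.
    period_h : float
        T, the consensus period of the average phase, in hours.
    """

    samples: np.ndarray
    period_h: float

    @property
    def n(self) -> int:
        return len(self.samples)

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 1 or len(s) < 5:
            raise ValueError("need at least 5 pooled phase-increment samples")
        if not np.all(np.isfinite(s)):
            raise ValueError("phase increments must be finite")
        if not (20.0 <= self.period_h <= 28.0):
            raise ValueError(f"period {self.period_h} h outside circadian range [20, 28]")


@dataclass(frozen=True)
class MomentEstimates:
    """Sample moments and unbiased h-statistics of the increments.

    m2 and m4 are the biased sample central moments; h2 = n·m2/(n−1) is the
    unbiased variance estimator and h4 the fourth h-statistic, unbiased for
    the fourth central moment.
    """

    mean: float
    m2: float
    m4: float
    h2: float
    h4: float
    n: int


def phase_increments(
    series: PeakSeries,
    *,
    per_cell: bool = False,
    max_cycle_gap: int = 2,
) -> PhaseIncrementSamples:
    """Build pooled one-cycle phase increments from detected peak series.

    For consecutive detected peaks of cell j at times t_i, t_{i+1} assigned
    to population cycles c_i, c_{i+1} (gap g = c_{i+1} − c_i), the change in
    the cell's *unwrapped* relative phase is

        Δ = 2π·(1 − g) + [(t̄_p(c_{i+1}) − t_{i+1}) − (t̄_p(c_i) − t_i)]·2π/τ,

    with t̄_p(c) the across-cell mean peak time of cycle c and τ the slice
    consensus period. The 2π·(1 − g) term matters: a cell that loses a full
    cycle against the population (a phase slip, g = 2) contributes its −2π
    excursion exactly once instead of being silently dropped. Those rare
    large increments carry most of the fourth-moment signal that separates
    the lower coupling bound from the upper one. Transitions with
    g > ``max_cycle_gap`` are discarded (the increment would span too many
    periods to count as a one-cycle sample).

    By default increments are pooled across all cells and transitions;
    ``per_cell=True`` keeps only each cell's first transition.
    """
    tau = series.consensus_period_h
    all_cycles = [int(k) for ix in series.cycle_indices for k in ix]
    if not all_cycles or max(all_cycles) < 1:
        raise ValueError("need at least 2 cycles to form phase increments")
    n_cycles = max(all_cycles) + 1

    tbar = {}
    for k in range(n_cycles):
        peaks = series.peaks_at_cycle(k)
        if len(peaks) >= 2:
            tbar[k] = float(np.mean(peaks))

    omega = 2.0 * np.pi / tau
    samples = []
    for p, ix in zip(series.peak_times_h, series.cycle_indices):
        for i in range(len(p) - 1):
            c0, c1 = int(ix[i]), int(ix[i + 1])
            g = c1 - c0
            if g < 1 or g > max_cycle_gap or c0 not in tbar or c1 not in tbar:
                continue
            delta = 2.0 * np.pi * (1 - g) + (
                (tbar[c1] - p[i + 1]) - (tbar[c0] - p[i])
            ) * omega
            samples.append(delta)
            if per_cell:
                break
    if len(samples) < 5:
        raise ValueError(
            f"only {len(samples)} phase-increment samples; need at least 5"
        )
    return PhaseIncrementSamples(np.asarray(samples), tau)


def h_statistics(samples: PhaseIncrementSamples | np.ndarray) -> MomentEstimates:
    """Unbiased second and fourth central-moment estimators.

    h2 = n·m2/(n−1) and

        h4 = [3(3−2n)·n²·m2² + n²(n²−2n+3)·m4] / [(n−1)(n−2)(n−3)·n],

    where m_p = (1/n)Σ(x_i − m)^p. Both are exactly unbiased for the second
    and fourth central moments of the sampling distribution.
    """
    x = samples.samples if isinstance(samples, PhaseIncrementSamples) else np.asarray(samples, float)
    n = len(x)
    if n < 5:
        raise ValueError("h-statistics require at least 5 samples")
    m = float(np.mean(x))
    d = x - m
    m2 = float(np.mean(d**2))
    m4 = float(np.mean(d**4))
    h2 = n * m2 / (n - 1)
    h4 = (3.0 * (3 - 2 * n) * n**2 * m2**2 + n**2 * (n**2 - 2 * n + 3) * m4) / (
        (n - 1) * (n - 2) * (n - 3) * n
    )
    return MomentEstimates(mean=m, m2=m2, m4=m4, h2=h2, h4=h4, n=n)


# ---------------------------------------------------------------------------
# Closed-form K and D bounds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OneCommunityBounds:
    """Interval estimates for coupling K and noise D of one community."""

    r: float
    concentration: float
    K_minus: float
    K_plus: float
    D_minus: float
    D_plus: float
    n_samples: int
    period_h: float

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "C": self.concentration,
            "K_minus": self.K_minus,
            "K_plus": self.K_plus,
            "D_minus": self.D_minus,
            "D_plus": self.D_plus,
            "n_samples": self.n_samples,
            "T": self.period_h,
        }


def coupling_and_noise_bounds(
    C: float,
    moments: MomentEstimates,
    T: float,
    r: float,
) -> OneCommunityBounds:
    """Closed-form bounds K− ≤ K ≤ K+ and D− ≤ D ≤ D+.

    The upper bound comes from the positive root of

        4K² − 2C²·h2·r·K − C²·h2/T = 0,

    the lower bound from

        12K² − C²·r·(6h2 − h4)·K − 3C²·h2/T = 0,

    both obtained by substituting K = C·D/2 into the Itô moment inequalities
    for the one-cycle increment. The noise bounds follow as D± = 2K±/C.

    For any h4 ≥ 0 the K− quadratic has a smaller (or equal) linear
    coefficient than the K+ quadratic with the same constant term, hence
    K− ≤ K+ holds structurally; a strongly negative sample h4 (possible in
    small samples) can reverse the order, which is reported as-is.
    """
    if moments.h2 <= 0:
        raise ValueError("coupling bounds require h2 > 0")
    if T <= 0 or C <= 0 or not (0 < r < 1):
        raise ValueError("invalid C, T or r for coupling bounds")
    h2, h4 = moments.h2, moments.h4
    K_plus = 0.25 * (C**2 * h2 * r + np.sqrt(C**4 * h2**2 * r**2 + 4 * C**2 * h2 / T))
    lin = C**2 * r * (6 * h2 - h4)
    K_minus = (lin + np.sqrt(lin**2 + 144 * C**2 * h2 / T)) / 24.0
    return OneCommunityBounds(
        r=r,
        concentration=C,
        K_minus=float(K_minus),
        K_plus=float(K_plus),
        D_minus=float(2 * K_minus / C),
        D_plus=float(2 * K_plus / C),
        n_samples=moments.n,
        period_h=T,
    )


def one_community_bounds_from_series(
    series: PeakSeries,
    r: float,
    *,
    per_cell: bool = False,
) -> OneCommunityBounds:
    """Full per-slice estimate: increments → h-statistics → bounds."""
    inc = phase_increments(series, per_cell=per_cell)
    moments = h_statistics(inc)
    C = solve_concentration(r)
    return coupling_and_noise_bounds(C, moments, inc.period_h, r)
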