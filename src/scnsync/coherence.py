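"""Phase coherence: relative phases and the Kuramoto order parameter.

From the peak times of one in-vitro cycle, each cell's relative phase is the
(small) offset of its peak from the slice-mean peak time, converted to
radians with the consensus period τ:

    θ_{r,j} = (t̄_p − t_{p,j}) · 2π/τ.

The order parameter r = |Σ_j exp(iθ_{r,j})| / N is the magnitude of the mean
unit phasor: 0 for incoherent phases, 1 for perfect synchrony. The mapping
from peak-time offsets to phases is linear (no wrapping correction) because
offsets are small relative to the period — the same small-angle reasoning
under which sin(x) ≈ x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from scnsync.traces import PeakSeries, peak_time_dispersion

__all__ = [
    "CoherenceResult",
    "mean_peak_time",
    "relative_phases",
    "order_parameter",
    "community_order_parameters",
    "coherence_dispersion_correlation",
    "slice_coherence",
]

#: Which in-vitro cycle feeds the coherence estimate by default: the second
#: one (index 1), i.e. the first full cycle after the culture transient.
DEFAULT_CYCLE_INDEX = 1


@dataclass(frozen=True)
class CoherenceResult:
    """Per-slice phase-coherence summary for one cycle."""

    mean_peak_time_h: float
    relative_phases_rad: np.ndarray
    r: float
    n_cells: int
    cycle_index: int
    dispersion_h: float | None = None
    r1: float | None = None
    r2: float | None = None

    def to_dict(self) -> dict:
        d = {
            "r": self.r,
            "n_cells": self.n_cells,
            "cycle_index": self.cycle_index,
            "mean_peak_time_h": self.mean_peak_time_h,
        }
        if self.dispersion_h is not None:
            d["dispersion_h"] = self.dispersion_h
        if self.r1 is not None:
            d["r1"] = self.r1
        if self.r2 is not None:
            d["r2"] = self.r2
        return d


def _cycle_peaks(series: PeakSeries, cycle_index: int) -> np.ndarray:
    times = series.peaks_at_cycle(cycle_index)
    if len(times) < 2:
        raise ValueError(
            f"cycle {cycle_index}: only {len(times)} contributing cells (need >= 2)"
        )
    return times


def mean_peak_time(series: PeakSeries, cycle_index: int = DEFAULT_CYCLE_INDEX) -> float:
    """Arithmetic mean of per-cell peak times for the given cycle, in hours."""
    return float(np.mean(_cycle_peaks(series, cycle_index)))


def relative_phases(
    series: PeakSeries,
    cycle_index: int = DEFAULT_CYCLE_INDEX,
    tau: float | None = None,
) -> np.ndarray:
    """Relative phase per contributing cell, in radians.

    θ_{r,j} = (t̄_p − t_{p,j})·2π/τ with τ the slice consensus period unless
    overridden. Phases sum to zero by construction.
    """
    tau = series.consensus_period_h if tau is None else tau
    if not (20.0 <= tau <= 28.0):
        raise ValueError(f"period {tau} h outside circadian range [20, 28]")
    peaks = _cycle_peaks(series, cycle_index)
    return (peaks.mean() - peaks) * 2.0 * np.pi / tau


def order_parameter(phases) -> float:
    """Magnitude of the mean unit phasor of the given phases (radians)."""
    phases = np.asarray(phases, dtype=float)
    if phases.size < 2:
        raise ValueError("order parameter needs at least 2 phases")
    return float(np.abs(np.mean(np.exp(1j * phases))))


def community_order_parameters(
    series: PeakSeries,
    labels,
    cycle_index: int = DEFAULT_CYCLE_INDEX,
    tau: float | None = None,
) -> tuple:
    """(r1, r2): order parameter within each labeled community.

    ``labels`` assigns 1 or 2 to each cell of ``series``. Each community uses
    its *own* mean peak time, so two internally tight groups sitting half a
    cycle apart both score r ≈ 1 even though the whole slice does not.

    A group with fewer than 2 cells has no defined order parameter and is
    reported as None; if neither group has 2 cells the call fails.
    """
    labels = np.asarray(labels)
    if len(labels) != series.n_cells:
        raise ValueError("labels must cover every cell in the series")
    tau = series.consensus_period_h if tau is None else tau
    out = []
    for lab in (1, 2):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            out.append(None)
            continue
        sub = PeakSeries(
            cell_ids=[series.cell_ids[j] for j in idx],
            peak_times_h=[series.peak_times_h[j] for j in idx],
            periods_h=series.periods_h[idx],
            consensus_period_h=series.consensus_period_h,
            cycle_indices=[series.cycle_indices[j] for j in idx],
            metadata=series.metadata,
            filtered=series.filtered,
        )
        out.append(order_parameter(relative_phases(sub, cycle_index, tau)))
    if out[0] is None and out[1] is None:
        raise ValueError("neither community has >= 2 labeled cells")
    return tuple(out)


def coherence_dispersion_correlation(r_values, dispersions_h) -> float:
    """Pearson correlation between per-slice r and peak-time dispersion.

    On real and realistic synthetic data this is strongly negative: wide
    peak-time scatter is the time-domain face of low phase coherence.
    """
    r_values = np.asarray(r_values, float)
    dispersions_h = np.asarray(dispersions_h, float)
    if len(r_values) != len(dispersions_h) or len(r_values) < 3:
        raise ValueError("need >= 3 paired (r, dispersion) observations")
    if np.std(r_values) == 0 or np.std(dispersions_h) == 0:
        raise ValueError("zero-variance input")
    return float(_stats.pearsonr(r_values, dispersions_h).statistic)


def slice_coherence(
    series: PeakSeries,
    cycle_index: int = DEFAULT_CYCLE_INDEX,
    labels=None,
) -> CoherenceResult:
    """Full coherence summary for one slice and one cycle."""
    phases = relative_phases(series, cycle_index)
    r1 = r2 = None
    if labels is not None:
        r1, r2 = community_order_parameters(series, labels, cycle_index)
    return CoherenceResult(
        mean_peak_time_h=mean_peak_time(series, cycle_index),
        relative_phases_rad=phases,
        r=order_parameter(phases),
        n_cells=len(phases),
        cycle_index=cycle_index,
        dispersion_h=peak_time_dispersion(series, cycle_index),
        r1=r1,
        r2=r2,
    )
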