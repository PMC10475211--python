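"""Trace processing: smoothing, resampling, peak detection and inclusion rules.

Raw input is a matrix of hourly single-cell bioluminescence intensities for
one SCN slice. Processing mirrors standard practice for PER2::LUC recordings:
traces are smoothed and resampled to one point per minute, per-cell peak
times are detected, and only cells showing at least three full cycles with a
circadian period between 20 and 28 h are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

__all__ = [
    "TraceMatrix",
    "PeakSeries",
    "smooth_and_resample",
    "detect_peaks",
    "filter_cells",
    "peak_time_dispersion",
    "process_traces",
]

#: Circadian inclusion window for per-cell periods, hours.
PERIOD_RANGE_H = (20.0, 28.0)

#: Minimum number of complete cycles (inter-peak intervals) per retained cell.
MIN_CYCLES = 3


@dataclass(frozen=True)
class TraceMatrix:
    """Intensity traces for one slice: cells × uniformly sampled times.

    Attributes
    ----------
    times_h : ndarray
        Uniform time grid in hours.
    intensities : ndarray, shape (n_cells, n_times)
        Bioluminescence intensities, arbitrary units.
    cell_ids : list of str
    metadata : dict
        Slice-level annotations (age, photoperiod, position, ...).
    """

    times_h: np.ndarray
    intensities: np.ndarray
    cell_ids: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        x = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "intensities", x)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("times_h must be a 1-D grid with >= 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be strictly increasing and uniform")
        if x.ndim != 2 or x.shape[1] != len(t):
            raise ValueError("intensities must be (n_cells, n_times)")
        if x.shape[0] < 2:
            raise ValueError("need at least 2 cells")
        if not np.all(np.isfinite(x)):
            raise ValueError("intensities must be finite")
        if len(self.cell_ids) != x.shape[0]:
            raise ValueError("cell_ids length must match number of cells")

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]

    @property
    def dt_h(self) -> float:
        return float(self.times_h[1] - self.times_h[0])

    @property
    def duration_h(self) -> float:
        return float(self.times_h[-1] - self.times_h[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities.T, columns=self.cell_ids)
        df.insert(0, "time_h", self.times_h)
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "TraceMatrix":
        if "time_h" not in df.columns:
            raise ValueError("trace CSV must have a 'time_h' first column")
        cells = [c for c in df.columns if c != "time_h"]
        return cls(
            times_h=df["time_h"].to_numpy(),
            intensities=df[cells].to_numpy().T,
            cell_ids=cells,
            metadata=metadata or {},
        )

    @classmethod
    def read_csv(cls, path, metadata: dict | None = None) -> "TraceMatrix":
        return cls.from_frame(pd.read_csv(path), metadata=metadata)


@dataclass(frozen=True)
class PeakSeries:
    """Per-cell peak times, period estimates, and aligned cycle indices.

    ``peak_times_h[j]`` is the ordered array of peak times for cell j;
    ``periods_h[j]`` the cell's mean inter-peak interval (NaN when the cell
    has fewer than two peaks). The slice consensus period is the median of
    the retained cells' periods.

    ``cycle_indices[j]`` labels each of cell j's peaks with the *population*
    cycle it belongs to, so that "cycle k" means the same in-vitro cycle for
    every cell even when a cell's first peak was clipped at the record edge.
    When not supplied, per-cell ordinal indices (0, 1, 2, ...) are used.
    """

    cell_ids: list
    peak_times_h: list
    periods_h: np.ndarray
    consensus_period_h: float
    cycle_indices: list | None = None
    metadata: dict = field(default_factory=dict)
    filtered: bool = False
    n_dropped: int = 0

    def __post_init__(self):
        object.__setattr__(self, "periods_h", np.asarray(self.periods_h, dtype=float))
        object.__setattr__(
            self, "peak_times_h", [np.asarray(p, dtype=float) for p in self.peak_times_h]
        )
        for p in self.peak_times_h:
            if len(p) > 1 and np.any(np.diff(p) <= 0):
                raise ValueError("peak times must be strictly increasing per cell")
        if self.cycle_indices is None:
            object.__setattr__(
                self,
                "cycle_indices",
                [np.arange(len(p)) for p in self.peak_times_h],
            )
        else:
            object.__setattr__(
                self,
                "cycle_indices",
                [np.asarray(ix, dtype=int) for ix in self.cycle_indices],
            )
            for p, ix in zip(self.peak_times_h, self.cycle_indices):
                if len(p) != len(ix):
                    raise ValueError("cycle_indices must parallel peak_times_h")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def n_cycles(self, j: int) -> int:
        """Number of complete cycles (inter-peak intervals) for cell j."""
        return max(len(self.peak_times_h[j]) - 1, 0)

    def peaks_at_cycle(self, cycle_index: int) -> np.ndarray:
        """Peak times of every cell that has the given population cycle."""
        out = []
        for p, ix in zip(self.peak_times_h, self.cycle_indices):
            hit = np.flatnonzero(ix == cycle_index)
            if len(hit):
                out.append(p[hit[0]])
        return np.asarray(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, peaks, idx, per in zip(
            self.cell_ids, self.peak_times_h, self.cycle_indices, self.periods_h
        ):
            for k, t in zip(idx, peaks):
                rows.append((cid, int(k), t, per))
        return pd.DataFrame(rows, columns=["cell_id", "cycle_index", "peak_time_h", "period_h"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


DEFAULT_SMOOTHING_WINDOW_H = 1.0


def smooth_and_resample(
    traces: TraceMatrix,
    *,
    window_h: float = DEFAULT_SMOOTHING_WINDOW_H,
    out_dt_min: float = 1.0,
) -> TraceMatrix:
    """Smooth with a centered moving average, then resample by cubic spline.

    The moving-average window is applied on the native grid with edge
    truncation (shorter effective window near the record ends), after which a
    cubic spline interpolates onto a grid of one point per ``out_dt_min``
    minutes spanning the input range. Deterministic.

    The default window (1 h) only suppresses measurement noise at the
    sampling scale. Wider windows also average away genuine fast phase
    jitter, which biases the order parameter upward and the phase-increment
    moments downward — exactly the quantities the coupling/noise inference
    consumes — so widen with care on low-noise recordings.
    """
    if traces.duration_h < 48.0:
        raise ValueError("need at least 48 h of data")
    if window_h > traces.duration_h:
        raise ValueError("smoothing window longer than the record")
    half = max(int(round(window_h / 2.0 / traces.dt_h)), 0)
    n = len(traces.times_h)
    csum = np.cumsum(
        np.pad(traces.intensities, ((0, 0), (1, 0)), mode="constant"), axis=1
    )
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    smoothed = (csum[:, hi] - csum[:, lo]) / (hi - lo)

    out_dt_h = out_dt_min / 60.0
    new_times = np.arange(traces.times_h[0], traces.times_h[-1] + out_dt_h / 2, out_dt_h)
    new_times = new_times[new_times <= traces.times_h[-1] + 1e-9]
    spline = CubicSpline(traces.times_h, smoothed, axis=1)
    resampled = spline(new_times)
    return TraceMatrix(
        times_h=new_times,
        intensities=resampled,
        cell_ids=list(traces.cell_ids),
        metadata=dict(traces.metadata),
    )


def detect_peaks(
    traces: TraceMatrix,
    *,
    min_separation_h: float = 16.0,
    prominence_fraction: float = 0.2,
) -> PeakSeries:
    """Detect per-cell peaks and estimate per-cell periods.

    A peak is a local maximum separated from its neighbours by at least
    ``min_separation_h`` (safe for circadian periods in [20, 28] h) with
    prominence above ``prominence_fraction`` of the cell's amplitude range.
    Cells with fewer than two peaks are kept in the output with an empty
    series and period NaN; they are removed later by :func:`filter_cells`.
    """
    dt = traces.dt_h
    distance = max(int(round(min_separation_h / dt)), 1)
    peak_times, periods = [], []
    for row in traces.intensities:
        rng = float(np.ptp(row))
        if rng <= 0:
            peak_times.append(np.array([]))
            periods.append(np.nan)
            continue
        idx, _ = find_peaks(row, distance=distance, prominence=prominence_fraction * rng)
        times = traces.times_h[idx]
        peak_times.append(times)
        periods.append(float(np.mean(np.diff(times))) if len(times) >= 2 else np.nan)
    periods = np.asarray(periods)
    ok = np.isfinite(periods)
    consensus = float(np.median(periods[ok])) if ok.any() else np.nan
    cycle_indices = _align_cycles(peak_times, consensus)
    return PeakSeries(
        cell_ids=list(traces.cell_ids),
        peak_times_h=peak_times,
        periods_h=periods,
        consensus_period_h=consensus,
        cycle_indices=cycle_indices,
        metadata=dict(traces.metadata),
    )


def _align_cycles(peak_times: list, consensus_period_h: float) -> list | None:
    """Assign each peak to a population cycle.

    The pooled peak times define a reference phase via their circular mean at
    the consensus period; each peak's cycle is the nearest integer multiple
    of the period from that reference. This keeps "cycle k" synonymous
    across cells even when a cell misses a peak at the record edge.
    """
    if not np.isfinite(consensus_period_h) or consensus_period_h <= 0:
        return None
    pooled = np.concatenate([p for p in peak_times if len(p)]) if peak_times else np.array([])
    if len(pooled) == 0:
        return None
    omega = 2.0 * np.pi / consensus_period_h
    ref = np.angle(np.mean(np.exp(1j * omega * pooled))) / omega  # in (−τ/2, τ/2]
    indices = [
        np.round((p - ref) / consensus_period_h).astype(int) for p in peak_times
    ]
    offset = min((ix[0] for ix in indices if len(ix)), default=0)
    return [ix - offset for ix in indices]


def filter_cells(
    series: PeakSeries,
    *,
    period_range_h: tuple = PERIOD_RANGE_H,
    min_cycles: int = MIN_CYCLES,
) -> PeakSeries:
    """Apply the inclusion rules: ≥ ``min_cycles`` complete cycles, circadian period.

    A cycle is one inter-peak interval, so ``min_cycles=3`` requires at least
    4 detected peaks. The per-cell period must lie inside
    ``period_range_h`` (inclusive). Idempotent. Raises if no cell survives.
    """
    lo, hi = period_range_h
    keep = [
        j
        for j in range(series.n_cells)
        if series.n_cycles(j) >= min_cycles
        and np.isfinite(series.periods_h[j])
        and lo <= series.periods_h[j] <= hi
    ]
    if not keep:
        raise ValueError("no cells pass the cycle-count and period filters")
    periods = series.periods_h[keep]
    return PeakSeries(
        cell_ids=[series.cell_ids[j] for j in keep],
        peak_times_h=[series.peak_times_h[j] for j in keep],
        periods_h=periods,
        consensus_period_h=float(np.median(periods)),
        cycle_indices=[series.cycle_indices[j] for j in keep],
        metadata=dict(series.metadata),
        filtered=True,
        n_dropped=series.n_cells - len(keep) + series.n_dropped,
    )


def peak_time_dispersion(series: PeakSeries, cycle_index: int) -> float:
    """SD of the chosen cycle's peak times across cells, in hours.

    The sample standard deviation (ddof=1) over all cells that have the
    requested cycle; cells without it are skipped. Requires at least two
    contributors.
    """
    times = series.peaks_at_cycle(cycle_index)
    if len(times) < 2:
        raise ValueError(
            f"cycle {cycle_index}: only {len(times)} contributing cells (need >= 2)"
        )
    return float(np.std(times, ddof=1))


def process_traces(
    traces: TraceMatrix,
    *,
    window_h: float = DEFAULT_SMOOTHING_WINDOW_H,
    min_separation_h: float = 16.0,
    prominence_fraction: float = 0.2,
    period_range_h: tuple = PERIOD_RANGE_H,
    min_cycles: int = MIN_CYCLES,
) -> PeakSeries:
    """Convenience wrapper: smooth → resample → detect peaks → filter cells."""
    smoothed = smooth_and_resample(traces, window_h=window_h)
    series = detect_peaks(
        smoothed,
        min_separation_h=min_separation_h,
        prominence_fraction=prominence_fraction,
    )
    return filter_cells(series, period_range_h=period_range_h, min_cycles=min_cycles)
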