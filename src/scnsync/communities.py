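"""Two-community detection from raw traces via RMT-filtered correlations.

The SCN splits into two functional neuronal subpopulations. To recover them
from raw traces alone, a Pearson cross-correlation matrix is built and then
cleaned with random-matrix-theory (RMT) arguments: the component of the
largest eigenvalue captures the global, slice-wide rhythm and is removed;
components whose eigenvalues fall inside the Marchenko–Pastur bulk
[(1−√(N/T))², (1+√(N/T))²] are sampling noise and are removed too. The sign
pattern of the leading eigenvector of the residual matrix then partitions
the cells into two maximally contrasted groups — positively correlated
within, negatively between, relative to the global activity.

This spectral split is a deliberately simple stand-in for heavier community
detection machinery: it satisfies the contrast property that defines the two
SCN clusters, and external label assignments can be supplied instead at any
point of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from scnsync.traces import TraceMatrix

__all__ = [
    "CommunityAssignment",
    "correlation_matrix",
    "rmt_filter",
    "split_two_communities",
    "detect_communities",
]


@dataclass(frozen=True)
class CommunityAssignment:
    """Result of a two-community split.

    ``labels`` holds 1/2 per cell (defined only up to swapping);
    ``quality`` is the mean within-group minus mean between-group entry of
    the filtered correlation matrix; ``degenerate`` flags a leading
    eigenvector with a single sign (no credible two-group structure).
    """

    labels: np.ndarray
    quality: float
    eigenvalues: np.ndarray
    degenerate: bool


def correlation_matrix(traces: TraceMatrix) -> np.ndarray:
    """Zero-lag Pearson correlation of z-scored raw traces.

    Constant traces get zero off-diagonal entries (flagged with a warning)
    rather than NaNs, so downstream spectral steps stay well-posed.
    """
    if traces.n_cells < 3:
        raise ValueError("need at least 3 cells")
    if traces.duration_h < 48.0:
        raise ValueError("need at least 48 h of data")
    x = traces.intensities
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{constant.sum()} constant trace(s); correlations set to 0")
        x = x.copy()
        x[constant] += np.nan  # mark, fix after corrcoef
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x)
    if constant.any():
        corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def rmt_filter(corr: np.ndarray, n_times: int) -> np.ndarray:
    """Remove the global mode and the Marchenko–Pastur noise bulk.

    Eigen-decomposes the correlation matrix, drops (a) the component of the
    single largest eigenvalue — the slice-wide common rhythm — and (b) every
    component whose eigenvalue lies inside the Marchenko–Pastur interval for
    an N×T data matrix of independent noise. The residual matrix keeps only
    structure that is neither global nor noise. When N ≥ T the
    Marchenko–Pastur bound is degenerate and only the global mode is removed
    (with a warning).

    The global mode is recognised by its signature, not merely by rank: a
    common rhythm loads every cell with the same sign. If the leading
    eigenvector is strongly two-signed (as happens when two communities sit
    in antiphase and their common rhythm cancels), it *is* the community
    contrast and is retained.
    """
    corr = np.asarray(corr, float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    n = corr.shape[0]
    eigvals, eigvecs = np.linalg.eigh(corr)  # ascending
    keep = np.zeros(n, dtype=bool)
    q = n / n_times
    if q < 1.0:
        hi = (1.0 + np.sqrt(q)) ** 2
        # Only components ABOVE the bulk carry coherent group structure; the
        # near-zero eigenvalues below the bulk's lower edge are degenerate
        # directions of a strongly correlated matrix and are dropped as well.
        keep = eigvals > hi
    else:
        warnings.warn(
            "N >= T: Marchenko-Pastur bound degenerate; removing only the global mode"
        )
        keep[:] = True
    lead = eigvecs[:, -1]
    strong = np.abs(lead) > 0.05 * np.abs(lead).max()
    sign_fraction = max(
        np.mean(lead[strong] > 0), np.mean(lead[strong] < 0)
    ) if strong.any() else 1.0
    if sign_fraction >= 0.9:  # single-signed loading = common rhythm
        keep[-1] = False
    filtered = (eigvecs[:, keep] * eigvals[keep]) @ eigvecs[:, keep].T
    return filtered


def split_two_communities(filtered: np.ndarray) -> CommunityAssignment:
    """Partition cells by the sign of the leading residual eigenvector."""
    filtered = np.asarray(filtered, float)
    if filtered.size == 0:
        raise ValueError("empty matrix")
    eigvals, eigvecs = np.linalg.eigh(filtered)
    if eigvals.max() < 1e-10:
        # nothing survived the filter: no community structure beyond the
        # global rhythm
        n = filtered.shape[0]
        return CommunityAssignment(
            labels=np.ones(n, int),
            quality=0.0,
            eigenvalues=eigvals,
            degenerate=True,
        )
    lead = eigvecs[:, np.argmax(eigvals)]
    labels = np.where(lead >= 0, 1, 2)
    degenerate = (labels == labels[0]).all()
    within = []
    between = []
    n = filtered.shape[0]
    mask1 = labels == 1
    off = ~np.eye(n, dtype=bool)
    same = (mask1[:, None] == mask1[None, :]) & off
    diff = (mask1[:, None] != mask1[None, :])
    quality = 0.0
    if not degenerate:
        quality = float(filtered[same].mean() - filtered[diff].mean())
    return CommunityAssignment(
        labels=labels,
        quality=quality,
        eigenvalues=eigvals,
        degenerate=degenerate,
    )


def detect_communities(traces: TraceMatrix) -> CommunityAssignment:
    """Raw traces → correlation → RMT filter → two-community split."""
    corr = correlation_matrix(traces)
    filtered = rmt_filter(corr, n_times=len(traces.times_h))
    return split_two_communities(filtered)
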