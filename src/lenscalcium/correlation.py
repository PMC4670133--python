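"""Temporal and spatial coherence of the cell population.

Sliding-window average correlation R_avg(T): Pearson correlation of each
cell pair inside a window T +- half_width, averaged over all pairs, with
the window slid along the recording.  Spatial structure is captured by
binning the full-series pairwise correlations by intercellular Euclidean
distance, giving R_avg(I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SlidingCorrelation",
    "DistanceBinnedSeries",
    "pairwise_window_correlation",
    "average_correlation_over_time",
    "distance_matrix",
    "correlation_vs_distance",
    "default_distance_bins",
]

_VAR_FLOOR = 1e-24


@dataclass
class SlidingCorrelation:
    window_centers: np.ndarray   # T (s)
    r_avg: np.ndarray            # R_avg(T), NaN where all pairs skipped
    n_pairs: np.ndarray          # pairs entering each window's average
    window_half_width: float
    step: float


@dataclass
class DistanceBinnedSeries:
    """A statistic aggregated over half-open intercellular-distance bins."""

    bin_centers: np.ndarray      # I (um)
    values: np.ndarray
    stderr: np.ndarray
    n_pairs: np.ndarray

    def slope(self) -> float:
        """OLS slope of value vs bin center (per um)."""
        if self.bin_centers.size < 2:
            raise ValueError("need >= 2 bins for a slope")
        return float(np.polyfit(self.bin_centers, self.values, 1)[0])


def pairwise_window_correlation(u_i: np.ndarray, u_j: np.ndarray,
                                times: np.ndarray, center: float,
                                half_width: float = 10.0) -> float:
    """Pearson correlation of two traces in the window [T - dt, T + dt].

    Returns NaN when either segment is constant in the window (the pair
    is skipped by the averaging routines).
    """
    times = np.asarray(times, dtype=float)
    mask = (times >= center - half_width) & (times <= center + half_width)
    if times[0] > center - half_width or times[-1] < center + half_width:
        raise ValueError("window extends beyond the recording")
    a = np.asarray(u_i, dtype=float)[mask]
    b = np.asarray(u_j, dtype=float)[mask]
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va < _VAR_FLOOR or vb < _VAR_FLOOR:
        return float("nan")
    return float((da @ db) / np.sqrt(va * vb))


def _window_corr_matrix(seg: np.ndarray) -> np.ndarray:
    """Pairwise Pearson over rows of ``seg``; NaN rows for constant cells."""
    d = seg - seg.mean(axis=1, keepdims=True)
    v = (d ** 2).sum(axis=1)
    ok = v >= _VAR_FLOOR
    c = d @ d.T
    denom = np.sqrt(np.outer(v, v))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = c / denom
    r[~ok, :] = np.nan
    r[:, ~ok] = np.nan
    return r


def average_correlation_over_time(traces: np.ndarray, times: np.ndarray,
                                  half_width: float = 10.0,
                                  step: float = 5.0) -> SlidingCorrelation:
    """R_avg(T) over all cell pairs, windows slid at ``step`` seconds.

    Window centers start at t0 + half_width and advance by ``step``;
    windows overlapping the recording edge are dropped so every window
    has equal length.  Constant-segment pairs are skipped, not zeroed.
    """
    traces = np.asarray(traces, dtype=float)
    times = np.asarray(times, dtype=float)
    if traces.shape[0] < 2:
        raise ValueError("need >= 2 cells")
    centers = np.arange(times[0] + half_width, times[-1] - half_width + 1e-9, step)
    r_avg = np.full(centers.size, np.nan)
    n_pairs = np.zeros(centers.size, dtype=int)
    iu = np.triu_indices(traces.shape[0], k=1)
    for w, T in enumerate(centers):
        mask = (times >= T - half_width) & (times <= T + half_width)
        r = _window_corr_matrix(traces[:, mask])[iu]
        good = np.isfinite(r)
        n_pairs[w] = int(good.sum())
        if n_pairs[w]:
            r_avg[w] = float(r[good].mean())
    return SlidingCorrelation(window_centers=centers, r_avg=r_avg,
                              n_pairs=n_pairs, window_half_width=half_width,
                              step=step)


def distance_matrix(positions: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise Euclidean distances (um)."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("need >= 2 positions")
    return squareform(pdist(positions))


def default_distance_bins(dist: np.ndarray, bin_width: float = 25.0) -> np.ndarray:
    """Contiguous bin edges [0, w, 2w, ...] up to the 95th pairwise percentile."""
    iu = np.triu_indices(dist.shape[0], k=1)
    dmax = float(np.percentile(dist[iu], 95))
    n_bins = max(int(np.ceil(dmax / bin_width)), 1)
    return np.arange(0, (n_bins + 1)) * bin_width


def correlation_vs_distance(traces: np.ndarray, positions: np.ndarray,
                            bin_width: float = 25.0,
                            bin_edges: np.ndarray | None = None
                            ) -> DistanceBinnedSeries:
    """R_avg(I): full-series pairwise correlation binned by distance.

    Bins are half-open [edge_k, edge_{k+1}); empty bins and
    constant-trace pairs are omitted.  stderr = SD / sqrt(n_pairs).
    """
    traces = np.asarray(traces, dtype=float)
    dist = distance_matrix(positions)
    if bin_edges is None:
        bin_edges = default_distance_bins(dist, bin_width)
    r = _window_corr_matrix(traces)
    iu = np.triu_indices(traces.shape[0], k=1)
    rv, dv = r[iu], dist[iu]
    good = np.isfinite(rv)
    rv, dv = rv[good], dv[good]
    centers, values, stderr, n_pairs = [], [], [], []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        m = (dv >= lo) & (dv < hi)
        if not m.any():
            continue
        vals = rv[m]
        centers.append(0.5 * (lo + hi))
        values.append(float(vals.mean()))
        stderr.append(float(vals.std(ddof=1) / np.sqrt(vals.size))
                      if vals.size > 1 else 0.0)
        n_pairs.append(int(vals.size))
    return DistanceBinnedSeries(bin_centers=np.asarray(centers),
                                values=np.asarray(values),
                                stderr=np.asarray(stderr),
                                n_pairs=np.asarray(n_pairs, dtype=int))
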