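"""Spatio-temporal grouping statistic.

For a characteristic time tau (t_res, dt_act or dt_deact) and a distance
bin I, delta_tau(I) averages, over cells, the mean absolute difference
|tau_i - tau_j| to the cells j lying in that distance bin around i.  An
increasing profile means nearby cells share similar signaling times,
i.e. the tissue is spatio-temporally grouped.  Profiles are normalized
per capsule so the smallest bin value equals one, removing inter-capsule
differences in absolute signaling times before group averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .correlation import distance_matrix, default_distance_bins

__all__ = ["GroupingProfile", "delta_tau", "normalize_profile", "grouping_slope"]


@dataclass
class GroupingProfile:
    statistic: str           # "t_res" | "dt_act" | "dt_deact"
    bin_centers: np.ndarray  # I (um)
    delta_tau: np.ndarray    # s (raw) or dimensionless (normalized)
    normalized: bool = False


def delta_tau(times: np.ndarray, positions: np.ndarray,
              bin_width: float = 25.0,
              bin_edges: np.ndarray | None = None,
              statistic: str = "t_res") -> GroupingProfile:
    """Average per-cell mean |tau_i - tau_j| per distance bin.

    For each bin, cells with at least one neighbor in the bin contribute
    the mean absolute time difference to those neighbors; the bin value
    is the mean of these per-cell terms.  Cells with non-finite times
    are dropped; bins with no pairs are omitted.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    finite = np.isfinite(times)
    times, positions = times[finite], positions[finite]
    if times.size < 2:
        raise ValueError("need >= 2 cells with finite times")
    dist = distance_matrix(positions)
    if bin_edges is None:
        bin_edges = default_distance_bins(dist, bin_width)
    absdiff = np.abs(times[:, None] - times[None, :])
    np.fill_diagonal(dist, np.nan)  # exclude self-pairs from bin membership
    centers, values = [], []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        inbin = (dist >= lo) & (dist < hi)
        counts = inbin.sum(axis=1)
        contrib = counts > 0
        if not contrib.any():
            continue
        per_cell = (absdiff * inbin).sum(axis=1)[contrib] / counts[contrib]
        centers.append(0.5 * (lo + hi))
        values.append(float(per_cell.mean()))
    return GroupingProfile(statistic=statistic,
                           bin_centers=np.asarray(centers),
                           delta_tau=np.asarray(values))


def normalize_profile(profile: GroupingProfile) -> GroupingProfile:
    """Divide every bin by the smallest bin value (capsule normalization).

    An all-zero or zero-minimum profile cannot be normalized; it is
    returned unchanged with a warning.
    """
    if profile.normalized:
        return profile
    mn = float(profile.delta_tau.min())
    if mn <= 0:
        warnings.warn("zero-minimum grouping profile left unnormalized")
        return profile
    return _dc_replace(profile, delta_tau=profile.delta_tau / mn, normalized=True)


def grouping_slope(profile: GroupingProfile) -> float:
    """OLS slope of the profile vs bin center (per um)."""
    if profile.bin_centers.size < 3:
        raise ValueError("need >= 3 populated bins for a slope")
    return float(np.polyfit(profile.bin_centers, profile.delta_tau, 1)[0])
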