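"""End-to-end orchestration: capsule analysis and cohort assembly.

``analyze_recording`` runs the full per-capsule chain (smoothing, event
extraction, sliding/binned correlation, kinetics, grouping, network) and
returns one summary row plus the intermediate products; ``analyze_cohort``
maps it over a list of capsules and assembles the CohortTable.
"""

from __future__ import annotations

import json
import hashlib
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlation, grouping, kinetics, network, traces as traces_mod
from .cohort import cohort_table
from .synthetic import CapsuleRecording
from .traces import TraceConfig, events_to_frame

log = logging.getLogger("lenscalcium")

__all__ = ["AnalysisConfig", "CapsuleAnalysis", "analyze_recording",
           "analyze_cohort", "COHORT_VARIABLES"]

# per-capsule variables entering cohort comparisons
COHORT_VARIABLES = ["frac_spontaneous", "mean_dt_act", "mean_dt_deact",
                    "s_act", "s_deact", "k_avg", "c_avg", "e_glob",
                    "n_c_over_n", "slope_t_res", "slope_dt_act",
                    "slope_dt_deact"]


@dataclass(frozen=True)
class AnalysisConfig:
    trace: TraceConfig = field(default_factory=TraceConfig)
    corr_half_width: float = 10.0
    corr_step: float = 5.0
    distance_bin_width: float = 25.0
    co_activation_window: float = 1.0
    distance_cutoff: float = 30.0
    louvain_runs: int = 20
    louvain_seed: int = 0


@dataclass
class CapsuleAnalysis:
    capsule_id: str
    group: str
    events: pd.DataFrame
    summary_row: dict
    sliding: correlation.SlidingCorrelation
    corr_vs_dist: correlation.DistanceBinnedSeries
    profiles: dict                  # statistic -> normalized GroupingProfile
    graph: "network.nx.Graph"
    metrics: network.NetworkMetrics | None
    exclusions: dict                # tallied per-stage exclusion counts


def analyze_recording(rec: CapsuleRecording,
                      config: AnalysisConfig = AnalysisConfig()) -> CapsuleAnalysis:
    """Full analysis of one capsule recording."""
    events = traces_mod.analyze_capsule(rec, config.trace)
    summary = traces_mod.summarize_capsule(events, capsule_id=rec.capsule_id)
    ev_df = events_to_frame(events)
    times = rec.times

    # every population analysis runs on the smoothed traces, like the
    # per-cell event extraction
    smoothed = np.vstack([traces_mod.smooth_trace(rec.traces[i],
                                                  config.trace.smooth_m)
                          for i in range(rec.n_cells)])
    sliding = correlation.average_correlation_over_time(
        smoothed, times, config.corr_half_width, config.corr_step)
    corr_dist = correlation.correlation_vs_distance(
        smoothed, rec.positions, config.distance_bin_width)

    resp = ev_df["is_responder"].to_numpy()
    t_res = ev_df["t_res"].to_numpy(dtype=float)
    row: dict = {
        "capsule_id": rec.capsule_id,
        "group": rec.cataract_type,
        "grade": rec.cataract_grade,
        "n_cells": summary.n_cells,
        "n_responders": summary.n_responders,
        "frac_spontaneous": summary.frac_spontaneous,
        "mean_dt_act": summary.mean_dt_act,
        "mean_dt_deact": summary.mean_dt_deact,
        "r_avg_dist_slope": corr_dist.slope()
        if corr_dist.bin_centers.size >= 2 else math.nan,
    }

    # kinetics: activation on t_res, deactivation on t_half
    for kind, col, key in (("activation", "t_res", "act"),
                           ("deactivation", "t_half", "deact")):
        vals = ev_df.loc[resp, col].dropna().to_numpy()
        try:
            sp = kinetics.estimate_speed(kinetics.build_curve(vals, kind),
                                         frame_dt=rec.frame_dt)
            row[f"s_{key}"] = sp.speed
            row[f"t20_{key}"], row[f"t80_{key}"] = sp.t20, sp.t80
        except ValueError:
            row[f"s_{key}"] = math.nan
            row[f"t20_{key}"] = row[f"t80_{key}"] = math.nan

    # spatio-temporal grouping profiles, capsule-normalized
    profiles: dict = {}
    for stat in ("t_res", "dt_act", "dt_deact"):
        vals = ev_df[stat].to_numpy(dtype=float)
        try:
            prof = grouping.normalize_profile(grouping.delta_tau(
                vals, rec.positions, config.distance_bin_width, statistic=stat))
            profiles[stat] = prof
            row[f"slope_{stat}"] = grouping.grouping_slope(prof) \
                if prof.bin_centers.size >= 3 else math.nan
        except ValueError:
            row[f"slope_{stat}"] = math.nan

    g = network.build_network(t_res, rec.positions, resp,
                              config.co_activation_window,
                              config.distance_cutoff)
    if g.number_of_nodes() >= 2:
        m = network.network_metrics(g, config.louvain_runs, config.louvain_seed)
        row.update(k_avg=m.k_avg, c_avg=m.c_avg, e_glob=m.e_glob,
                   n_c_over_n=m.n_c_over_n, modularity_q=m.modularity_q)
    else:
        m = None
        row.update(k_avg=math.nan, c_avg=math.nan, e_glob=math.nan,
                   n_c_over_n=math.nan, modularity_q=math.nan)

    exclusions = {
        "non_responders": summary.n_cells - summary.n_responders,
        "no_half_decay": int(ev_df["is_responder"].sum()
                             - ev_df["dt_deact"].notna().sum()),
        "constant_corr_pairs_skipped": int(
            (len(ev_df) * (len(ev_df) - 1) // 2) - int(corr_dist.n_pairs.sum())),
    }
    log.info("capsule %s: %d cells, %d responders, %d non-responders excluded",
             rec.capsule_id, summary.n_cells, summary.n_responders,
             exclusions["non_responders"])
    return CapsuleAnalysis(rec.capsule_id, rec.cataract_type, ev_df, row,
                           sliding, corr_dist, profiles, g, m, exclusions)


def analyze_cohort(capsules: list[CapsuleRecording],
                   config: AnalysisConfig = AnalysisConfig()
                   ) -> tuple[pd.DataFrame, list[CapsuleAnalysis]]:
    """Analyze every capsule and assemble the cohort table."""
    analyses = [analyze_recording(rec, config) for rec in capsules]
    table = cohort_table([a.summary_row for a in analyses]) if analyses \
        else pd.DataFrame()
    return table, analyses
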