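"""Readers and writers for the pipeline's canonical plain-text formats.

A capsule on disk is three files sharing a stem:
  <stem>_traces.csv   wide table, first column ``time_s``, one column per cell id
  <stem>_roi.csv      ``cell_id,x_um,y_um``
  <stem>_meta.json    capsule_id, t_stim, frame_dt, group labels
plus, for synthetic capsules only, ``<stem>_truth.json`` with the
generative ground truth.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from .synthetic import CapsuleRecording, GroundTruth

__all__ = ["write_capsule", "read_capsule", "write_network"]

_TIME_TOL = 1e-6  # s; allowed deviation from uniform sampling


def write_capsule(rec: CapsuleRecording, out_dir: str | Path,
                  stem: str | None = None) -> dict[str, Path]:
    """Write one capsule's traces, ROI table and metadata; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or rec.capsule_id
    ids = rec.cell_ids

    traces = pd.DataFrame(rec.traces.T, columns=ids)
    traces.insert(0, "time_s", rec.times)
    tr_path = out_dir / f"{stem}_traces.csv"
    traces.to_csv(tr_path, index=False, float_format="%.6g")

    roi = pd.DataFrame({"cell_id": ids,
                        "x_um": rec.positions[:, 0],
                        "y_um": rec.positions[:, 1]})
    roi_path = out_dir / f"{stem}_roi.csv"
    roi.to_csv(roi_path, index=False, float_format="%.4f")

    meta = {"capsule_id": rec.capsule_id, "t_stim": rec.t_stim,
            "frame_dt": rec.frame_dt, "cataract_type": rec.cataract_type,
            "cataract_grade": rec.cataract_grade}
    meta_path = out_dir / f"{stem}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1))

    paths = {"traces": tr_path, "roi": roi_path, "meta": meta_path}
    if rec.ground_truth is not None:
        gt = rec.ground_truth
        truth = {
            "onset_delay": [None if math.isnan(v) else v for v in gt.onset_delay],
            "t_on": [None if math.isnan(v) else v for v in gt.t_on],
            "is_responder": gt.is_responder.tolist(),
            "in_spont_cluster": gt.in_spont_cluster.tolist(),
            "is_spontaneous": gt.is_spontaneous.tolist(),
            "spont_event_times": [list(map(float, ev))
                                  for ev in gt.spont_event_times],
        }
        truth_path = out_dir / f"{stem}_truth.json"
        truth_path.write_text(json.dumps(truth))
        paths["truth"] = truth_path
    return paths


def read_capsule(traces_csv: str | Path, roi_csv: str | Path,
                 meta_json: str | Path) -> CapsuleRecording:
    """Load and reconcile one capsule; validates ids and uniform sampling.

    Cell ids must match one-to-one between the trace columns and the ROI
    rows (row order is irrelevant); the time column must be strictly
    increasing and uniform to within 1e-6 s.
    """
    traces = pd.read_csv(traces_csv)
    roi = pd.read_csv(roi_csv)
    meta = json.loads(Path(meta_json).read_text())

    if traces.columns[0] != "time_s":
        raise ValueError("first trace column must be 'time_s'")
    t = traces["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    if np.ptp(dt) > _TIME_TOL:
        raise ValueError("non-uniform sampling in time column")

    trace_ids = list(traces.columns[1:])
    roi_ids = list(roi["cell_id"].astype(str))
    missing_roi = set(trace_ids) - set(roi_ids)
    missing_tr = set(roi_ids) - set(trace_ids)
    if missing_roi or missing_tr:
        raise ValueError(
            f"cell id mismatch: traces without ROI {sorted(missing_roi)}, "
            f"ROI without trace {sorted(missing_tr)}")
    roi = roi.set_index(roi["cell_id"].astype(str)).loc[trace_ids]
    mat = traces[trace_ids].to_numpy(dtype=float).T
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-numeric or non-finite trace values")
    return CapsuleRecording(
        capsule_id=meta["capsule_id"],
        positions=roi[["x_um", "y_um"]].to_numpy(dtype=float),
        traces=mat,
        frame_dt=float(dt.mean()),
        t_stim=float(meta["t_stim"]),
        cataract_type=meta.get("cataract_type", "synthetic"),
        cataract_grade=meta.get("cataract_grade"),
    )


def write_network(g: nx.Graph, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Export a network as GraphML plus a plain edge list."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gml = out_dir / f"{stem}_network.graphml"
    nx.write_graphml(g, gml)
    edges = out_dir / f"{stem}_edges.csv"
    pd.DataFrame(sorted(g.edges()), columns=["cell_id_a", "cell_id_b"]) \
        .to_csv(edges, index=False)
    return {"graphml": gml, "edges": edges}
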