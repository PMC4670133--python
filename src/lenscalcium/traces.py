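"""Per-cell trace preprocessing and event-time extraction.

From a smoothed Fura-2 ratio trace we extract three characteristic times:
t_res (response onset: first sustained threshold crossing after agonist
application), t_max (time of the post-onset maximum), and t_half (first
time after the peak at which the signal has decayed halfway back to the
pre-stimulus baseline).  Derived intervals: dt_act = t_max - t_res
(activation) and dt_deact = t_half - t_max (deactivation).  Cells that
never cross the onset threshold, or whose response amplitude is too
small, are non-responders and carry no event times.  Pre-stimulus
spontaneous activity is flagged with a robust median + k*MAD excursion
rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .synthetic import CapsuleRecording

__all__ = [
    "TraceConfig",
    "CellEventTimes",
    "CapsuleEventSummary",
    "smooth_trace",
    "detect_response",
    "extract_event_times",
    "detect_spontaneous",
    "analyze_capsule",
    "summarize_capsule",
    "events_to_frame",
]

_SD_FLOOR = 1e-6  # ratio units; guards zero-variance baselines


@dataclass(frozen=True)
class TraceConfig:
    """Trace-analysis parameters.

    smooth_m is the adjacency-averaging half-window in samples; the onset
    threshold is baseline_mean + response_k * baseline_SD; spontaneous
    excursions must exceed median + spont_k * MAD for at least
    spont_min_duration consecutive pre-stimulus samples.
    """

    smooth_m: int = 2
    response_k: float = 3.0
    min_amplitude: float = 0.05
    spont_k: float = 4.0
    spont_min_duration: int = 3
    baseline_window: Optional[tuple[float, float]] = None  # default: [0, t_stim)

    def __post_init__(self) -> None:
        if self.smooth_m < 0:
            raise ValueError("smooth_m must be >= 0")
        if self.response_k <= 0:
            raise ValueError("response_k must be > 0")
        if self.spont_min_duration < 1:
            raise ValueError("spont_min_duration must be >= 1")


@dataclass
class CellEventTimes:
    """Characteristic times of one cell; all times in seconds."""

    cell_id: str
    is_responder: bool
    is_spontaneous: bool = False
    t_res: float = math.nan
    t_max: float = math.nan
    t_half: float = math.nan
    peak_value: float = math.nan
    deact_excluded: bool = False  # no half-decay within the recording

    @property
    def dt_act(self) -> float:
        return self.t_max - self.t_res

    @property
    def dt_deact(self) -> float:
        return self.t_half - self.t_max


@dataclass
class CapsuleEventSummary:
    capsule_id: str
    n_cells: int
    n_responders: int
    n_spontaneous: int
    frac_spontaneous: float     # N_S
    mean_dt_act: float          # over responders
    mean_dt_deact: float        # over responders with a half-decay


def smooth_trace(u: np.ndarray, m: int) -> np.ndarray:
    """Adjacency averaging with half-window ``m`` (center sample excluded).

    Interior sample t becomes the mean of the m samples on each side,
    the center value itself contributing nothing.  Near the boundaries
    the window truncates symmetrically to the largest feasible m' <= m.
    m = 0 returns the input unchanged.
    """
    u = np.asarray(u, dtype=float)
    if m == 0:
        return u.copy()
    n = u.size
    if n < 2 * m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    out = np.empty_like(u)
    csum = np.concatenate([[0.0], np.cumsum(u)])
    for t in range(n):
        mp = min(m, t, n - 1 - t)
        if mp == 0:
            out[t] = u[t]
        else:
            s = (csum[t + mp + 1] - csum[t - mp]) - u[t]
            out[t] = s / (2 * mp)
    return out


def _baseline_stats(u: np.ndarray, times: np.ndarray, t_stim: float,
                    window: Optional[tuple[float, float]]) -> tuple[float, float]:
    """Robust baseline location and scale over the pre-stimulus window.

    Median and 1.4826 * MAD (a consistent Gaussian SD estimate) rather
    than mean/SD: spontaneously active cells carry pre-stimulus
    transients that would otherwise inflate both and delay onset
    detection by several seconds.
    """
    if window is None:
        window = (0.0, t_stim)
    t0, t1 = window
    mask = (times >= t0) & (times < t1)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    seg = u[mask]
    med = float(np.median(seg))
    sd = 1.4826 * float(np.median(np.abs(seg - med)))
    return med, max(sd, _SD_FLOOR)


def detect_response(u_smoothed: np.ndarray, times: np.ndarray, t_stim: float,
                    config: TraceConfig = TraceConfig()
                    ) -> tuple[bool, float]:
    """Onset detection: first post-stimulus sustained threshold crossing.

    The threshold is baseline + response_k * baseline scale, where the
    baseline location/scale are the robust estimates of
    :func:`_baseline_stats`, and the signal must stay above it for at
    least 2 consecutive samples.  A cell
    with no such crossing, or with (peak - baseline) < min_amplitude, is
    a non-responder; then ``(False, nan)`` is returned.
    """
    u_smoothed = np.asarray(u_smoothed, dtype=float)
    times = np.asarray(times, dtype=float)
    if not (times[0] <= t_stim <= times[-1]):
        raise ValueError("t_stim outside the recording")
    mean, sd = _baseline_stats(u_smoothed, times, t_stim, config.baseline_window)
    thr = mean + config.response_k * sd
    post = times >= t_stim
    above = u_smoothed >= thr
    idx = np.nonzero(post)[0]
    t_res = math.nan
    for k in idx:
        if above[k] and (k + 1 < above.size and above[k + 1]):
            t_res = float(times[k])
            break
    if math.isnan(t_res):
        return False, math.nan
    peak = float(u_smoothed[post].max())
    if peak - mean < config.min_amplitude:
        return False, math.nan
    return True, t_res


def extract_event_times(u_smoothed: np.ndarray, times: np.ndarray,
                        t_res: float, t_stim: float,
                        config: TraceConfig = TraceConfig(),
                        cell_id: str = "") -> CellEventTimes:
    """Peak and half-decay times for a responding cell.

    t_max is the global maximum at or after t_res; t_half the first time
    after t_max at which the signal falls to baseline + half the response
    amplitude.  If the trace never decays that far, the cell keeps its
    activation times but is excluded from deactivation statistics.
    """
    u_smoothed = np.asarray(u_smoothed, dtype=float)
    times = np.asarray(times, dtype=float)
    mean, _ = _baseline_stats(u_smoothed, times, t_stim, config.baseline_window)
    after = times >= t_res
    seg = u_smoothed[after]
    seg_t = times[after]
    k_max = int(np.argmax(seg))
    t_max = float(seg_t[k_max])
    peak = float(seg[k_max])
    half_level = mean + 0.5 * (peak - mean)
    decay = seg[k_max:] <= half_level
    ev = CellEventTimes(cell_id=cell_id, is_responder=True, t_res=float(t_res),
                        t_max=t_max, peak_value=peak)
    if decay.any():
        ev.t_half = float(seg_t[k_max + int(np.argmax(decay))])
    else:
        ev.deact_excluded = True
    return ev


def detect_spontaneous(u_smoothed: np.ndarray, times: np.ndarray, t_stim: float,
                       config: TraceConfig = TraceConfig()) -> bool:
    """Pre-stimulus activity flag.

    True iff the pre-stimulus segment contains an excursion above
    median + spont_k * MAD lasting at least spont_min_duration
    consecutive samples.  MAD is the raw median absolute deviation with
    a small floor for flat baselines.
    """
    u_smoothed = np.asarray(u_smoothed, dtype=float)
    times = np.asarray(times, dtype=float)
    pre = u_smoothed[times < t_stim]
    if pre.size < 30:
        raise ValueError("pre-stimulus segment too short (< 30 samples)")
    med = float(np.median(pre))
    mad = max(float(np.median(np.abs(pre - med))), _SD_FLOOR)
    above = pre > med + config.spont_k * mad
    run = 0
    for a in above:
        run = run + 1 if a else 0
        if run >= config.spont_min_duration:
            return True
    return False


def analyze_capsule(rec: CapsuleRecording,
                    config: TraceConfig = TraceConfig()) -> list[CellEventTimes]:
    """Smooth every trace and extract per-cell events and flags."""
    times = rec.times
    out: list[CellEventTimes] = []
    for i, cid in enumerate(rec.cell_ids):
        u = smooth_trace(rec.traces[i], config.smooth_m)
        spont = detect_spontaneous(u, times, rec.t_stim, config)
        is_resp, t_res = detect_response(u, times, rec.t_stim, config)
        if is_resp:
            ev = extract_event_times(u, times, t_res, rec.t_stim, config, cell_id=cid)
        else:
            ev = CellEventTimes(cell_id=cid, is_responder=False)
        ev.is_spontaneous = spont
        out.append(ev)
    return out


def summarize_capsule(events: list[CellEventTimes],
                      capsule_id: str = "") -> CapsuleEventSummary:
    """Capsule-level summary; non-responders are excluded from all means."""
    n = len(events)
    resp = [e for e in events if e.is_responder]
    n_spont = sum(e.is_spontaneous for e in events)
    dt_act = [e.dt_act for e in resp]
    dt_deact = [e.dt_deact for e in resp if not e.deact_excluded]
    return CapsuleEventSummary(
        capsule_id=capsule_id,
        n_cells=n,
        n_responders=len(resp),
        n_spontaneous=n_spont,
        frac_spontaneous=n_spont / n if n else math.nan,
        mean_dt_act=float(np.mean(dt_act)) if dt_act else math.nan,
        mean_dt_deact=float(np.mean(dt_deact)) if dt_deact else math.nan,
    )


def events_to_frame(events: list[CellEventTimes]) -> pd.DataFrame:
    """Per-cell events as a tidy DataFrame (the events CSV layout)."""
    rows = []
    for e in events:
        rows.append({
            "cell_id": e.cell_id,
            "t_res": e.t_res,
            "t_max": e.t_max,
            "t_half": e.t_half,
            "dt_act": e.dt_act if e.is_responder else math.nan,
            "dt_deact": e.dt_deact if (e.is_responder and not e.deact_excluded)
            else math.nan,
            "is_responder": e.is_responder,
            "is_spontaneous": e.is_spontaneous,
            "peak_value": e.peak_value,
        })
    return pd.DataFrame(rows)
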