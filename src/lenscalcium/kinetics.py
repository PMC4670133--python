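"""Capsule-level activation and deactivation kinetics.

The activation curve is the cumulative fraction of responding cells vs
the delay from the first event (t_res for activation, t_half for
deactivation).  The speed S is the slope between the curve's 20% and
80% crossings: S = 0.6 / (t80 - t20), in fraction of cells per second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ActivationCurve", "SpeedEstimate", "build_curve", "estimate_speed"]


@dataclass
class ActivationCurve:
    delays: np.ndarray     # s, sorted, relative to the first event
    fraction: np.ndarray   # cumulative fraction in (0, 1]
    kind: str              # "activation" | "deactivation"


@dataclass
class SpeedEstimate:
    speed: float           # fraction per s
    t20: float
    t80: float
    kind: str
    simultaneous: bool = False  # >= 60% of cells within one step


def build_curve(times: np.ndarray, kind: str = "activation") -> ActivationCurve:
    """Empirical cumulative activated/deactivated fraction vs delay."""
    t = np.sort(np.asarray(times, dtype=float))
    t = t[np.isfinite(t)]
    if t.size < 2:
        raise ValueError("need >= 2 finite event times")
    delays = t - t[0]
    frac = np.arange(1, t.size + 1) / t.size
    # collapse ties: keep the last (highest) fraction at each delay
    uniq, idx = np.unique(delays[::-1], return_index=True)
    frac = frac[::-1][idx]
    return ActivationCurve(delays=uniq, fraction=frac, kind=kind)


def _crossing(delays: np.ndarray, frac: np.ndarray, q: float) -> float:
    """First delay at which the step curve reaches fraction q.

    Linear interpolation between consecutive event points when the curve
    jumps over q; exact step values are returned as-is.
    """
    k = int(np.argmax(frac >= q))
    if frac[k] == q or k == 0:
        return float(delays[k])
    f0, f1 = frac[k - 1], frac[k]
    d0, d1 = delays[k - 1], delays[k]
    return float(d0 + (q - f0) / (f1 - f0) * (d1 - d0))


def estimate_speed(curve: ActivationCurve,
                   frame_dt: float = 1.0) -> SpeedEstimate:
    """20%-to-80% slope of the cumulative curve.

    When the 20% and 80% crossings coincide (a mass jump — most cells
    simultaneous to within one frame) the speed is reported as the cap
    0.6 / frame_dt with the simultaneity flag set.
    """
    if curve.fraction[-1] < 0.8:
        raise ValueError("curve never reaches 80%")
    t20 = _crossing(curve.delays, curve.fraction, 0.2)
    t80 = _crossing(curve.delays, curve.fraction, 0.8)
    if t80 > t20:
        return SpeedEstimate(speed=0.6 / (t80 - t20), t20=t20, t80=t80,
                             kind=curve.kind)
    return SpeedEstimate(speed=0.6 / frame_dt, t20=t20, t80=t80,
                         kind=curve.kind, simultaneous=True)
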