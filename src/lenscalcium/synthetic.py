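"""Synthetic lens-capsule recordings.

Generates seed-reproducible Fura-2 ratio recordings of a near-confluent
lens epithelial cell (LEC) monolayer responding to an agonist: cells on a
jittered hexagonal lattice, spatially correlated response-onset delays
(Gaussian random field with exponential covariance), double-exponential
Ca2+ transients, clustered pre-stimulus spontaneous activity, and a
minority of non-responders.  A single ``severity`` knob degrades onset
synchrony (larger delay dispersion, shorter spatial correlation length)
while leaving single-cell kinetics untouched, emulating how cataract
progression affects collective but not single-cell signaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "CapsuleRecording",
    "generate_positions",
    "generate_onsets",
    "synthesize_traces",
    "generate_capsule",
    "generate_cohort",
    "pulse_peak_time",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic capsule recording.

    Lengths are in micrometres, times in seconds, trace values in
    dimensionless 360/380 ratio units.
    """

    n_cells: int = 225
    field_size: float = 320.0
    cell_spacing: float = 20.0
    jitter_sd: float = 2.0
    t_total: float = 600.0
    frame_dt: float = 1.0
    t_stim: float = 120.0
    onset_corr_length: float = 50.0   # lambda: spatial corr. length of delays
    onset_delay_sd: float = 3.0       # sigma_d
    rise_tau: float = 4.0
    decay_tau: float = 30.0
    amp_mean: float = 0.5
    amp_sd: float = 0.1
    baseline: float = 1.0
    noise_sd: float = 0.02
    frac_nonresponder: float = 0.05
    spont_cluster_count: int = 2
    spont_cluster_radius: float = 40.0
    spont_rate: float = 1.0           # events/min per spontaneous cell
    spont_decay_tau: float = 5.0      # decay of spontaneous transients (s)
    spont_rise_factor: float = 1.5    # rise_tau multiplier for spontaneous responders
    spont_extra_delay: float = 3.0    # extra mean onset delay (s) for spontaneous responders
    severity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be > 0")
        if not (0 <= self.t_stim < self.t_total):
            raise ValueError("t_stim must lie inside the recording")
        for name in ("field_size", "cell_spacing", "t_total",
                     "onset_corr_length", "rise_tau", "decay_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("frac_nonresponder", "severity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("jitter_sd", "onset_delay_sd", "amp_sd", "noise_sd",
                     "spont_rate", "spont_cluster_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def effective_delay_sd(self) -> float:
        """Onset delay SD after severity scaling: sigma_d * (1 + 2s)."""
        return self.onset_delay_sd * (1.0 + 2.0 * self.severity)

    @property
    def effective_corr_length(self) -> float:
        """Correlation length after severity scaling: lambda * (1 - 0.8s)."""
        return self.onset_corr_length * (1.0 - 0.8 * self.severity)


@dataclass
class GroundTruth:
    """True per-cell generative quantities (synthetic capsules only)."""

    onset_delay: np.ndarray          # d_i (s), relative to t_stim; NaN for non-responders
    t_on: np.ndarray                 # absolute onset time (s); NaN for non-responders
    is_responder: np.ndarray         # bool
    in_spont_cluster: np.ndarray     # bool: within radius of a cluster center
    is_spontaneous: np.ndarray       # bool: fired >= 1 pre-stimulus event
    amplitude: np.ndarray            # A_i; NaN for non-responders
    spont_event_times: list          # per-cell list of pre-stimulus event times
    cluster_centers: np.ndarray      # (k, 2)


@dataclass
class CapsuleRecording:
    """One capsule: positions, ratio traces and metadata.

    ``traces`` is (n_cells, n_frames); frame k is at time k * frame_dt.
    """

    capsule_id: str
    positions: np.ndarray            # (n_cells, 2) um
    traces: np.ndarray               # (n_cells, n_frames)
    frame_dt: float
    t_stim: float
    cataract_type: str = "synthetic"
    cataract_grade: int | None = None
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.traces = np.asarray(self.traces, dtype=float)
        if self.positions.shape[0] != self.traces.shape[0]:
            raise ValueError("positions and traces disagree on cell count")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_dt

    @property
    def cell_ids(self) -> list:
        return [f"cell_{i:04d}" for i in range(self.n_cells)]


def pulse_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time from onset to peak of the double-exponential pulse.

    The pulse A*(1 - exp(-t/tr))*exp(-t/td) peaks at tr*ln(1 + td/tr).
    """
    return rise_tau * math.log(1.0 + decay_tau / rise_tau)


def _hex_lattice(field_size: float, spacing: float) -> np.ndarray:
    """All hexagonal-lattice points inside the square [0, L]^2."""
    row_h = spacing * math.sqrt(3.0) / 2.0
    pts = []
    n_rows = int(field_size / row_h) + 1
    n_cols = int(field_size / spacing) + 2
    for r in range(n_rows):
        y = r * row_h
        x0 = (spacing / 2.0) if (r % 2) else 0.0
        for c in range(n_cols):
            x = x0 + c * spacing
            if x <= field_size and y <= field_size:
                pts.append((x, y))
    return np.asarray(pts, dtype=float)


def generate_positions(config: GeneratorConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Place ``n_cells`` on a jittered hexagonal lattice inside the field.

    Jitter displacements are Gaussian with the radius clipped at
    2 * jitter_sd, so the minimum pairwise distance is guaranteed to stay
    above cell_spacing - 4 * jitter_sd.  Raises ``ValueError`` when the
    field cannot host the requested cell count at the given spacing.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lattice = _hex_lattice(config.field_size, config.cell_spacing)
    if lattice.shape[0] < config.n_cells:
        raise ValueError(
            f"field of {config.field_size} um side fits only "
            f"{lattice.shape[0]} cells at {config.cell_spacing} um spacing; "
            f"{config.n_cells} requested")
    # most central lattice sites first -> compact, near-confluent patch
    center = lattice.mean(axis=0)
    order = np.argsort(np.linalg.norm(lattice - center, axis=1), kind="stable")
    pos = lattice[order[: config.n_cells]].copy()
    if config.jitter_sd > 0:
        disp = rng.normal(0.0, config.jitter_sd, size=pos.shape)
        r = np.linalg.norm(disp, axis=1, keepdims=True)
        cap = 2.0 * config.jitter_sd
        scale = np.where(r > cap, cap / np.maximum(r, 1e-300), 1.0)
        pos = pos + disp * scale
    np.clip(pos, 0.0, config.field_size, out=pos)
    return pos


def generate_onsets(positions: np.ndarray, config: GeneratorConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sample spatially correlated response delays and responder flags.

    Delays are a Gaussian random field with covariance
    sigma_d^2 * exp(-|r_i - r_j| / lambda), shifted so the earliest
    responder is at delay 0.  ``severity`` inflates sigma_d and shrinks
    lambda (see :class:`GeneratorConfig`).  Returns ``(delays, is_responder)``
    with delays NaN for non-responders.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n == 0:
        raise ValueError("positions must be non-empty")
    sd = config.effective_delay_sd
    lam = max(config.effective_corr_length, 1e-9)
    if sd == 0.0:
        raw = np.zeros(n)
    else:
        diff = positions[:, None, :] - positions[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))
        cov = sd ** 2 * np.exp(-dist / lam)
        cov[np.diag_indices(n)] += 1e-10 * sd ** 2  # Cholesky jitter
        chol = np.linalg.cholesky(cov)
        raw = chol @ rng.standard_normal(n)
    n_nonresp = int(round(config.frac_nonresponder * n))
    is_responder = np.ones(n, dtype=bool)
    if n_nonresp > 0:
        is_responder[rng.choice(n, size=n_nonresp, replace=False)] = False
    delays = np.full(n, np.nan)
    if is_responder.any():
        resp_raw = raw[is_responder]
        delays[is_responder] = resp_raw - resp_raw.min()
    return delays, is_responder


def _double_exp(t: np.ndarray, t_on: float, amp: float,
                rise_tau: float, decay_tau: float) -> np.ndarray:
    """Double-exponential pulse normalized so its peak equals ``amp``."""
    tp = pulse_peak_time(rise_tau, decay_tau)
    peak = (1.0 - math.exp(-tp / rise_tau)) * math.exp(-tp / decay_tau)
    dt = t - t_on
    out = np.zeros_like(t, dtype=float)
    m = dt >= 0
    out[m] = (amp / peak) * (1.0 - np.exp(-dt[m] / rise_tau)) \
        * np.exp(-dt[m] / decay_tau)
    return out


def synthesize_traces(positions: np.ndarray,
                      onsets: tuple[np.ndarray, np.ndarray],
                      config: GeneratorConfig,
                      rng: np.random.Generator | None = None,
                      capsule_id: str = "synthetic") -> CapsuleRecording:
    """Build ratio traces from positions and onset delays.

    Responders get a double-exponential transient at t_stim + delay on top
    of the baseline; cells inside spontaneous clusters additionally fire
    shared-timing pre-stimulus transients (Poisson, amplitude 0.4 * A,
    per-cell +-1 s timing jitter); non-responders are baseline + noise.
    Spontaneous responders are slower: rise_tau is scaled by
    ``spont_rise_factor`` and their onset shifted by ``spont_extra_delay``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    positions = np.asarray(positions, dtype=float)
    delays, is_responder = onsets
    delays = np.asarray(delays, dtype=float)
    is_responder = np.asarray(is_responder, dtype=bool)
    n = positions.shape[0]
    t = np.arange(0.0, config.t_total, config.frame_dt)

    # spontaneous clusters: random centers in the field, members by radius
    k = config.spont_cluster_count
    centers = rng.uniform(0.0, config.field_size, size=(k, 2)) if k > 0 \
        else np.empty((0, 2))
    in_cluster = np.zeros(n, dtype=bool)
    for c in centers:
        in_cluster |= np.linalg.norm(positions - c, axis=1) <= config.spont_cluster_radius

    amps = np.maximum(rng.normal(config.amp_mean, config.amp_sd, size=n),
                      0.2 * config.amp_mean)
    # per-cluster shared pre-stimulus event times (Poisson in [0, t_stim))
    cluster_events: list[np.ndarray] = []
    for _ in range(k):
        mean_n = config.spont_rate * config.t_stim / 60.0
        n_ev = rng.poisson(mean_n)
        cluster_events.append(np.sort(rng.uniform(0.0, max(config.t_stim - 10.0, 0.0),
                                                  size=n_ev)))

    traces = np.full((n, t.size), config.baseline)
    spont_event_times: list[list[float]] = [[] for _ in range(n)]
    is_spont = np.zeros(n, dtype=bool)
    t_on = np.full(n, np.nan)

    for i in range(n):
        if in_cluster[i]:
            for ci, c in enumerate(centers):
                if np.linalg.norm(positions[i] - c) <= config.spont_cluster_radius:
                    for ev in cluster_events[ci]:
                        ev_i = float(np.clip(ev + rng.uniform(-1.0, 1.0),
                                             0.0, config.t_stim - 1.0))
                        traces[i] += _double_exp(t, ev_i, 0.4 * amps[i],
                                                 config.rise_tau,
                                                 config.spont_decay_tau)
                        spont_event_times[i].append(ev_i)
            if spont_event_times[i]:
                is_spont[i] = True
        if is_responder[i]:
            rise = config.rise_tau
            onset = config.t_stim + delays[i]
            if is_spont[i]:
                rise *= config.spont_rise_factor
                onset += rng.exponential(config.spont_extra_delay) \
                    if config.spont_extra_delay > 0 else 0.0
            t_on[i] = onset
            traces[i] += _double_exp(t, onset, amps[i], rise, config.decay_tau)

    if config.noise_sd > 0:
        traces = traces + rng.normal(0.0, config.noise_sd, size=traces.shape)
    # ratio signals are strictly positive
    np.clip(traces, 1e-6, None, out=traces)

    gt = GroundTruth(
        onset_delay=np.where(is_responder, t_on - config.t_stim, np.nan),
        t_on=t_on,
        is_responder=is_responder,
        in_spont_cluster=in_cluster,
        is_spontaneous=is_spont,
        amplitude=np.where(is_responder, amps, np.nan),
        spont_event_times=spont_event_times,
        cluster_centers=centers,
    )
    return CapsuleRecording(
        capsule_id=capsule_id,
        positions=positions,
        traces=traces,
        frame_dt=config.frame_dt,
        t_stim=config.t_stim,
        cataract_type="synthetic",
        cataract_grade=None,
        ground_truth=gt,
    )


def generate_capsule(config: GeneratorConfig,
                     capsule_id: str = "synthetic") -> CapsuleRecording:
    """End-to-end generation of one capsule from a config (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    pos = generate_positions(config, rng)
    onsets = generate_onsets(pos, config, rng)
    return synthesize_traces(pos, onsets, config, rng, capsule_id=capsule_id)


def generate_cohort(n_capsules_per_group: int | Sequence[int],
                    severity_by_group: dict[str, float],
                    base_config: GeneratorConfig = GeneratorConfig(),
                    seed: int = 0) -> list[CapsuleRecording]:
    """Generate a labeled cohort of capsules, one severity per group.

    Per-capsule seeds are derived deterministically from ``seed`` via
    ``np.random.SeedSequence.spawn``, so the same master seed reproduces
    the cohort trace-for-trace.  Group labels are stored in
    ``cataract_type``.
    """
    if not severity_by_group:
        raise ValueError("severity_by_group must name at least one group")
    groups = list(severity_by_group)
    if isinstance(n_capsules_per_group, int):
        counts = [n_capsules_per_group] * len(groups)
    else:
        counts = list(n_capsules_per_group)
        if len(counts) != len(groups):
            raise ValueError("one capsule count per group required")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(sum(counts))
    capsules = []
    idx = 0
    for g, cnt in zip(groups, counts):
        for j in range(cnt):
            sub_seed = int(children[idx].generate_state(1)[0] % (2 ** 31))
            idx += 1
            cfg = replace(base_config, severity=severity_by_group[g], seed=sub_seed)
            cap = generate_capsule(cfg, capsule_id=f"{g}_{j:02d}")
            cap.cataract_type = g
            capsules.append(cap)
    return capsules
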