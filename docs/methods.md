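# Methods

This note documents the models, estimators and numerical choices behind
`lenscalcium`, and what the synthetic-data validation does and does not
establish about real recordings.

## Synthetic recordings

One generated capsule emulates a Fura-2 360/380 recording of a
near-confluent LEC monolayer at 1 frame/s with agonist stimulation at
`t_stim`.

**Geometry.** `n_cells` sites of a hexagonal lattice (pitch
`cell_spacing`, default 20 μm ≈ an LEC diameter) inside a square field
(default 320 μm, a 40× field of view), most central sites first, each
displaced by a Gaussian jitter whose radius is truncated at
2·`jitter_sd`. The truncation makes the minimum pairwise distance
≥ `cell_spacing` − 4·`jitter_sd` a hard guarantee rather than a
probabilistic one. If the field cannot host the requested count the
generator fails loudly rather than overlap cells.

**Onset delays.** Responder onsets are `t_stim` + dᵢ with d a Gaussian
random field over the cell positions, covariance
σ_d²·exp(−|rᵢ−rⱼ|/λ) (defaults σ_d = 3 s, λ = 50 μm), sampled by dense
Cholesky factorization (n ≤ a few hundred, so O(n³) is immaterial; a
1e-10·σ_d² diagonal jitter stabilizes the factorization) and shifted so
the earliest responder sits at delay 0. The exponential-covariance field
is the simplest stationary model that makes nearby cells respond
together. A fraction `frac_nonresponder` (default 5%) of cells is
flagged non-responsive and receives baseline + noise only.

**Severity.** A single scalar s ∈ [0,1] rescales σ_d → σ_d·(1+2s) and
λ → λ·(1−0.8s). It therefore degrades *collective* properties — onset
synchrony, spatial grouping, network density — while leaving single-cell
kinetics (rise/decay constants, amplitudes) untouched. This is the
generative encoding of the empirical dissociation the pipeline is meant
to detect: disease severity shows in population measures, not in
per-cell transient shape.

**Transients.** A responder's trace is baseline + A·g(t−t_on) + noise
with g the double-exponential pulse (1−e^(−t/τ_r))·e^(−t/τ_d)
normalized to unit peak, so `amp_mean`/`amp_sd` (0.5 ± 0.1 ratio units)
are actual peak-above-baseline amplitudes; τ_r = 4 s, τ_d = 30 s,
baseline 1.0, noise SD 0.02. The pulse peaks at
τ_r·ln(1 + τ_d/τ_r) after onset, which the tests use as a closed form.

**Spontaneous activity.** `spont_cluster_count` centers are placed
uniformly in the field; every cell within `spont_cluster_radius`
(40 μm) is a cluster member. Each cluster draws Poisson pre-stimulus
event times (default 1 event/min per cell) shared by its members up to
±1 s per-cell jitter, with amplitude 0.4·A and a shorter decay
(`spont_decay_tau` = 5 s): spontaneous events appear in the data as
discrete, brief, locally synchronized transients occupying a minority of
the pre-stimulus window. Spontaneous responders are also slower to
respond to the agonist: their rise time is scaled by
`spont_rise_factor` (1.5, giving larger Δt_act) and their onset shifted
by an exponential extra delay (mean `spont_extra_delay` = 3 s). Ground
truth records both cluster membership and whether a cell actually fired
≥ 1 event; detector sensitivity is scored against cells that fired.

**Determinism.** (config, seed) fully determines every array. Cohorts
derive per-capsule seeds from the master seed via
`numpy.random.SeedSequence.spawn`, so a cohort is reproducible
trace-for-trace.

**What the generator does not model.** No IP₃/ER biophysics, no Ca²⁺
wave propagation (co-activation arises only through the static delay
field), no baseline drift or photobleaching, no cell-size or shape
heterogeneity, no raw images. Passing tests therefore demonstrate that
the estimators recover the *statistical structure they assume*; they do
not validate the pipeline against optical artifacts or mechanistically
propagating waves in real recordings.

## Trace analysis

**Smoothing.** Adjacency averaging with half-window m (default 2 s):
the smoothed value at t is the mean of the m samples on each side, the
center sample excluded. Near the edges the window truncates
symmetrically to the largest feasible m′ ≤ m. The exclusion of the
center sample is harmless for slowly varying signals and is kept as the
defining form of the filter.

**Onset.** t_res is the first post-stimulus time at which the smoothed
trace exceeds baseline + k·scale (k = 3) and stays above it for ≥ 2
samples. Baseline location and scale are the *median* and 1.4826·MAD of
the pre-stimulus window (floored at 10⁻⁶ to guard flat traces). Robust
estimates matter: with mean/SD, the pre-stimulus transients of
spontaneously active cells inflate the threshold and delay their
detected onsets by a median 3–7 s; with median/MAD the pooled onset
error is ≤ 2 s for ≥ 95% of responders (measured against generator
ground truth, 20 capsules). Cells with no crossing or with response
amplitude < `min_amplitude` (0.05 ratio units) are non-responders,
matching the ~5% exclusion typical of these recordings.

**Peak and half-decay.** t_max is the global maximum at or after t_res;
t_half the first time after t_max at which the trace falls to
baseline + (peak − baseline)/2, "baseline" again being the pre-stimulus
median. Traces that never decay to half within the recording keep their
activation statistics but are excluded from deactivation statistics.

**Spontaneous flag.** A cell is spontaneously active iff its
pre-stimulus segment contains an excursion above median + 4·MAD (raw
MAD here; ≈ 2.7 Gaussian SDs) lasting ≥ 3 consecutive samples. At
defaults this achieves sensitivity ≈ 0.93 at FPR < 0.01 on synthetic
ground truth; the residual misses are cells sitting in two overlapping
event clusters, whose doubled event load re-inflates the MAD.

## Population statistics

**Correlation.** Window correlation is plain Pearson of the two
segments in [T−Δt, T+Δt] (Δt = 10 s, step 5 s; windows overlapping the
recording edge are dropped so all are equal length). Any consistent
normalization of the cross-product sum cancels in the ratio, so the
scale-free Pearson form is used directly. Pairs with a constant segment
are skipped (not zeroed, which would bias R_avg downward) and tallied.
All population analyses run on the smoothed traces, consistent with the
per-cell stage. R_avg(I) bins the full-series pairwise correlations by
distance into half-open 25 μm bins up to the 95th percentile of
pairwise distances; stderr = SD/√n_pairs. The distance-decay of
R_avg(I) is a weak per-capsule signal: beyond ~3 correlation lengths
the model predicts a flat profile, so the property test fits the slope
over bins within 3λ, where the sign is stable; cohort-level statements
use the median over capsules.

**Kinetics.** The activation (deactivation) curve is the empirical
cumulative fraction of responders vs t_res (t_half) delay from the
first event. The 20%/80% crossings are read off the step curve with
linear interpolation between consecutive event points (exact step
values returned as-is), and S = 0.6/(t₈₀−t₂₀). If ≥ 60% of cells fall
within one frame the speed is capped at 0.6/frame_dt with a
simultaneity flag instead of dividing by zero.

**Grouping.** For each distance bin, Δτₓ(I) averages over cells the
per-cell mean |τᵢ−τⱼ| to bin neighbors; cells with no neighbor in a bin
are excluded from that bin's outer average (avoiding 0/0). Profiles are
normalized per capsule by their minimum bin value (idempotent;
zero-minimum profiles are left raw with a warning), then summarized by
the OLS slope over bin centers. Group curves are capsule-normalized
first, then averaged.

**Networks.** Nodes are responders; an edge requires
|t_res,i − t_res,j| ≤ 1 s (inclusive) *and* distance < 30 μm (strict).
k_avg = 2|E|/N; C_avg is the Watts–Strogatz mean local clustering with
Cᵢ = 0 for degree < 2; E_G is the mean inverse shortest-path length
over ordered pairs with 1/∞ = 0 for disconnected pairs. Communities
come from Louvain modularity maximization; because the algorithm is
order-dependent, the community count and modularity are averaged over
20 seeded restarts, and isolated nodes count as singleton communities,
keeping n_c/N in [1/N, 1]. Every metric is verified against brute-force
references (explicit triangle counting, all-pairs BFS, exhaustive
partition search for N ≤ 8) in the tests.

**Cohort comparison.** One-way fixed-effects ANOVA per variable with
Bonferroni correction applied within a comparison family (the set of
variables passed to one `run_full_comparison` call), significance at
P ≤ 0.05. Degenerate all-identical inputs give F = 0, p = 1 rather
than NaN. The spontaneous-vs-quiet cell comparison divides each cell's
Δt_act (Δt_deact) by its capsule mean before pooling, excluding
capsules without spontaneous cells.

## Validation design and problem sizes

The test suite and the acceptance script validate at a compact capsule
size — 120 cells on a 260 μm field, 400 s recordings with stimulation
at 100 s, cohorts of 10 + 10 capsules (severity 0.1 vs 0.7) — chosen so
the full chain exercises every stage in seconds while keeping per-stage
statistics (≈ 7,000 cell pairs, ≈ 114 network nodes per capsule) large
enough for stable medians. Detection-recovery rates pool 20 seeded
capsules. Null calibration permutes the labels of a 16-capsule
single-severity cohort 500 times and checks each contrast's rejection
rate against 0.05 plus binomial Monte-Carlo slack.

## Known limitations

- The onset detector assumes a single evoked transient; multi-peaked
  post-stimulus responses are summarized by their global maximum.
- Δt_act carries a small measurement bias (~0.1 s at default kinetics,
  ≈ 1%) from the interaction of smoothing lookahead with threshold
  crossing; it is identical across severity groups and does not affect
  contrasts.
- The spontaneous-flag and grouping statistics treat the pre- and
  post-stimulus regimes as cleanly separated by `t_stim`; protocols
  with slow agonist wash-in would blur that boundary.
- Capsule-level inference uses plain one-way ANOVA, as is conventional
  for this assay; no hierarchical modeling of cell-within-capsule
  variance is attempted.
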