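# lenscalcium

Spatio-temporal analysis of Ca²⁺ signaling in lens epithelial cell (LEC)
monolayers.

Anterior lens capsules excised during cataract surgery carry a monolayer
of LECs whose intracellular Ca²⁺ dynamics can be recorded with Fura-2
ratiometric imaging (360/380 nm, 1 frame/s). After agonist stimulation
(acetylcholine), every cell produces a rise-and-decay Ca²⁺ transient, and
the *collective* organization of those transients — how synchronously
neighboring cells respond, how tightly responses cluster in space, how
connected the inferred intercellular communication network is — carries
information about tissue health that single-cell kinetics do not.
`lenscalcium` implements that analysis chain for researchers working with
per-ROI ratio traces, together with a synthetic-recording generator that
reproduces the statistical structure of such experiments, so the whole
pipeline is testable without patient data.

## The analysis

For each cell *i* with ratio trace *uᵢ(t)* (adjacency-smoothed, the
center sample excluded from the averaging window):

- **Characteristic times** — response onset *t*ᵣₑₛ (first sustained
  crossing of a robust baseline threshold after stimulation), peak time
  *t*ₘₐₓ, and half-decay time *t*₁⁄₂; activation and deactivation
  intervals Δ*t*ₐ꜀ₜ = *t*ₘₐₓ − *t*ᵣₑₛ and Δ*t*ₙₑₐ꜀ₜ = *t*₁⁄₂ − *t*ₘₐₓ.
  Non-responders (~5%) are excluded; pre-stimulus spontaneous activity is
  flagged by a median + k·MAD excursion rule.
- **Coherence** — sliding-window (Δt = 10 s, step 5 s) average pairwise
  Pearson correlation R_avg(T), and the full-series correlation binned by
  intercellular Euclidean distance, R_avg(I).
- **Kinetics** — the cumulative fraction of activated (deactivated) cells
  vs delay from the first event; activation/deactivation speeds
  S_A, S_DA = 0.6 / (t₈₀ − t₂₀) from the curve's 20%/80% crossings.
- **Grouping** — Δτₓ(I): the mean absolute difference of a characteristic
  time between cells as a function of their distance, min-normalized per
  capsule; its slope measures spatio-temporal clustering.
- **Networks** — cells activated within 1 s of each other *and* closer
  than 30 μm are linked; the graph is summarized by average degree k_avg,
  Watts–Strogatz clustering C_avg, global efficiency E_G, and the
  relative number of Louvain communities n_c/N (averaged over seeded
  restarts).
- **Cohorts** — per-capsule summaries compared across groups (cataract
  type, severity grade) with one-way ANOVA and Bonferroni correction at
  P ≤ 0.05.

The generator places cells on a jittered hexagonal lattice, draws
spatially correlated onset delays from a Gaussian random field with
exponential covariance (correlation length λ), synthesizes
double-exponential transients with clustered pre-stimulus spontaneous
events, and exposes a `severity` parameter that degrades onset synchrony
(larger delay SD, shorter λ) while leaving single-cell kinetics
untouched.

## Worked example

```python
import lenscalcium as lc
from lenscalcium import cohort as ch
from lenscalcium.pipeline import analyze_cohort

base = lc.GeneratorConfig(n_cells=120, field_size=260, t_total=400, t_stim=100)
caps = lc.generate_cohort(10, {"mild": 0.1, "moderate": 0.7}, base, seed=1)
table, analyses = analyze_cohort(caps)
print(table.groupby("group")[["s_act", "k_avg", "c_avg", "n_c_over_n"]]
      .median().round(3))
for r in ch.run_full_comparison(table, ["s_act", "mean_dt_act"],
                                contrast=("mild", "moderate")):
    print(f"{r.variable}: F={r.f_stat:.2f}, p_adj={r.p_adjusted:.2e}, "
          f"significant={r.significant}")
```

prints

```
          s_act  k_avg  c_avg  n_c_over_n
group
mild      0.092  1.746  0.225       0.310
moderate  0.051  0.807  0.073       0.653
s_act: F=48.09, p_adj=3.52e-06, significant=True
mean_dt_act: F=0.00, p_adj=1.00e+00, significant=False
```

Read: capsules with degraded onset synchrony ("moderate") activate
collectively about half as fast (S_A 0.051 vs 0.092 /s), their
co-activation networks are sparser (k_avg 0.81 vs 1.75), less clustered
(C_avg 0.07 vs 0.23) and more segregated (n_c/N 0.65 vs 0.31), while the
mean single-cell activation time does not differ — the dissociation
between single-cell and collective measures that motivates the
network-level analysis.

The same run is available from the shell:

```
lenscalcium run-all --seed 1 --out out/demo
```

which writes per-capsule event tables, correlation curves, GraphML
networks, the cohort table, the ANOVA comparisons and a run manifest.

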