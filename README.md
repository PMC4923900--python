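# timeclust

Time-course expression profiling for treated-vs-control animal studies:
two-stage polynomial regression on log-transformed time, R² stringency
filtering, and k-means clustering of fitted response profiles with a
data-driven choice of the cluster count.

## The problem

In growth-promoter trials, pigs receive a beta-adrenergic agonist (BA, in
feed) or recombinant growth hormone (GH, injected) and are compared with
feed-only controls across a multi-week time course (days 1, 3, 7, 13, 27;
10 animals per arm per day, 15 at day 27; each animal measured once).
Skeletal-muscle expression is profiled on ~44k-probe microarrays, and the
question is which groups of probes share a temporal response to treatment —
for example a coordinated induction of serine/one-carbon/glycine pathway
genes peaking at day 3.

`timeclust` implements the analysis layer for such studies, together with a
synthetic-study generator that plants known temporal templates so every
stage can be validated end to end without any array data.

## The model

For each probe, each treated arm is fitted against control with a
polynomial in transformed time `T = log t` (the log scale stops days 13 and
27 from dominating the fit):

```
y = β₀ + β₁T + … + β_d T^d + g·(γ₀ + γ₁T + … + γ_d T^d) + ε,
```

where `g` indicates the treated arm and `d = 2` by default. The pipeline
then proceeds in stages:

1. **Global filter** — keep probes whose full model beats intercept-only in
   the ANOVA F-test at `p < 0.05` (raw p by default; BH-FDR optional).
2. **Stepwise refinement** — backward elimination of terms at `α = 0.05`;
   the reduced model's R² is the probe's goodness of fit.
3. **R² stringency** — only probes with `R² ≥ 0.5` (strict tier) or
   `R² ≥ 0.2` (relaxed tier, for weak/noisy responses) enter clustering.
4. **Clustering** — each survivor is represented by its z-scored fitted
   treated-minus-control curve over the day grid; k-means is swept over
   candidate k and the cluster count is chosen by mean silhouette width,
   with a gap-statistic check for the single-cluster case. Fewer than 5
   survivors is reported as the degenerate zero-cluster outcome.

Supporting statistics: per-day Welch differential expression with Venn
overlap counts and the top-N-overlap statistic, plus the animal-phenotype
layer — two-way ANOVA (treatment × time) blocked by pig batch, SED
(`√(MSE·(1/n₁+1/n₂))`), and Dunnett many-to-one comparisons with seeded
Monte-Carlo critical values.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts (small tables under `results/`, full matrices under `scratch/`):

```sh
python analysis/01_simulate_studies.py --seed 1
python analysis/02_fit_timecourse.py   --seed 1
python analysis/03_cluster_profiles.py --seed 1
```

which prints:

```
ba_mimic (ba vs control): 501 significant of 1450; survivors R2>=0.5: 450, R2>=0.2: 450 (median selected-model R2 0.9314)
gh_mimic (gh vs control): 529 significant of 1480; survivors R2>=0.5: 0, R2>=0.2: 471 (median selected-model R2 0.2977)
ba_mimic: k = 9 over 450 surviving probes at R2 >= 0.5
gh_mimic: k = 12 over 471 surviving probes at R2 >= 0.2
gh_mimic at strict R2 >= 0.5: k = 0 (0 survivors) — the zero-cluster outcome
7-probe gene: 7 of 7 probes in one cluster (cluster 3)
```

Reading this: the high-amplitude BA-like cohort (9 planted templates at 5×
the replicate noise) is recovered as 9 clusters at the strict stringency
tier, with all seven probes of the planted multi-probe gene co-clustered.
The weak, transient GH-like cohort (12 templates at 2× an elevated noise
level, deliberately poorly fitted by a quadratic) yields nothing at the
strict tier but 12 clusters at the relaxed tier — the qualitative contrast
between a potent and a weak treatment arm.

The same pipeline is scriptable end to end from a YAML config:

```sh
timeclust run-all --config config.yaml --seed 1
```

and each stage (`simulate`, `regress`, `cluster`, `de`, `phenostats`) is
available as a standalone subcommand; see `timeclust --help`.

## Layout

- `src/timeclust/` — the library: `core` (types, IO, time transform),
  `simulate` (planted-template generator), `regression` (two-stage engine),
  `clustering` (profiles, k-means, optimal k), `de` (per-day Welch, Venn,
  top-N), `phenostats` (blocked ANOVA, SED, Dunnett), `pipeline` + `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — model details, generator design, numerical choices.
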