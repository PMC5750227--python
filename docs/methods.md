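# Methods

This note records the statistical model, the synthetic data generator, and
the numerical conventions used throughout `netspread`, together with the
rationale for each non-obvious choice.

## 1. The propagation model

The quantity of interest is the **disease exposure** of cortical parcel *i*,

```
exposure(i) = Σ_j Conn_ij · Atrophy(j),        j ∈ reservoir
```

where the reservoir is a set of subcortical parcels carrying positive
baseline atrophy z-values and `Conn` is one of two connectomes (functional:
correlation-like weights in [−1, 1]; structural: non-negative sparse
weights).  A purely geometric comparator replaces `Conn_ij` with the
Euclidean centroid distance; under a connectivity-spread mechanism the
distance comparator should correlate *negatively* with thinning (near
parcels thin more) and more weakly than the true mechanism.

Exposure is linear in the atrophy map by construction, which the tests
exploit (additivity/homogeneity properties, and an explicit double-loop
oracle).  The reservoir can be restricted — `basal_ganglia` keeps the
caudate, putamen, pallidum and accumbens bilaterally — and the association
can be scoped to one hemisphere.

### Association and inference

Parcel-level thinning (the vertex t-statistics averaged within parcels) is
related to exposure by the Spearman rank correlation with average ranks for
ties.  Inference is nonparametric throughout:

- **Permutation p.** Thinning values are shuffled over the in-scope parcels
  (`n_perm` draws) and the add-one estimator `p = (k + 1)/(n_perm + 1)` is
  reported, where `k` counts null statistics at least as extreme as the
  observed one.  The add-one form is never exactly zero and is exact for the
  group-invariance null.  The default is **two-sided**; directional
  alternatives (`greater`, `less`) are available, and the distance
  comparator documents its hypothesised negative direction.
- **Bootstrap CI.** A 95% percentile interval from resampling parcels with
  replacement (`n_boot` draws), re-ranking inside every resample.

The two-predictor model (`multivariate_fit`) regresses parcel thinning on
functional and structural exposure jointly by OLS, refusing near-collinear
predictors (|r| > 0.999) with a pointer to single-predictor runs.

### Vertex-wise thinning and cluster correction

`Δt = t1 − t2` (positive = thinning) is modelled per vertex as
`Δt = β0 + βg·[group == PD] + site dummies + age + sex + ε`, fitted for all
vertices at once via the normal equations.  Supra-threshold clusters
(`t ≥ t_threshold`) are connected components of the vertex adjacency graph;
their familywise-corrected p compares each observed extent with the
permutation null of the **maximum** cluster size, with group labels shuffled
*within site strata* so site effects survive the shuffle.  Strata containing
only one group cannot be permuted; they are left fixed and a warning is
raised.  Network summaries average vertex t within each of the seven
intrinsic networks, with a label-permutation p on |mean| and a vertex-level
bootstrap CI.

### Clinical statistics

Cohort-table comparisons are computed from summary statistics (pooled or
Welch t, each verified against scipy on raw data) so that printed tables can
be checked directly; sex uses the Pearson χ² without continuity correction.
Cluster-level thinning within patients is related to CSF markers by partial
correlation (OLS residualisation, df = n − k − 2) and to cognitive change by
OLS of ΔMoCA on four cluster-thinning values plus age and sex, with optional
Bonferroni scaling of the four cluster p-values.

## 2. The synthetic study generator

`synthkit` creates a complete, self-consistent study.  All stages draw from
independent deterministic streams derived from one seed
(`SeedSequence(entropy=seed, spawn_key=(crc32(stage),))`), so datasets are
byte-reproducible and adding a stage never perturbs another.

### Geometry

Cortical centroids are sampled on a left-hemisphere spherical shell (radius
55–75 mm, pushed off the midline) and mirrored to the right; the seven
networks are contiguous polar-angle sectors, mirrored.  Fifteen subcortical
"seats" (thalamus, caudate, putamen, pallidum, accumbens, hippocampus,
amygdala bilaterally, plus brainstem) sit at anatomically plausible
coordinates.  Each cortical parcel owns `vertices_per_parcel` vertices
jittered around its centroid (clamped to its side of the midline) and joined
by a symmetric within-hemisphere k-nearest-neighbour graph.

### Connectomes

With pairwise centroid distance `d` and decay length λ:

- **distance**: `d` itself.
- **functional**: `exp(−d/λ)` within hemisphere and
  `homotopic_factor · exp(−d_mirror/λ)` across hemispheres (`d_mirror` is
  the distance to the mirrored position, reproducing strong homotopic
  coupling), multiplied by symmetric lognormal pairwise gains and by
  per-node lognormal **hub factors** `h_i·h_j`, plus small symmetric noise,
  clipped to [−1, 1] with unit diagonal.
- **structural**: `exp(−d/λ)` with lognormal scatter, cross-hemisphere
  entries scaled by `interhemi_attenuation` (tractography misses
  interhemispheric pathways), the weakest half of off-diagonal entries
  zeroed (sparsity), zero diagonal.

The hub factors matter: pairwise gains average out when exposure sums over
the reservoir, so without per-node structure the functional connectome is
almost a deterministic function of distance and the three models are not
distinguishable.  Hub factors survive the summation and give the functional
exposure identity of its own.

### Thickness panel

`t1 = baseline_mean + subject offset + vertex noise`;
`t2 = t1 − aging_thinning − site offset − [PD]·b·exposure(parcel(v)) +
noise`, floored at 0.05 mm.  A `parcel_effect` override plants an arbitrary
per-parcel effect instead of `b·exposure` (used to generate
distance-mechanism data for the model-selection test).  In the noise-free
limit the group difference in Δt equals the planted effect exactly, which
the tests assert.

### Parameters (defaults) and rationale

| parameter | default | rationale |
|---|---|---|
| `n_cortical`, `n_subcortical` | 448, 15 | modelled parcellation size |
| `n_pd`, `n_hc`, `n_sites` | 105, 57, 4 | modelled cohort |
| `baseline_mean` | 3.055 mm | whole-brain baseline thickness |
| `aging_thinning` | 0.019 mm/yr | normal aging change, both groups |
| `spread_coefficient` b | 0.003 mm per unit exposure | yields ~0.0125 mm mean PD-specific extra thinning, the order of the observed group excess (~0.009 mm/yr) |
| `between_subject_sd`, `within_subject_sd`, `noise_sd` | 0.10, 0.15, 0.03 mm | plausible biological/measurement scatter; noise sized so desk-scale power clears its requirement with margin |
| `site_sd` | 0.02 mm | additive follow-up site offsets, absorbed by the site covariate |
| `distance_decay` λ | 25 mm | connectivity falls off within a hemisphere but is not all-or-nothing |
| `conn_gain_sd`, `conn_hub_sd` | 0.6, 0.5 | pairwise scatter + hub structure (see above) |
| `homotopic_factor` | 0.8 | strong functional homotopic coupling |
| `interhemi_attenuation` | 0.2 | structural interhemispheric under-recovery |
| `atrophy_mean`, `atrophy_sd` | 2.5, 0.8 | positive reservoir z-values (|N|, floored at 0.1) |

All of these were fixed from design-time pilot runs **before** the test
suite was written, and are not adjusted by any test.

### What the generator does *not* emulate

Real cortical folding and surface topology (vertices are jittered point
clouds, not meshes); longitudinal registration error; dropout and missing
visits; realistic spatial autocorrelation of thickness noise; disease
heterogeneity (one global spread coefficient); connectome measurement error
structure beyond lognormal scatter.  Statistical conclusions about the
*pipeline* are unaffected, but effect sizes on synthetic data are not
forecasts for real data.

## 3. Numerical conventions

- **Vertex→parcel mapping** is nearest cortical centroid within the vertex's
  hemisphere; exact ties go to the lowest parcel id (deterministic,
  order-invariant).
- **Spearman** uses average ranks; the implementation is the Pearson
  correlation of ranks, verified to 1e-12 against an independent
  rank-then-correlate oracle and `scipy.stats.spearmanr`.
- **Permutation p** always uses the add-one estimator, so the smallest
  attainable p is `1/(n_perm + 1)`.
- **Cluster correction in the acceptance suite** uses `t_threshold = 1.0` on
  the reduced 400-vertex surface: at threshold 2.0 the surviving clusters
  are single-digit extents, the max-extent null is dominated by ties and the
  test becomes conservative (empirical FWE ≈ 0.02).  Threshold 1.0 reduces
  the discreteness so calibration of the correction itself is measurable
  (FWE ≈ 0.04–0.05).  The pipeline default remains 2.0.
- **Bootstrap coverage testing** uses iid bivariate Gaussian pairs with
  Pearson ρ = 0.5, for which the population Spearman correlation has the
  closed form `(6/π)·asin(ρ/2) ≈ 0.483`, giving an exact target.  The
  per-replicate sample is n = 1000 because the percentile interval's
  two-sided coverage error decays slowly: at n = 200–600 it genuinely covers
  ~93%, a known property of the method, while at n = 1000 coverage is
  ~0.946 — close enough to nominal that the test checks implementation
  correctness rather than the method's small-sample limitation.
- **Whole-brain change** is a paired t-test on subject mean thickness; an
  all-zero change returns t = 0, p = 1, while a constant non-zero change
  (zero variance, undefined t) is flagged `degenerate`.
- `summary.json` outputs are byte-identical across reruns of the same
  configuration; every stochastic routine takes an explicit seed.

## 4. Limitations

Desk-scale Monte Carlo bands are 99% binomial intervals, so roughly 1 in
100 acceptance-suite runs of a *correct* implementation could fail a
calibration check if seeds were varied; the shipped tests fix their seeds
and were verified to pass with margin.  The network-summary permutation
tests |mean| against label exchange, which detects networks whose mean
differs from a random parcel set — networks far *below* a globally positive
field yield p near 1 by design.  The percentile bootstrap undercovers
slightly at small parcel counts (see above); users analysing few parcels
should prefer the permutation p for decisions and read the CI as a rough
uncertainty band.
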