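# Methods

This note documents the statistical models, parameter defaults and
numerical choices implemented in `lakesize`, and the scope and known
gaps of the synthetic-data generator. It makes no empirical claims
beyond what the code computes on its inputs.

## Shell size and per-fauna measures

A species' size is `S = √(height × width)` in millimetres — the side
of the square equal in area to the shell's bounding rectangle. The
estimator is symmetric in height and width and scale-equivariant
(`S(ch, cw) = c·S(h, w)`), so elongate and squat shells are ranked on
a common footing. Heights and widths must be strictly positive.

Each fauna (lake) is summarised by four measures on log10 scale:

| measure | definition | missing when |
|---|---|---|
| `s_mean` | log10 of the arithmetic mean of raw S | never (n ≥ 1) |
| `s_max` | log10 max S | never |
| `s_min` | log10 min S | never |
| `s_range` | log10(max S − min S) | n < 2 or max = min |

`s_range` is the log of the *raw* difference (default
`s_range_mode="raw_difference"`); a `log_difference` variant
(`log10 max − log10 min`, i.e. the size ratio) and a geometric-mean
variant for `s_mean` are available in `RunConfig` for sensitivity
checks. The raw-difference default keeps the range in the same units
as the other measures' antilogs and makes the order-statistic
artifact analysis below directly interpretable.

Pooled log10 sizes are characterised by the bias-corrected sample
skewness G1 and the Shapiro–Wilk test (scipy implementations).

## Inclusion filters

Species without measurable size (missing height or width) are flagged,
not dropped, at load time; the analysis excludes them and reports the
percentage excluded. Lakes retaining fewer than
`min_species_per_lake = 4` measured species are excluded from the
lake-level battery. A named lake (default `"Caspian Sea"`) can be
excluded via `exclude_caspian`; independently, the pipeline always
refits the area regressions for `s_range` and `s_max` without that
lake when it is present (a sensitivity table for a single
physiographic outlier).

## Beta diversity

Faunal distinctness uses family-level incidence (presence/absence of
each gastropod family per lake, measured species only). Pairwise
dissimilarity is Jaccard, `β = (b + c)/(a + b + c)` with `a` shared
families and `b`, `c` the families unique to each lake (computed with
`scipy.spatial.distance.pdist`, cross-checked against a set-based
implementation in the tests). Each lake's predictor value is the mean
of its dissimilarities to all other lakes. Faunas with no families are
rejected rather than silently given β = 1.

## Regression battery

Seven lake-level predictors, in fixed table order: log10 area (km²),
mean Jaccard dissimilarity, log10 distance to the nearest coeval lake
(km), percent endemism, latitude, longitude, log10 measured species
richness. Richness is the count of size-bearing species actually in
the analysis, not the nominal faunal list.

For each size measure the battery fits one multiple OLS on all seven
predictors and seven simple OLS fits (statsmodels, classical
homoskedastic standard errors, two-sided t tests). Designs are checked
for rank deficiency before fitting, and the offending collinear
columns are named in the error. A constant response is reported with
R² = 0 rather than the undefined ratio statsmodels produces.

**Collinearity screening.** VIF_j = 1/(1 − R²_j) from the auxiliary
regression of predictor j on the remaining predictors; exact
collinearity yields `inf` rather than an exception.

**Hierarchical partitioning.** The multiple model's R² is decomposed
into independent contributions I_j: the average, over all k! orders in
which predictors can enter the model, of the R² gain when predictor j
enters. This is computed from the 2^k subset R² values with
factorial weights rather than by enumerating orders, and is guarded at
k ≤ 12. The joint contribution is J_j = marginal R²_j − I_j. Exact
identities, verified in the tests against a brute-force enumeration of
entry orders: ΣI = R²(full model), and I_j + J_j = marginal R²_j.
Percentages reported are 100·I_j/ΣI.

## Resampling null test

The order-statistics problem: `s_max`, `s_min` and `s_range` depend on
the number of species sampled even when all faunas share one size
distribution, so any richness-correlated predictor acquires spurious
slope. The null test asks whether an observed simple-regression slope
exceeds what subsampling alone produces:

1. From each fauna draw `max(2, ⌈0.25·n⌉)` species without
   replacement (fraction and floor configurable).
2. Recompute the four measures and refit the simple regression of each
   measure on the predictor (lakes whose subsampled measure is missing
   are dropped; replicates retaining fewer than 3 lakes are discarded).
3. Repeat 1000 times. `P = #(null slope > observed slope) / repetitions`
   — the literal one-sided count with a strict inequality, so when
   `fraction = 1` every null slope equals the observed slope and P = 0.
   A `two_sided_magnitude` mode (`#(|null| ≥ |observed|)/reps`) is
   available as an alternative convention.

Per-replicate random streams come from
`np.random.SeedSequence(seed).spawn(repetitions)`, keyed only by seed
and replicate index: every measure × predictor combination in a
battery pass sees the *same* subsampled faunas, and a battery P value
equals the corresponding single-test P at the same seed (tested). The
battery runs the test for all four measures against log10 area and
percent endemism.

## Stratified and temporal analyses

- **Within families**: a family enters if, after dropping
  (family, lake) cells with fewer than 2 measured species, it still
  occurs in ≥ 6 lakes. Each family's per-lake size measures are
  regressed on the lake's overall log10 measured richness and log10
  area (the lake-level quantities, not the family's own count, which
  can be constant or degenerate for small families).
- **Species longevity**: occurrences dated with uncertainty > 3 Myr
  are excluded; longevity pools a species' remaining occurrences
  across lakes as max(first_age) − min(last_age); single-horizon
  species are retained at longevity 0. OLS of log10 S on longevity
  requires ≥ 10 records and non-degenerate longevities.
- **Lake age at horizon**: per-(lake, horizon) fauna summaries with the
  lake's age at that horizon (`age_base` − mean occurrence age); OLS
  of each measure on lake age, with a warning when all horizons come
  from a single lake.
- **Clade rank**: OLS of log10 S on rank within a lineage, requiring
  ≥ 3 distinct ranks.

## Synthetic-data generator

`SimConfig`/`generate_dataset` produce a lake table and a species table
with full ground truth, in two modes:

- `sampling_null` (default): every lake draws sizes from one shared
  skew-normal distribution of log10 S. Any richness–size-measure
  association in this mode is the sampling artifact by construction.
- `structured`: the scale of the size distribution additionally widens
  with log10 lake area (`area_scale_coef`, clipped at 0.05 dex), a
  genuine area effect the analysis should detect.

Defaults and their provenance (all overridable):

- **Species–area relationship**: `n = round(c·A^z · 10^ε)`,
  `ε ~ N(0, σ)`, with `c = 7.0`, `z = 0.27`, `σ = 0.35` dex, floored
  at 5 species — calibrated to the bundled lake table's own log–log
  richness-vs-area fit (slope ≈ 0.268, intercept ≈ 0.835, residual
  SD ≈ 0.378).
- **Size distribution**: skew-normal in log10 mm with location 0.55,
  scale 0.45 and shape solved in closed form from the target sample
  skewness `size_g1 = 0.355` (the method-of-moments inversion; the
  attainable |G1| for a skew-normal is < 0.9952, enforced).
- **Geometry**: a species with size S and log10 aspect ratio r gets
  `height = S·10^(r/2)`, `width = S·10^(−r/2)`, so `√(h·w)`
  reconstructs S exactly; r is drawn per family (16 realistic
  freshwater families with distinct size centres and aspect means).
- **Families conditional on size**: family labels are assigned with
  probability ∝ weight × normal density of the species' size under
  the family's size band, preserving the pooled size distribution
  exactly while giving families coherent size ranges.
- **Between-lake composition**: each lake uses a random subset of the
  family list (`family_pool_prob = 0.55`, at least
  min(3, n_families) families) with log-normally jittered weights
  (`family_weight_sd = 1.0`). This makes Jaccard dissimilarity partly
  idiosyncratic rather than a pure function of richness.
- **Endemism**: Bernoulli per species with
  `logit p = −2.0 + 1.5·log10 n + η`, `η ~ N(0, 1.5)` per lake.
- **Ages**: per-lake spans up to 18 Ma; occurrence first/last ages are
  two sorted uniforms within the span; dating uncertainty is
  exponential (mean 1 Myr); three equal-width stratigraphic horizons;
  lineages and clade ranks over endemic species per (lake, family).

`score_recovery` checks a generated dataset against its own ground
truth: the SAR exponent must lie in its 95 % CI, the endemism slope
sign must be recovered, and in structured mode the area effect on
`s_range` must come out positive.

### Known gaps

- Because every lake subsamples family bands from a shared species
  pool, richer faunas still tend to contain more families, leaving a
  residual negative correlation between mean Jaccard dissimilarity and
  richness (typically r ≈ −0.6) that is stronger than in the bundled
  empirical table (r ≈ −0.12). Consequently the synthetic predictor
  set's maximum VIF (typically 3–6) exceeds the bundled table's
  (≈ 2.9). This is an emergent property of the pool construction, not
  a tuned target.
- Lakes are generated independently: there is no spatial
  autocorrelation, and `distance` is drawn independently of the
  coordinates.
- Within-lake size distributions are exchangeable across species; no
  phylogenetic signal in size beyond the family bands.

## Numerical choices

- All RNG flows through `numpy.random.default_rng`/`SeedSequence`;
  derived seeds are taken modulo 2³¹.
- Subset R² values for partitioning use `numpy.linalg.lstsq` on the
  centred design; the battery's reported fits come from statsmodels.
- Exact-identity tests use absolute tolerance 1e-10; distributional
  tests use seed-fixed datasets with tolerances stated per test.

## Limitations

- The resampling null addresses only the richness artifact in the
  simple regressions; it does not correct the multiple model.
- Classical OLS inference assumes homoskedastic, independent errors;
  with ~23 lakes, P values should be read as descriptive.
- Family-level incidence treats families as exchangeable units;
  finer taxonomic resolution would change the beta-diversity scale.
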