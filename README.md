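# lakesize

Regression toolkit for asking what predicts the shell sizes of gastropod
faunas in long-lived lakes — and for checking whether an apparent
predictor is real or a sampling artifact of species richness.

## The scientific problem

Long-lived lakes (lifespans of 10⁵–10⁷ years) accumulate endemic
gastropod faunas whose shell sizes span more than two orders of
magnitude. A natural question is which lake or fauna characteristics —
surface area, isolation, endemism, faunal distinctness, latitude,
richness — predict the size structure of each fauna.

The catch is that three of the four natural per-fauna size statistics
are order statistics. A fauna's maximum size grows, and its minimum
shrinks, with the number of species drawn even if every lake samples
the *same* underlying size distribution. Any predictor correlated with
richness (area, for instance, through the species–area relationship)
will then show a "significant" regression on size range or maximum for
purely combinatorial reasons. This package implements both the
regression battery and the subsample-resampling null test that
separates genuine ecological signal from this richness artifact.

### What it computes

- **Shell size** of a species as `S = √(height × width)` (mm) — the
  side of the square with the same area as the shell's bounding
  rectangle, so elongate and squat shells are comparable.
- **Four per-fauna measures** on log10 scale: mean size `s_mean`,
  maximum `s_max`, minimum `s_min`, and size range
  `s_range = log10(max S − min S)`.
- **Faunal distinctness** as family-level Jaccard dissimilarity between
  lakes, averaged per lake.
- **Regression battery**: for each size measure, one multiple OLS on
  seven lake-level predictors plus seven simple OLS fits, with
  variance-inflation-factor screening and hierarchical partitioning of
  the multiple model's R² into per-predictor independent contributions.
- **Resampling null test**: subsample 25 % of every fauna (minimum 2
  species) without replacement, recompute the measures, refit the
  simple regressions, repeat 1000 times; the P value is the fraction of
  null slopes exceeding the observed one. A high P means the observed
  slope is no steeper than richness-driven sampling alone produces.
- **Stratified follow-ups**: within-family regressions, species
  longevity vs. size, per-horizon fauna age trends, clade-rank trends
  within lineages.
- **Synthetic data generator** with a sampling-null mode (one shared
  size distribution, richness from a species–area power law) and a
  structured mode (size spectra genuinely widen with lake area), plus
  ground-truth recovery scoring.

## Worked example

```python
from lakesize import SimConfig, RunConfig, generate_dataset, run_analysis

ds = generate_dataset(SimConfig(seed=7))          # 23 synthetic lakes
res = run_analysis(ds.species, ds.lakes, RunConfig(seed=7, resample_reps=1000))

print(res.battery[res.battery["size_measure"] == "s_range"][
    ["variable", "mr_slope", "mr_p", "i_pct", "lr_slope", "lr_p", "lr_r2"]
].round(3).to_string(index=False))
```

```
      variable  mr_slope  mr_p  i_pct  lr_slope  lr_p  lr_r2
    log10_area     0.025 0.554 21.685     0.083 0.002  0.383
     mean_beta    -1.007 0.397 27.064    -2.658 0.001  0.429
log10_distance    -0.027 0.728  0.764    -0.029 0.752  0.005
  pct_endemism     0.001 0.652 11.663     0.004 0.021  0.229
      latitude     0.008 0.537  7.276     0.019 0.135  0.103
     longitude    -0.003 0.246 10.214    -0.004 0.175  0.086
log10_richness     0.099 0.559 21.334     0.288 0.002  0.376
```

Lake area, faunal distinctness, endemism and richness all show
individually significant simple regressions on size range
(`lr_p` < 0.05). But this dataset was generated under the sampling
null — every lake draws from the same size distribution — and the
resampling test says exactly that:

```python
print(res.resampling[["size_measure", "predictor", "observed_slope", "p_value"]]
      .round(3).to_string(index=False))
```

```
size_measure    predictor  observed_slope  p_value
     s_range   log10_area           0.083    0.963
     s_range pct_endemism           0.004    0.879
       s_max   log10_area           0.073    0.852
       s_max pct_endemism           0.004    0.769
       s_min   log10_area          -0.066    0.412
       s_min pct_endemism          -0.002    0.222
      s_mean   log10_area           0.004    0.692
      s_mean pct_endemism           0.000    0.657
```

Every observed slope is well within the distribution of slopes produced
by subsampling alone (all P ≫ 0.05): the "significant" regressions are
the richness artifact, correctly flagged.

## Command line

```bash
lakesize simulate --seed 7 --out sim/              # synthetic dataset + ground truth
lakesize run --species sim/species.csv --lakes sim/lakes.csv --out results/ --seed 7
lakesize report --in results/                      # print the run log
```

`lakesize run` writes the size summaries, beta-diversity matrix,
predictor table, VIF report, the full regression battery (full
precision and a 3-decimal display copy), the Caspian-style sensitivity
refit when configured, the resampling results, and a JSON run log.
Analysis options (subsample fraction, repetitions, inclusion
thresholds, measure variants) live in a YAML config; see
`lakesize.RunConfig`.

## Bundled data

`lakesize.study_lakes()` returns a 23-lake summary table (location,
area, duration, distance to nearest coeval lake, species richness,
percent endemism, mean family-level Jaccard dissimilarity) used by the
tests and the acceptance script. For example, percent endemism
correlates with log10 richness at r = 0.514, P = 0.012 in this table.

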