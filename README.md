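# karstpheno

Quantitative community ecology of karst **dolines** — enclosed limestone
depressions whose concave topography creates steep microclimatic gradients
over tens of metres.  `karstpheno` turns plot×species cover relevés and
per-plot topography (depth below the doline rim, sky-view factor, % bare
rock) into:

* **discrete vegetation groups** along the depth gradient — multi-start
  K-means on a sqrt+Hellinger-transformed cover matrix, group number chosen
  by silhouette analysis on Bray–Curtis dissimilarities, silhouette-based
  reallocation of misfit plots, and ecological (depth-ordered, crevice-last)
  group numbering;
* **diagnostic species** — a synoptic table of percentage presence and the
  φ fidelity coefficient computed for equalized group sizes, with a
  one-sided Fisher exact concentration filter;
* **flowering-onset spectra** — the percentage of species in each plot that
  start flowering in each month (February merged into March, September into
  August), plus community-mean ecological indicator values (light,
  temperature, moisture, nutrients, reaction);
* **ordination and three-tier significance** — CA/DCA with
  detrending-by-segments, passive (envfit-style) projection of variables
  onto the first two axes, Spearman correlation tables, single-constraint
  CCA with Monte Carlo permutation tests, and the **modified permutation
  test** that permutes species attributes among species (not plots) to
  correct the circularity of community-mean statistics;
* a **synthetic doline-transect generator** with known six-group structure,
  Gaussian species responses, rock-crevice specialists and trait coupling,
  so that every stage of the pipeline can be validated against ground truth.

It is written for vegetation scientists who want a scripted, testable
version of the classic JUICE/vegan workflow for fine-scale gradient studies.

## The statistics at the core

**Equalized φ fidelity.** For `k` groups with per-group relative occurrence
frequencies `f_g` (presence count / group size) and `F = Σ_g f_g`, the
fidelity of a species to group `t`, computed as if all groups had equal
size, is

```
φ = (k·f_t − F) / sqrt(F · (k − 1) · (k − F))
```

which equals the classical 2×2 φ association coefficient on any equal-size
replication of the groups.  Species with φ > 0.20 whose concentration is
significant at p < 0.05 (one-sided Fisher exact test on the raw counts) are
flagged diagnostic.

**Silhouette-based reallocation.** After K-means, the plot with the most
negative silhouette width `s(i) = (b−a)/max(a,b)` (Bray–Curtis) is moved to
the cluster with the smallest mean dissimilarity to it, iterating until no
width is negative.

**Modified permutation test.** Plot means of species attributes (indicator
values, onset months) inherit structure from species composition; the null
is therefore generated by permuting the attribute values *among species*,
rebuilding the plot-level means, and recomputing the statistic.

**CCA explanatory power.** For one constraining variable, the percentage of
total variance `PTV = 100 · (constrained inertia / total inertia)` with
`F = constrained / (residual / (n − 2))`, tested by unrestricted permutation
of the constraint across plots.

## Worked example

```python
from karstpheno.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="out", sim_seed=1, cluster_seed=1, perm_seed=1)
manifest = run_pipeline(cfg)
print(manifest["clustering"]["k"], round(manifest["clustering"]["mean_silhouette"], 3))
```

prints `6 0.54`: on the default synthetic survey (10 dolines, 295 plots of
2 m × 2 m) the silhouette scan over k = 2…10 peaks at six groups (mean
widths 0.216, 0.311, 0.403, 0.481, **0.540**, 0.496, …) and two plots are
reallocated.  The CCA table (`out/cca.csv`) then ranks the explanatory
power of monthly flowering onset on floristic composition:

```
month,PTV,p,F
March,13.6,0.001,46.2
August,12.8,0.001,42.9
...
```

March and August shares carry the most compositional signal — early
flowering at moist, nutrient-rich doline bottoms; late flowering in rock
crevices — the same inverse-phenology pattern the package is designed to
detect.  The synoptic table (`out/synoptic.csv`) flags e.g. a bottom
specialist present in 86% of group-1 plots and nowhere else with φ×100 =
91.3 (Fisher p ≈ 3e-47).

The same workflow is available from a shell:

```bash
karstpheno simulate --out data --seed 1
karstpheno cluster data/community.csv data/plot_meta.csv --k auto --seed 1
karstpheno run-all --out results --seed 1
```

## Input formats

All inputs are CSV with a header row.

| file | columns |
| --- | --- |
| community (long) | `plot, species, value` — cover code (`r,+,1…5`) or percent |
| community (wide) | plot-indexed matrix, one column per species |
| plot metadata | `plot, transect, position, depth, svf, bare_rock` |
| traits | `species, onset, L, T, M, N, R` (onset = raw month 2–9; indicators may be empty) |

Cover codes are converted through a configurable midpoint table
(default `r→0.1, +→0.5, 1→2.5, 2→15, 3→37.5, 4→62.5, 5→87.5` %).
Out-of-range values (SVF outside [0,1], negative depth, onset outside 2–9)
are rejected, never coerced.

## Documentation

`docs/methods.md` describes the models, the synthetic generator, numerical
choices and known limitations.
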