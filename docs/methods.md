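# Methods

This note documents the statistical procedures implemented in `karstpheno`,
the assumptions behind them, the synthetic data generator used to validate
them, and the numerical choices made where the design was genuinely open.

## Data model

A survey consists of three tables: a plot×species cover matrix (ordinal
cover codes or percentages), per-plot topography (transect, along-transect
position, depth below the transect top in metres, sky-view factor in
[0, 1], % bare rock), and per-species traits (flowering-onset month and the
five ecological indicator values L/T/M/N/R).  Identifiers are opaque
strings; no taxonomy is interpreted.  Validation rejects, and never
silently clips, out-of-range values.  The cover scale is a configurable
code→midpoint table; the default seven-degree table is
`r→0.1, +→0.5, 1→2.5, 2→15, 3→37.5, 4→62.5, 5→87.5` (%).  Whether `r` and
`+` are distinct is survey-specific; both are supported and either can be
dropped from a custom scale.

## Transformations

The analysis matrix is built by decoding covers to percentages, taking the
element-wise square root (variance stabilization of visually estimated
covers), then applying the Hellinger transformation (square root of the row
profile).  This order — sqrt first, Hellinger second — is the package
default and is configurable; the alternative order is exposed for
sensitivity analysis.  Euclidean distance on the Hellinger matrix equals
the Hellinger distance on the raw matrix, which justifies running plain
(Euclidean) K-means on it.  Bray–Curtis dissimilarity is computed on the
same transformed matrix by default, so clustering and silhouette analysis
see one data view; a flag switches it to the raw percentage matrix.

## Clustering

K-means uses 20 independent starts; each start initializes every centroid
as the mean of 5 distinct randomly drawn plots (a sample-mean initializer),
runs Lloyd iterations to a fixed assignment, and the run with the smallest
total within-cluster sum of squares wins.  Nearest-centroid ties break
toward the lowest group index; a cluster emptied during iteration is
reseeded from the plot currently farthest from its centroid (logged).  The
WSS is asserted non-increasing across iterations.

The number of groups is chosen by scanning k (default 2–10) and maximizing
the mean silhouette width computed from the Bray–Curtis matrix, ties going
to the smaller k.  Silhouette widths use the standard `(b−a)/max(a,b)` with
the singleton convention `s(i)=0`.

Reallocation ("remos"-style) then iteratively moves the plot with the most
negative silhouette width into the cluster with the smallest mean
dissimilarity to it.  The single-worst-plot variant was chosen because it
is deterministic and terminates (cycle detection plus an iteration cap); a
move that would empty a cluster is skipped.  On well-separated data the
procedure is a no-op, which is the expected outcome for a clean partition.

Finally groups are renumbered ecologically: groups whose mean bare rock
exceeds 50% (rock-crevice vegetation) go last; the others are ordered by
decreasing mean depth, so group 1 is the doline bottom and the penultimate
group the karst plateau.

## Fidelity and the synoptic table

Fidelity is the φ coefficient of the 2×2 species×group presence table
computed *for equalized group sizes*: with per-group frequencies `f_g` and
`F = Σ f_g`,

φ = (k·f_t − F) / √(F (k−1) (k−F)).

This closed form equals the classical φ on groups replicated to any common
size (property-tested against that oracle).  A species present in every
plot of every group has no concentration anywhere and is assigned φ = 0 by
continuity; a species absent everywhere is an error.  φ is computed on
presence/absence, not abundance.

The significance filter is the Fisher exact test on the raw
(non-equalized) counts, one-sided toward concentration in the target group
(the tabulation-software convention; a two-sided variant is available).
The one-sided p is the inclusive hypergeometric upper tail; note that equal
proportions inside and outside the target give a large p but not exactly 1
— p = 1 occurs at the minimum of the support.

The synoptic table reports integer-rounded % presence and φ×100 to one
decimal.  Species diagnostic for a group (φ > 0.20 and p < 0.05) are
blocked by group, within a block by declining φ; remaining species follow
by declining overall presence.

## Traits

Raw onset months 2–9 are recoded by merging February into March and
September into August.  Flowering spectra are unweighted percentages of the
species (with known onset) present in a plot that start flowering in each
month; species missing the trait leave both numerator and denominator.
Indicator-value means are likewise unweighted arithmetic means over the
species scored for that indicator; an unscored plot yields a missing value,
never zero.  Cover-weighted variants of both sit behind a flag for
sensitivity analysis.

## Ordination

CA is the SVD of the χ²-standardized residual matrix; site scores are
standard coordinates (weighted mean 0, weighted sum of squares 1) with a
deterministic sign convention, species scores are the abundance-weighted
averages of site scores, and eigenvalues are the squared singular values
(≤ 1, with 1 attained exactly by a disconnected block structure).

DCA extracts axis 1 as the CA axis; each higher axis is iterated by
reciprocal averaging with detrending-by-segments against every lower axis
inside each iteration (default 26 segments, capped so each segment keeps
roughly three plots on small matrices — on a handful of plots 26 segments
would annihilate the axis).  The reported eigenvalue is the shrinkage of
one averaging cycle at convergence.  Axis rescaling to SD units is a
*linear* calibration: scores are divided by the abundance-weighted RMS
spread of species scores about their plots' scores.  The classic iterative
nonlinear within-axis rescaling is deliberately not reproduced; the
contract is the set of equivalence properties (detrending and rescaling off
reduces exactly to CA; weighted per-segment means of axis 2 along axis 1
vanish; axis-1 eigenvalue is untouched by detrending), not numeric
agreement with any legacy binary.  Detrended axes are kept in extraction
order and only CA eigenvalues are required to be monotone.

Passive vector fitting regresses a plot-level variable on the first two
axis-score columns: `r` is the multiple correlation, the arrow is the unit
coefficient vector, and p.par comes from the F distribution of the
regression.  Species-derived variables (indicator means, onset shares)
additionally get p.perm (variable permuted across plots, one-sided on r)
and p.modif; topographic variables get the parametric p only, since
permutation nulls are not meaningful for variables that do not derive from
the species matrix.

The modified permutation test permutes attribute values among the scored
species — the missingness pattern stays fixed — rebuilds the plot-level
means from the community matrix, and recomputes the statistic; p is the
inclusive two-sided count `(1+#{|T*|≥|T|})/(n_perm+1)`.  When both sides of
a correlation are species-derived (month share vs indicator mean), the
attribute under test (the onset month) is permuted and the other side held
fixed; the choice is symmetric in spirit but must be fixed, and is
documented here.

Single-constraint CCA projects the residual matrix onto the row-mass
weighted, centred constraint; PTV = 100·constrained/total inertia,
F = constrained/(residual/(n−2)), and the Monte Carlo p permutes the
constraint freely across plots (no blocking by transect; a blocked variant
would be a restricted permutation and is not implemented).  Per-month
explanatory powers are separate single-variable models, not marginal terms
of a joint model.  All permutation p-values lie on the grid
`(1+j)/(n_perm+1)` and are reproducible from the stage seed.

## Synthetic data generator

The generator defines the conditions every downstream test runs under.  It
emulates ten dolines (depths 2.45–21.74 m) crossed rim-to-rim by transects
of 2 m plots (295 plots in total): each limb follows a cosine bowl, so rim
plots sit at depth 0; the sky-view factor decreases linearly with depth
(proxy slope 0.75 of the global maximum depth, Gaussian noise sd 0.03);
bare rock declines from ~30% at the rims with sd 6, and a random 8.5% of
plots are rock-crevice sites with 55–95% bare rock.

Six archetypes mirror bottom / lower slope / middle / upper slope / plateau
/ crevice.  Soil archetypes occupy normalized-depth bands with edges
0.55/0.35/0.20/0.03, chosen so the cosine-profile geometry reproduces
group sizes close to the 50/48/48/76/39/25 design of the motivating survey.
Species respond unimodally (Gaussian) along the gradient; crevice species
respond to bare rock instead, and soil-species intensity is damped by
`(1−rock/100)^1.5`.  Because doline vegetation belts behave as terraces
with sharp boundaries rather than a perfectly smooth coenocline, plot
positions are shrunk toward their band centre by a `terrace` factor
(default 0.6; 0 recovers a smooth gradient).  Occurrence is
Poisson-thinned (rate 2.5 at the optimum, i.e. ~92% detection) and covers
are rounded through the ordinal scale and back, reproducing realistic
sparsity and discretization noise.

Trait coupling carries the phenological signal: onset centres are March /
April / May / May / June / August for archetypes 1–6 with ±1 month jitter
and occasional February/September raw values (exercising the recoding);
moisture and nutrient indicators increase with niche depth (slopes 4.0 and
4.5 per unit normalized depth), light and temperature decrease (−4.5,
−2.5), reaction is flat around 6.8 (limestone).  Coupling strengths of 0
decouple traits from the gradient entirely, which is how the null
behaviour of the trait statistics is tested.  5% of indicator values and
3% of onsets are missing.

What the generator does **not** emulate: real floristic composition and
species pools, dispersal limitation, spatial autocorrelation along a
transect beyond the shared gradient, interannual dynamics, and any
quantitative SVF–geometry relation (only the monotone coupling matters for
the tests).  Passing tests therefore demonstrate that the algorithms
recover structure of the kind and strength built in here — six discrete,
depth-ordered, trait-coupled groups — not that any particular field data
set will behave as cleanly.

## Problem sizes and tolerances

Unit oracles run on matrices of 4–40 plots; null-calibration checks use
500 simulated data sets for permutation-p uniformity (Kolmogorov–Smirnov
at the 1% level, 99–199 permutations each) and 1000 simulated data sets ×
199 permutations for the modified-test type-I error (accepted within
[0.03, 0.07] at α = 0.05); structure-recovery checks use 20 generator
seeds at the full default size (295 plots, ~130 species).  Algebraic
identities are asserted at 1e-10–1e-12, iterative eigen-solutions at 1e-8.
Two cross-checks (CA eigenvalues, CCA inertia decomposition) additionally
compare against the R vegan implementation.

## Known limitations

* DCA axis scaling is linear; axis *lengths* are therefore not comparable
  with gradient lengths reported by implementations with nonlinear
  rescaling, although configurations and eigenvalues are.
* The Fisher filter treats plots as exchangeable; spatial dependence
  within transects is ignored (as it is in the standard workflow).
* `ground_truth(config)` answers only for configurations simulated in the
  current session (results are cached by configuration, not persisted).
* The CLI covers the standard path; unusual analyses should use the
  library API directly.
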