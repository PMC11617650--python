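# Methods

This note describes the models and procedures the package implements, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Overview

The pipeline predicts hybrid maize-style grain yield for every cell ("bin")
of a geographic grid covering a target population of environments (TPE),
from three inputs: trial-level standardized yield BLUEs, a pedigree, and a
wide table of environmental covariates at the trial locations and grid bins.
It proceeds in four stages:

1. **Marker engineering.** Environmental covariates are compressed into K
   one-dimensional *engineered enviromic markers* (EEMs) by a large ensemble
   of regression trees predicting trial environment means, hierarchically
   clustered into K forests.
2. **Reaction-norm mixed model.** Genotype performance is modelled as an
   intercept plus linear reaction norms on the markers, with genotypes tied
   through the pedigree relationship matrix: `u ~ N(0, Σ ⊗ A)`. An ensemble
   of runs, each using one sampled tree-gradient per marker cluster,
   produces averaged genotype × bin surfaces with run-to-run standard
   errors.
3. **Zones and recommendation.** The fitted Σ and the marker surfaces imply
   a genetic variance and a genetic correlation between any two bins; Ward
   clustering of the correlations delineates breeding zones. Per bin, the
   recommended genotype is chosen among those statistically tied with the
   best by geographic representativeness. Parental lines receive surfaces
   through the additive relationship matrix even though they carry no
   phenotypes.
4. **Validation.** Leave-one-trial-out and leave-region-out cross-validation
   of the reaction-norm model against a covariate-free baseline and a
   marker-kernel model, scored per trial (Pearson, Spearman, RMSE), with the
   per-trial abilities interpolated over the grid by ordinary kriging.

## Prediction grid

Trial lon/lat (WGS84 degrees) are projected to planar km with a local
equirectangular chart about the trial centroid; at the few-hundred-km
extents the pipeline targets, the distortion is far below one bin width.
The study area is the convex hull of the trial points dilated by a buffer
(default 50 km) with **mitred** joins, so the dilation extends hull edges
squarely rather than rounding corners; a square of points dilated by b is
then exactly the enclosing square grown by b, which makes the grid-count
arithmetic transparent. Bins are squares (default 5 km edge, i.e. 25 km²
pixels) anchored at the buffered polygon's bounding-box corner; a bin is
kept iff its centroid lies inside the buffered hull.

## Engineered enviromic markers

For each of N trees (default 10 000; the demo uses 1000):

* a random half of the phenotyped genotypes is drawn and the per-trial mean
  of their BLUEs is the tree's response m (a fresh realisation of the
  "environment mean" each time, so the bank averages over genotype
  composition);
* a random covariate subset of size √p is drawn (the standard random-forest
  rule; the source method names no subset size);
* an unpruned CART regression tree of m on the subset is fitted with a
  minimum leaf of 2 trials (small-n default).

Tree predictions over the **prediction grid** (not the trials) are
standardized per tree; one minus the Pearson correlation between these
standardized prediction vectors is the distance for average-linkage
hierarchical clustering, cut at K = 7 clusters. Marker k is the mean of
cluster k's standardized predictions, re-standardized to mean 0 / sd 1 over
the grid, so markers are well-scaled where predictions are made; trials are
then scored with the same stored scalings. The *wide-environment gradient*
(used for charting and the variance profile) is the standardized mean over
all trees; by construction the cluster-size-weighted average of the
(un-restandardized) markers reproduces it.

Covariate importances (impurity decrease) are tallied per tree into an
envirome-wide association table: how often each covariate ranked 1st…5th,
its mean importance, and importance shares by data-source tag (the column
prefix, e.g. `sat_`/`clim_`/`soil_`/`wx_`), normalised to 100 %.

Marker validation: the in-sample correlation between observed trial means
and the ensemble mean prediction, and a leave-one-trial-out correlation in
which a reduced bank (default 150–200 trees; logged) is refitted without
each trial.

## The reaction-norm mixed model

One run fits

    y = Xb + Zu + e,   u ~ N(0, Σ ⊗ A),   e ~ N(0, I σe²)

where X holds one intercept per year; each genotype's block of Z is
`[1 | ε₁ … ε_K]` over its records; Σ is the (K+1)×(K+1) covariance of
(intercept, K slopes); and A is the additive (numerator) relationship
matrix from the pedigree by the tabular method (founders — including
competitor hybrids of unknown parentage — are unrelated and non-inbred).
A positive-semidefiniteness repair adds minimal, logged diagonal jitter
when round-off requires it.

### REML

Variance parameters are estimated by restricted maximum likelihood through
Henderson's mixed-model equations; the restricted log-likelihood is
evaluated with the determinant identity
`-2 l_R = n log σe² + log|Σ⊗A| + log|C| + y'Py`, never forming the n×n
phenotypic covariance. Because the K marker gradients are strongly
inter-correlated, the REML optimum of Σ routinely sits on (or numerically
at) the singular boundary, where EM-type iterations stall and
average-information steps overshoot. The optimizer therefore works on an
unconstrained Cholesky parameterization, Σ = LL' + εI with a fixed ridge
ε = 1e-6·var(y), and minimises −2 l_R by L-BFGS with exact analytic
gradients (verified against finite differences). The ridge bounds the
asymptotically flat singular directions so the quasi-Newton iteration
terminates cleanly; its bias (≤ 1e-6 of the phenotypic variance per
eigenvalue) is negligible against every tolerance used downstream.
Convergence: relative change of the restricted log-likelihood below 1e-8
(optimizer default budget 200 iterations); non-converged fits carry a flag.
A diagonal-Σ fallback triggers automatically when the phenotyped-genotype
count is below 5(K+1).

### Ensemble

Each of n_runs (default 1000; demo 50) runs draws one tree-predictor per
marker cluster, uses the K standardized single-tree gradients as that run's
markers, fits the model (warm-started from the previous run), and predicts
every bin as `ŷ(g, bin) = b̄ + u0_g + Σ_k u_kg ε_k(bin)` with b̄ the mean
fitted year intercept (no year is singled out). Non-converged runs are
dropped; more than 20 % dropped aborts. Outputs: the run-averaged surface,
the run-to-run standard error of that average, the pooled (run-mean) Σ, and
all slope draws. Stability/adaptability angles are `arctan(slope)` in
degrees over every sampled marker of every run — 0° is perfectly stable,
±45° strongly reactive, negative values mean yield falls along a rising
gradient — summarised per genotype as min/max/mean.

### Comparator models

*Baseline*: irrigation as fixed effect; genotype main effect random with
covariance σg²A; no covariates. With trial-level BLUEs there is exactly one
record per (trial, genotype) cell, so an iid trial×genotype interaction is
exactly confounded with the residual; it is dropped with a warning and
reported as zero rather than left to an arbitrary EM split of a flat
likelihood ridge. New-environment predictions are irrigation effect +
genotype BLUP.

*Kernel*: genotype main (A), environment main (linear kernel of the
standardized marker vectors, scaled to unit mean diagonal), and their
Hadamard-product interaction. All components enter REML through factor
matrices (K = FF' contributes the factor F), which makes the
interaction-kernel fit the exact record-level counterpart of a
diagonal-Σ random regression — a property the tests exploit. These iid
component variances are optimised on the log scale by the same
exact-gradient L-BFGS scheme (a component on the zero boundary becomes a
smooth flat direction rather than a constraint).

## Breeding zones

With `z(bin) = (1, ε₁ … ε_K)'`, the additive genetic variance at a bin is
`z'Σz` and the genetic covariance between bins is `z_i'Σz_j`, using the
pooled ensemble Σ. The full bin×bin matrix is never materialised: Ward
clustering runs on `d = √(2(1−r))` over a random subsample (default 2000
bins) and the remaining bins join the nearest zone centroid in marker
space. Zones are relabelled by descending mean yield potential (zone 1 most
productive). The zone table reports bin and trial counts, the top-1
selection gain (absolute on the standardized scale — a percentage of a
near-zero standardized mean is meaningless; a % gain appears only when a
positive-scale back-transform is supplied), and within/between-zone mean
correlations. The variance-vs-gradient profile pairs per-bin variance with
the wide gradient and adds a Gaussian-kernel smoother (bandwidth default
0.4 × IQR of the gradient; at infinite bandwidth it degenerates to the
global mean line).

## Recommendation

Per bin: (1) a two-sided t-test on the ensemble run-to-run standard errors
(df = kept runs − 1, pooled SE `√(SE_best² + SE_g²)`, α default 0.05) keeps
every genotype statistically tied with the best; (2) among the tied set the
winner minimises the planar distance from the bin centroid to its nearest
trial ("geographic representativeness"; a mean-of-k-nearest mode is
available), with ties broken by higher predicted mean then lexicographic
id. Genotypes never trialed cannot win. Raising α can only widen tied sets,
so the winner's predicted mean is non-increasing in α. Occupation tables
report bins won, % of grid, distinct trial bins and years measured, and the
stability angles. Parental surfaces come directly from the parents' BLUPs
(propagated through A); per bin the top two distinct parents define the
suggested cross, whose reported value is the additive mid-parent mean — no
dominance or heterosis is modelled.

## Validation

Metrics are computed strictly within trial and then averaged (unweighted
mean ± sd over trials): pooling records across trials can reverse the sign
of the association (Simpson's paradox), and a constructed example of that
reversal is part of the test suite. Trials with fewer than 3 genotypes are
skipped; zero-variance trials yield missing correlations. Leave-one-trial-out
refits the chosen model without each trial — by default the marker bank is
re-engineered per fold from the remaining trials (a frozen-bank fast mode
exists and is logged); the kinship matrix is marginalised to the phenotyped
genotypes inside folds, which is exact for Gaussian priors and much faster.
Leave-region-out holds out each region in turn; "overall" pools all folds'
trial-level metrics.

Ordinary kriging of the per-trial abilities: empirical semivariogram in 15
equal-width lag bins up to half the maximum pairwise distance; spherical
model (nugget, partial sill, range) fitted by weighted least squares with
pair counts as weights; the kriging system with the unbiasedness constraint
is solved per bin, so weights sum to one and, with zero nugget, the surface
interpolates the data exactly. Identical abilities short-circuit to a
constant surface.

## The synthetic-data generator

The generator produces data with exactly the statistical structure the
model assumes, at a scale where the full chain runs in minutes:

* **Covariates**: smooth spatially autocorrelated surfaces (low-rank
  Gaussian random fields, correlation range 60 km), standardized over bins;
  each causal field gets collinear copies (pairwise r ≈ 0.9) plus pure-noise
  fields, emulating the redundancy of satellite/climate/soil/weather stacks.
* **True gradients**: K_true = 2 standardized saturating (tanh) transforms
  of linear blends of the causal fields — recoverable by trees, not equal to
  any single raw covariate.
* **Census**: founder parents crossed into hybrids, plus a fraction of
  competitor hybrids with unknown parents; only hybrids are phenotyped.
* **Genetics**: (intercept, slopes) drawn from the matrix normal with row
  covariance A and column covariance Σ_true (default: intercept variance
  1.0, slope variance 0.64 per gradient, intercept–slope correlation −0.2
  — strong genotype-by-environment interaction with rank switching).
* **Phenotypes**: year effects (sd 0.3), an irrigation offset (0.2) on a
  random quarter of trials, a nonzero *mean* reaction norm (0.8 per
  gradient) acting as the environment main effect — without it trial means
  would carry almost no covariate signal and there would be nothing for the
  marker stage to learn — plus genotype terms and N(0, 0.5²) residuals.
  Trials sit at sampled bins with unbalanced genotype subsets (0.6–1.4 ×
  the nominal per-trial count); regions are the four quadrants of the study
  area.
* **Demo scale**: ~600 bins (10 km cells, 20 km buffer over a ~2.2° box),
  40 trials, 60 hybrids + 20 parents. A separate census-shaped generator
  reproduces the reference study's bookkeeping (183 trials, 12 400 records,
  85 + 79 genotypes, 48 irrigated) with meaningless yields, for exercising
  the readers at full census scale.

What the generator does **not** emulate: raw imagery or reflectance bands,
plot-level field layouts and their spatial adjustment (the pipeline consumes
trial-level BLUEs), non-Gaussian residuals, genotype-by-management
structure beyond a constant irrigation offset, dominance/heterosis, and
spatially structured measurement error. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the model's own
assumptions — not field performance on real trial networks.

## Numerical choices and degenerate inputs

* Constant trees (no covariate signal) predict a constant; their
  standardized prediction is zero and they join cluster 1; a constant-m
  world degenerates gracefully to grand-mean predictions.
* Markers with zero variance over the reference keep their raw scale
  (division by 1 instead of 0).
* Σ bending elsewhere (e.g. user-supplied matrices) clips eigenvalues at
  1e-8 of the leading one; the kinship repair rejects matrices whose
  minimum eigenvalue is below −1e-8 relative.
* Kriging with a singular system (colocated points) falls back to a
  least-squares solve; fewer than 5 finite abilities is an error.
* Ties in Spearman correlations use average ranks (scipy default).
* All randomness flows through `numpy.random.default_rng` seeded from one
  integer per entry point; derived seeds stay below 2³¹.

## Problem sizes used by the shipped analyses

The numbered analysis scripts, the end-to-end tests and the acceptance
script run the demo conditions (≈600 bins, 40 trials, 60 hybrids, 1000
trees, 50 ensemble runs; cross-validation with 200-tree banks and 5 runs
per fold). These sizes are the package's demonstration scale — an order of
magnitude below the defaults in `RunConfig`, which mirror the full-scale
study design (10 000 trees, 1000 runs, 5 km bins, 50 km buffer).

## Known limitations

* Slope identifiability is weak when markers are nearly collinear; the
  ensemble's per-marker slopes should be read through the pooled surfaces
  and stability summaries, not individually.
* The recommendation's run-to-run SE measures ensemble (marker-sampling)
  uncertainty, not full posterior prediction uncertainty; a model-based SE
  alternative is noted in the code.
* Selection gains on the standardized scale are absolute differences;
  percentage gains require the optional affine back-transform to a
  positive yield scale.
* The grid geometry is planar-equirectangular; continental-scale TPEs would
  need a proper projected CRS.
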