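# Methods

This note documents the models, algorithms and numerical choices behind
`phyloimpute`, and what the synthetic test bed does and does not show.

## Data model

A trait table is a species × trait matrix with a per-trait schema:
`continuous`, `count`, `binary` or `multicategorical`, plus an optional
`natural_log` model-scale transform (valid only for strictly positive
numeric traits — a signed latitude-like trait keeps the identity scale, a
mathematical necessity the schema makes explicit rather than hiding).
Counts are validated as non-negative integers on the observed scale;
derived tables (back-transformed or pooled across multiple imputations)
may carry non-integer counts and are flagged as such rather than rounded,
because evaluation happens on the model scale.

Dataset construction mirrors how near-complete trait subsets are carved
from large compilations:

* **Severe outliers**: values strictly above Q3 + 3·IQR. Quartiles use
  linear interpolation between order statistics (the "type 7" rule, the
  default in mainstream numeric stacks) since no convention is canonical.
* **Class imbalance**: a categorical trait is dropped when its modal
  category holds *strictly more than* 90 % of observed values.
* **Near-complete-case filter**: keep the largest row subset such that
  (a) every trait has ≤ 10 % missingness and (b) every gappy row retains
  ≥ 3 observed companion traits. Rows violating (b) are dropped first;
  then rows with the most missing cells are dropped greedily (ties broken
  by species ID) until (a) holds. The greedy order is our choice — only
  the outcome constraints are externally specified.

## Phylogenetic eigenvectors

Eigenvectors are a principal coordinates analysis of the patristic
distance matrix: Gower double-centering of −½·D∘D followed by a symmetric
eigendecomposition. We retain the smallest k axes whose cumulative share
of the **positive**-eigenvalue sum reaches the threshold (default 0.65);
negative eigenvalues, which can appear for non-ultrametric inputs, are
excluded from both numerator and denominator. This is the PVR flavour of
phylogenetic eigenvector analysis; the Ornstein-Uhlenbeck branch-length
transformation of PEM-style eigenvector maps is deliberately out of
scope. Ultrametricity is checked with relative tolerance 1e-3 and only
warned about, since trees are expected to be ultrametricised upstream.

## Phylogenetic signal

**Pagel's λ** (continuous traits): the off-diagonal of the
Brownian-motion tip covariance C is multiplied by λ ∈ [0, 1] (diagonal
unchanged); the mean and rate are profiled out analytically and λ is
maximised by bounded scalar optimisation (tolerance 1e-6). The test
against λ = 0 uses the likelihood ratio with the boundary mixture
½χ²₀ + ½χ²₁. A star tree makes C(λ) independent of λ; the estimator
reports "unidentifiable" instead of a number. The estimate is invariant
to location/scale changes of the trait and cross-checks against the
`phytools::phylosig` implementation to 0.01 on shared inputs.

**Fritz & Purvis' D** (binary traits): internal node values are
unweighted averages of their children's values (postorder); d is the sum
of |parent − child| over all edges. D scales d_obs between the mean d of
tip-label shuffles (D = 1, no signal) and of threshold-Brownian
simulations at the observed prevalence (D = 0, Brownian clumping), 1000
nulls each by default, with tail p-values against both nulls. Any
self-consistent d works because the normalisation uses the same statistic
under both nulls.

## Missingness simulation

* **MCAR**: per trait, exactly round(p·n) observed cells (rounding half
  away from zero, fixed for reproducibility), drawn from a per-replicate
  permutation so plans at increasing p are nested — differences between
  proportions then reflect the amount of missingness, not which species
  vanished. Pre-existing gaps count toward neither p nor the pool: p is
  additional missingness.
* **MAR**: a logistic regression of the missingness indicator on
  auxiliary traits is fitted to a large gappy reference table
  (complete-predictor rows, categorical predictors dummy-coded);
  predictors with all coefficient p ≥ α are dropped and the model refit.
  A trait with no surviving predictor is MAR-ineligible and simply casts
  no MAR vote. To mask, the fitted intercept is shifted by a scalar
  (Brent root-finding) so the expected masked count equals
  round(p·n) — default target 0.20, configurable, since the original
  control level is not externally fixed — and cells are independent
  Bernoulli draws. This preserves the covariate dependence while holding
  overall missingness comparable across mechanisms.
* **MNAR**: deterministic biased deletion. Numeric traits lose the cells
  at or below the tail quantile (lower, upper, or centre-on-zero via
  absolute value — the latter emulating deletion of near-equatorial
  latitudes); categorical traits lose a configured fraction (default all)
  of one category, by default the rarest when none is named.

Masks are value objects (mechanism, proportion, replicate, seed, explicit
cell set), serialisable to CSV, and shared across every imputation method
within a replicate — the fair-comparison backbone of the design.

## Candidate imputers

All methods see the table on the model scale and a per-target predictor
list from single-covariate association screening (family by target type:
linear, Poisson, logistic, multinomial logit; an auxiliary is kept iff
any coefficient has p < α). Count targets are modelled on the log scale
by the imputers themselves; Poisson regression appears only in screening.
Eigenvector columns bypass screening and are always included when a
phylogeny source is configured — they are appended wholesale, never
imputed and never scored.

* **mean/mode**: column mean / modal category (mode ties broken by the
  lexicographically smallest label). No phylogenetic variant — this is
  what makes the standard design count 16 method-source combinations × 6
  mechanism settings = 96.
* **KNN**: Gower dissimilarity over the target's predictors
  (range-normalised numeric differences, 0/1 categorical mismatches,
  pairwise-available averaging), k nearest donors aggregated by median /
  mode. A query row with no predictor overlap widens to all columns, and
  a fully unobserved row degenerates to the donor median/mode rather than
  aborting a replicate.
* **RF (missForest-style)**: initialise by mean/mode; visit traits in
  order of increasing missingness; per iteration refit a random forest
  per trait (regression: max_features = p/3; classification: √p; 100
  trees by default) on rows observed for that trait and re-predict its
  missing cells; stop when the difference criterion (normalised squared
  change over numeric imputed cells; proportion of changed categorical
  cells) rises for both families, returning the previous iterate, or at
  10 iterations.
* **MICE**: chained equations, initial fill by random draws from observed
  values, visit order by increasing missingness, 5 cycles × m = 5
  imputations by default. Numeric traits use predictive mean matching
  (type-0: linear least-squares fit, donor pool = 5 observed values with
  nearest fitted means, uniform draw — so imputed values are always
  members of the observed set); binary/multicategorical traits use
  logistic / multinomial-logit probability draws. The m completions are
  pooled by mean / mode. Omitting the posterior parameter draw is a
  deliberate simplification — deterministic and desk-scale — and means
  the procedure is not fully "proper" multiple imputation; since
  everything is pooled to a single value for scoring, this does not
  affect the selection machinery.

A grid-tuning helper reruns any evaluation context over a parameter grid
and returns the configuration with the lowest mean error (ties → smallest
parameter values, then declaration order).

## Evaluation and selection

MSE (numeric) and PFC (categorical) are computed only over cells that
were deliberately masked *and* have an observed true value, on the model
scale (an original-scale evaluation is available behind the inverse
transform). Per-replicate records are averaged per (mechanism,
proportion, method, source, trait) with standard errors attached; the
per-trait MSE is averaged over cells then replicates. The majority vote
gives each trait one vote for the combination with its lowest mean error
(mechanism proportions averaged first), starting under MAR; an exact vote
tie restricts the candidate set and repeats under MNAR, then MCAR, with
the full trace recorded; a persistent tie is an error, not a silent pick.
Dataset comparisons report N, min/max/range, median, mean, SE, 0.95 CI
half-width (Student-t quantile × SE, df = N−1), variance and SD for
numeric traits and category counts/proportions for categorical ones, on
the original scale.

## Synthetic test bed

The generator produces ultrametric Yule or birth-death trees (exponential
waiting times; extinct birth-death replicates resimulated up to a retry
cap) and traits from a separable latent model: per trait, Brownian tip
values with λ-rescaled covariance; across traits, a PSD correlation
matrix mixes otherwise-independent drivers. Observation links: identity
(exponentiated when the trait is declared log-scale, giving log-normal
body sizes), 1 + Poisson(exp(a + b·z)) for right-skewed strictly positive
counts (clutch-size-like, so the log transform is always valid), and
empirical-quantile thresholding for categoricals (default three-level
cuts at the 0.55/0.85 quantiles, emulating realistic activity-time
imbalance). Pre-existing gaps are MCAR at 5 % by default (≤ 10 % and
never violating the near-complete-case side conditions); a helper can
instead inject covariate-driven (MAR) gaps for exercising the MAR
machinery. Defaults — 152 taxa, seven traits (two log-scale continuous,
two counts, one signed, one binary, one three-level), moderate inter-trait
correlation — mirror the structure of a real squamate compilation.

What passing tests on this bed show: the machinery recovers known signal,
respects known mechanisms, and ranks methods sensibly when relationships
are real and monotone. What they do not show: robustness to measurement
error, taxonomic non-independence of sampling effort, non-linear
trait-trait relationships, or tree misspecification — all properties of
real data the generator deliberately idealises.

## Problem sizes and determinism

Estimator-recovery suites use 100-tip trees with 200 replicates for λ and
15 replicates × 400 nulls for D; the end-to-end suite runs 3 methods ×
{none, one tree} × {MCAR 0.10, 0.20; MAR; MNAR} × 10 replicates on 100
taxa — sizes chosen so the whole battery runs on a laptop in minutes
while keeping Monte-Carlo error well inside the asserted tolerances.
Every stochastic operation takes an explicit seed; pipeline seeds are
derived from the master seed per (mechanism, proportion, replicate) —
never per method — via integer-keyed seed sequences, so replays are
bit-identical across platforms and any single (setting, replicate) can be
reproduced in isolation from the run manifest.

## Known limitations

* The MAR calibration target (0.20) is a package default, not an
  externally fixed constant; comparisons across MAR studies should state
  it.
* The OU-transformed (PEM) eigenvector variant is not implemented; on
  strongly non-Brownian traits PVR axes may carry less signal.
* λ is estimated for the *observed* trait, which for counts and
  thresholded categoricals differs from the latent generating λ;
  recovery tests therefore pin only the λ ∈ {0, 1} endpoints tightly.
* Multiple-imputation uncertainty (Rubin's rules) is intentionally not
  propagated; the pipeline collapses MICE to a single pooled table.
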