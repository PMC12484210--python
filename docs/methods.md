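# Methods

This note documents the model, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Model and estimation

Constructs come in four kinds.  *Composites* (genes, ROIs) carry ≥1 observed
indicators and a free weight vector; *observed* constructs (PTE, gender, age,
AUDIT) and the *outcome* (CAPS-5 severity) carry exactly one indicator with
weight and loading fixed at 1; *interaction* constructs carry no indicators —
their score is the standardized element-wise product of the two parent scores
and is recomputed deterministically whenever a parent's score changes.  Only
gene × PTE interactions are built by the study preset; the model format also
accepts arbitrary declarative construct/edge lists, so alternative structures
(e.g. reversed pathways) can be specified without code changes.

All indicators are standardized with the **population (divide-by-n) variance
convention**, and every component score is constrained to unit population
variance.  This is what makes two identities exact rather than approximate:
loadings equal indicator–component correlations, and R² per endogenous
construct equals 1 − RSS/n.

The fitting criterion is the sum of squared residuals of every indicator
equation and every structural equation plus `λ·Σb²` over structural
coefficients only.  Weights and loadings are never penalized; the penalty
addresses collinearity among the 22 (respectively 64) predictors per
structural equation, not the measurement part.  The ALS schedule is:

* **A-step.** Given scores: loading of indicator *i* on its construct is the
  least-squares slope (= correlation).  Incoming paths of each endogenous
  construct solve `(G'G + λI) b = G'γ`; constructs sharing a predictor set are
  solved in one multi-right-hand-side call.  At λ = 0 a rank-deficient
  predictor block gets the minimum-norm solution with a logged warning.
* **W-step.** For each free composite in turn, the weight vector solves an
  exact least-squares problem assembled from every criterion term its score
  enters linearly (its indicator block, its own structural equation, all
  equations where it is a predictor, with interaction scores held fixed), and
  the score is rescaled to unit variance.  Because the constrained optimum is
  the projection of the assembled target onto the composite's indicator span,
  each sub-step cannot increase the criterion; with interactions present the
  recomputation of product scores can, so convergence (not monotonicity) is
  the asserted property in that case.

Defaults: equal-weight initialization (1/√k) for determinism (random
initialization with a seed is available for basin checks), relative-change
tolerance 1e-6, at most 500 iterations; non-convergence yields a warning plus
the criterion trace, never a silent failure.  Orientation: each composite is
flipped, after convergence, so the sum of its loadings is positive; structural
coefficients are transformed congruently, leaving fitted values unchanged.

## Penalty selection

"10 × 5-fold" is read as 10 independent repetitions of 5-fold cross-validation
(both knobs configurable).  Standardization parameters are learned on the
training folds only; held-out scores are formed with training weights (and
training centering constants for interaction products).  The out-of-fold loss
is the sum of squared structural residuals on held-out rows — structural only,
because that is the part the penalty regularizes; the paper-scale grid
[0, 1000] is covered by default with 41 points (0 plus 40 log-spaced), since a
dense integer grid is affordable only for small models.  Ties select the
larger λ.  Folds are seeded, so the CV curve is bit-for-bit reproducible.
A fold whose training half contains a constant indicator column is resampled
with a warning (relevant for rare genotypes at small n).

## Bootstrap and mediation

Rows are resampled with replacement; each resample is restandardized and the
model refit at the selected λ (weights, loadings, paths — everything), warm
started from the full-sample weights.  Component sign indeterminacy would
otherwise inflate SEs, so each composite is aligned to correlate positively
with the full-sample score on the drawn rows; interaction components inherit
the product of their parents' signs.  Intervals are plain 2.5/97.5 percentile
intervals, and significance is strict zero exclusion on the unrounded bounds.
No multiplicity layer is added: the model is estimated jointly, and the
package deliberately exposes the raw per-path decisions (the type-I
calibration below checks they are honest).  Degenerate resamples (a SNP
constant in the draw) are discarded and redrawn, with a warning above 1%.
λ is held fixed across refits; re-tuning inside the bootstrap is out of scope.
Indirect effects multiply the chain's coefficients draw-by-draw, so the point
estimate is exactly the product of the direct estimates and the CI reflects
the joint uncertainty of both legs.

## Fit indices

FIT = 1 − (all indicator + structural residual sums of squares)/(total sum of
squares of indicators and endogenous components); the penalty term is
excluded.  GFI = 1 − tr((S−Σ̂)²)/tr(S²) and SRMR is the RMS standardized
residual over the lower triangle **including the diagonal**.  The reproduced
matrix Σ̂ is defined by reconstruction: endogenous component scores are
replaced by their structural predictions (recursively from the exogenous
components), indicators are rebuilt as loading × implied score, and Σ̂ is
their covariance; diagonal cells of single-indicator observed/outcome
constructs are set to 1 because those constructs carry no measurement
residual.  This definition is a deliberate contract choice — component-model
literature does not pin one down — and it is conservative: any variance the
sparse structural part does not transmit is reproduced as zero, so Σ̂ omits
the within-construct covariance of weakly predicted ROIs and GFI/SRMR on
realistic data are markedly worse than measurement-level fit would suggest.
Comparisons should therefore be relative (same definition, competing models),
and the cutoff flags (0.93 / 0.08) are reported alongside, not in place of,
the raw values.

## Descriptives

Group comparisons use the Welch unequal-variance t with Welch–Satterthwaite
degrees of freedom; this form reproduces the study's printed severity
statistic from its rounded group summaries to ~0.003, which a pooled-variance
form does not.  The moments screen reports sample skewness and plain
(non-excess) kurtosis — the normal reference value is 3 — against the
conventional cutoffs |skew| < 2 and kurtosis < 7.

## Synthetic data

The generator's defaults are the study's data conditions: n = 231; genotype
class frequencies per the packaged table (the one internally inconsistent row
renormalized, and documented in the resource); PTE ~ beta-binomial over 17
items with mean 3.72 and SD 2.47; severity on the CAPS-5 scale (28.20 ± 20.33,
truncated at 0); age 46.1 ± 13.5; AUDIT as an over-dispersed count
(3.04 ± 3.61, capped at 40); 32.5% male.  Total brain volume is 1450 ± 120
cm³, a conventional adult value chosen once; ROI part volumes are generated on
the relative scale and multiplied back onto each subject's total, so volumes
co-scale with head size and the analysis-side division recovers the planted
structure exactly.

Structure is planted at the level of construct scores.  Exogenous scores are
the standardized equal-weight composites of the simulated indicators (so a
"gene score" is exactly what an equal-weight analysis would compute from the
dosages); endogenous scores are the planted linear combination of parent
scores plus a Gaussian residual scaled to give unit variance, with a
configuration error if the planted coefficients alone imply variance above 1.
ROI part indicators equal `loading × score + residual`, with two deliberate
choices:

* the residuals of a construct's parts are **balanced to sum to zero**, so the
  equal-weight composite of the parts equals the construct score exactly.
  The configured `indicator_loading` (default 0.9, inside the study's reported
  0.85–0.97 bilateral band) is then the population value of the estimated
  loading, and planted structural paths pass through the measurement layer
  without attenuation — which is what makes ±0.05 path / ±0.02 loading
  recovery a sharp test of the estimator rather than of an arbitrary
  attenuation factor;
* within-gene SNP dependence uses a latent equicorrelated Gaussian copula
  (default latent correlation 0.8, chosen so multi-SNP gene loadings land in
  the study's 0.83–0.92 band), which preserves the marginal genotype
  frequencies exactly in expectation.

What the generator does **not** emulate: linkage patterns beyond exchangeable
within-gene correlation, gene–environment dependence, measurement error in the
phenotype instruments, site/scanner effects, and any non-linear or
non-Gaussian structure in the volumes.  The zero-truncation of severity is a
mild, realistic departure from Gaussian residuals; it attenuates paths into
the outcome by a few percent, which the recovery tolerances absorb.  Passing
recovery tests therefore demonstrates that the estimator recovers the model it
assumes under study-scale conditions — not that the study's real-data
estimates are correct.

## Problem sizes used in the checks

Recovery uses 20 independent simulations at n = 2,000 with the default planted
paths at λ = 0 and compares the across-seed mean of each planted coefficient
(tolerance ±0.05; loadings ±0.02): averaging isolates estimator bias from the
~0.02 per-seed sampling noise the 20 replicates are there to cancel.  The
type-I calibration uses the null generator on a 5-ROI submodel (the three
mediating ROIs plus two others, 119 paths) at n = 231 with 500 resamples per
seed and 20 seeds, giving 2,380 per-path decisions; the observed rate is
checked against 0.05 ± 0.02.  The bootstrap coverage check uses a
single-predictor toy at n = 200 with 300 resamples and 80 outer replicates.
These sizes keep the full suite and the acceptance script to a few minutes
while leaving the binomial error of each rate comfortably inside its band.

## Known limitations

The reproduced-covariance definition (above) makes GFI/SRMR conservative for
sparse structural models.  Single-indicator constructs contribute no
measurement information, so their "loadings" are definitionally 1.  The ridge
penalty biases paths toward zero at the selected λ — by design — so
regularized estimates should not be compared against unregularized planted
values without accounting for shrinkage.  The CV loss is a package contract
(out-of-fold structural residuals); other losses would select different
penalties.  Listwise deletion is the only missing-data policy.
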