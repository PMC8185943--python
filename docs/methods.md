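# Methods

## Scope and data model

The package operates on person-by-item matrices of ordinal responses
(integer categories 1..K, NaN for missing) with optional person
covariates. All analyses assume a single latent trait; multidimensional
structure is out of scope and will surface as misfit rather than being
modelled. Missing responses are handled by pairwise deletion in the
correlation stage and by dropping the item from the person's likelihood
in the IRT stage; both are appropriate only for ignorable missingness at
the per-mille rates the package targets.

## Polychoric correlations

Two-step maximum likelihood: thresholds are fixed at inverse-normal
quantiles of each item's cumulative category proportions (computed on the
pairwise-complete subsample), then the latent correlation is found by
bounded scalar maximization of the bivariate-normal likelihood of the
contingency table on [−0.999, 0.999] (tolerance 1e−6). Two-step rather
than joint ML because it is standard practice, orders of magnitude
faster, and the efficiency loss is negligible at the sample sizes in
scope. Infinite thresholds (unobserved edge categories) are truncated at
±8 on the normal scale. Standard errors come from the observed
information of the profile likelihood; estimates that hit the ±0.999
clamp report an undefined SE with a warning. Bivariate-normal rectangle
probabilities use a vectorized Gauss–Legendre/tail-expansion evaluation
of the bivariate normal CDF accurate to ~1e−14, so polychoric error is
statistical, not numerical.

Skewness in the descriptives table is the adjusted Fisher–Pearson sample
estimator (the common spreadsheet/`scipy bias=False` convention); the
per-item mean inter-item correlation averages signed values, not absolute
values.

## Ordinal factor analysis

The one-factor model is fitted to the correlation structure: minimize
(r − σ(λ))' W⁻¹ (r − σ(λ)) with σ_jk = λ_jλ_k, factor variance fixed at
1, W the diagonal of the asymptotic covariance Γ of the polychoric
vector. Γ is estimated by a nonparametric person bootstrap (default 200
replicates, seeded). A bootstrap rather than an analytic Γ keeps the
covariance estimator agnostic to how the correlations were produced and
directly testable; the price is runtime, which is why the replicate
matrix is computed once per dataset and sub-indexed when items are
dropped during reduction (valid because each pairwise correlation depends
only on its own pair's margins).

The test statistic is the scaled-and-shifted T = (nF − b)/a with a, b
chosen from tr(UΓ) and tr((UΓ)²) so that T has mean df and variance 2df
under the fitted model, U being the DWLS residual-weight operator. Fit
indices: CFI/TLI against an independence baseline corrected the same way;
RMSEA with its 90% CI from noncentral-χ² inversion; SRMR/CRMR as the root
mean square correlation residual (identical for correlation input, both
reported for interface parity); WRMR with the bootstrap variance diagonal.
These are the conventional DWLS-based estimators; the categorical-ML and
"unbiased" variants cited in some applied work are deliberately not
implemented, so printed fit values from studies using those estimators
are comparable only qualitatively.

Modification indices are 1-df score tests in the DWLS metric for freeing
one residual correlation; the EPC is score/information and approximates
the omitted residual correlation itself, which is what makes the
|EPC| ≥ 0.1 flag interpretable. Power is computed for detecting
|EPC| = 0.1 at α = 0.05 from the noncentrality MI·(0.1/EPC)²; α and the
0.80 "high power" convention are reporting choices, not estimates.
Degenerate (just-identified, p = 3) models report MI = 0.

Green–Yang categorical omega reconstructs the sum score's true-score and
total variances from bivariate-normal category probabilities implied by
the fitted loadings and thresholds. The CI is a bias-corrected and
accelerated person bootstrap in which thresholds, polychorics and the
factor fit are re-estimated per resample (weights held at the original
DWLS diagonal); acceleration uses a 20-group delete-block jackknife
because a full person-level jackknife would multiply runtime by n.

Non-positive-definite polychoric matrices are eigenvalue-smoothed (floor
1e−4, rescaled to unit diagonal) with a warning before fitting.

## Item reduction and category collapsing

The elimination loop alternates three screens until the retained set has
no polychoric correlation above the cutoff (default 0.7) and no
modification-index flag at |EPC| ≥ 0.1: (1) items with two or more
supra-cutoff correlations are removed one at a time, worst first, with
re-screening after each removal (a batch mode removes every item above a
count threshold in one block first, reproducing block-style published
workflows); (2) isolated supra-cutoff pairs lose their less-general
member; (3) after a CFA refit, the less-general member of the top-MI
flagged pair is removed. Ties in step 1 break by higher mean inter-item
correlation, then lower generality. Content generality cannot be computed
from response data, so it is an explicit, required configuration — for
the ISQ the shipped ranking encodes the published retain/drop choices.
Every removal is logged with its reason and statistics, and the final set
is re-audited against both criteria before the trace is returned.

Category collapsing: a category is collapsible when its characteristic
curve is nowhere the pointwise maximum on a dense grid (≥ 81 points
spanning [−4, 4]). One shared map is derived per scale (the published
workflow applied a single 7→5 recode to all items): interior categories
flagged for at least half the items are merged pairwise left to right; a
lone flagged category joins whichever interior neighbour's curve peaks
lower; extremes never merge and no new category absorbs more than two old
ones. Per-item maps are intentionally not the default.

## Graded response model

Bock–Aitkin EM with the latent trait fixed to N(0, 1) in the calibration
group. Quadrature: 61 equally spaced nodes on [−6, 6] with normalized
normal-density weights (configurable); with these settings EAP scores
agree with a 2001-point dense-grid integration to better than 1e−6.
M-steps solve each item's expected-count multinomial likelihood exactly
(L-BFGS in a (log a, b₁, log-gap) parameterization that enforces
threshold ordering), with tables normalized so replication weights scale
out. Convergence: max parameter change < 1e−4, or a stalled
log-likelihood increment (< ~1e−7) for ridge-flat directions such as a
single binary item's slope; the marginal log-likelihood is asserted
nondecreasing every iteration. Standard errors use the empirical
cross-product information built from per-person Fisher-identity scores.

Limited-information fit: the statistic vector stacks all univariate
category proportions and the p(p−1)/2 bivariate cross-moments E[X_jX_k];
a Browne-type residual-based quadratic form with the sample covariance of
the per-person statistic vector gives a χ² statistic with
df = p(p−1)/2 − p (univariate margins saturate the thresholds; the
cross-moments test the slopes). The exact weighting is
implementation-defined up to that df identity and is validated by
parametric-bootstrap calibration of its p-values rather than against any
published table. RMSEA and CFI (against an independence baseline on the
same statistics) derive from it; SRMR compares observed polychorics to
slope-implied loading products.

Local dependence: per pair, observed vs model-expected bivariate tables
compared by Pearson X², standardized as (X² − df)/√(2df); cells with
expected counts below 1 are pooled into neighbours (noted per pair) with
df adjusted. Values above 10 are flagged.

Scoring: EAP with posterior SD; person reliability is 1 − PSD² (the
formula is stated because conventions differ); T = 50 + 10·θ̂, anchored
to the calibration sample's latent metric. Marginal reliability is the
empirical ratio var(θ̂)/(var(θ̂) + mean(PSD²)) with a percentile person
bootstrap (default 1000 resamples) that resamples scores without
refitting; refit-per-resample is available but changes third-decimal
behaviour only.

## Differential item functioning

Two-stage iterative Wald procedure (stage count configurable): every item
is first tested with all other items as anchors, the focal group's latent
mean and variance re-estimated in each fit; items flagged after
Benjamini–Hochberg FDR (α = 0.05, family = items within one grouping
variable) lose anchor status, and all items are re-tested against the
purified anchors. The omnibus statistic tests (a_j, b_j·) jointly
(df = K) using the inverse empirical cross-product information of the
full multigroup parameter vector; flagged items get per-parameter z
follow-ups. Group construction assigns boundary values to the "≤" group,
requires the covariate for ≥ 90% of persons, errors below 10 members per
group and warns below 50; multi-level covariates (e.g. gender identity)
require an explicit dichotomization mapping — none is assumed.

Under the intersection null the BH step makes per-item flag rates
conservative (≈ α/m), which the type-I simulation confirms; power for a
slope shift of 1.0 → 1.8 at n = 500/group exceeds 0.95.

The demographic regression is OLS of θ̂ on age, sex and their
interaction. Age is centred at the sample mean so the reported sex
contrast β_F−M refers to an average-aged person despite the interaction
term; persons outside the binary sex coding are excluded from this
regression only, with the count reported.

## Synthetic data generator

The generator emulates the study conditions the pipeline was built for:
682 persons in an adult (n = 495) and adolescent (n = 187) cohort, 20
seven-category logistic GRM items, completely-at-random missingness at
4e−5, and six redundant item pairs. Default slopes for the study-like
configuration derive from the published 20-item loading profile
(0.61–0.89), which is what reproduces the scale's redundancy regime —
with generic moderate loadings almost no pair crosses 0.7 and the
reduction stage has nothing realistic to do. Generic banks
(`default_items`) use slopes uniform on [1, 2.5] and thresholds from
sorted standard-normal draws pushed at least 0.3 apart and recentred —
documented defaults, not estimates.

Doublets: both members load γ (default 0.5) on a shared standard-normal
factor, with the common loading rescaled to λ√(1−γ²) on the standardized
underlying-variable scale, so the pair's latent correlation rises to
λ_jλ_k(1−γ²) + γ² while correlations with other items shrink by √(1−γ²).
Marginal category probabilities are preserved exactly on that
standardized scale, i.e. up to the logistic-vs-normal residual shape
difference (third-decimal effects); preserving them exactly while raising
the pair correlation above λ_jλ_k is impossible, and the inflated pair
correlation is the property the downstream diagnostics must detect.

Covariates (age by cohort, sex, gender, bracketed household income) are
drawn independently of each other and of the trait; the generator does
not emulate covariate dependence, non-ignorable missingness, response
styles, acquiescence, or any content semantics. Passing tests therefore
demonstrate that the machinery recovers structure it is pointed at —
not that real questionnaire data satisfy the model.

A note on calibration conventions: the slope-implied loading
λ = a/√(a² + π²/3) treats the logistic residual as if it were normal with
matched variance. Polychoric correlations of logistic-GRM data converge
to values a few hundredths above λ_jλ_k, so factor loadings recovered
from such data sit slightly above the conversion formula. Tests that need
a population value for an estimator therefore compute it by running the
estimator on an n = 200000 (omega) or n = 100000 (marginal reliability)
draw rather than from the conversion formula.

## Problem sizes and tolerances used in the shipped checks

The test suite and acceptance script use: n = 2000 for the 8-item
recovery study (slope RMSE < 0.15, threshold RMSE < 0.12); 200 no-DIF
replicates at n = 500/group with 4 four-category items for the type-I
check and 20 replicates for power; 20 replicates at n = 2000 for the
doublet LD/MI top-flag check; bootstrap replicate counts of 60–300 in
tests against the 200/1000 analysis defaults. These sizes were chosen so
each property is measured with enough Monte-Carlo precision for its
stated band while the whole suite stays desk-scale; the analysis defaults
themselves are unchanged.

## Known limitations

- Single-factor structure only; no bifactor or multidimensional fallback.
- The bootstrap Γ makes CFA runtime O(B · p²) polychoric fits; for p much
  beyond 30 an analytic Γ would be the right extension.
- The C2-type statistic's weighting is implementation-defined (calibrated
  by simulation, df-identical to the cited statistic) and will not
  numerically match other software's C2 values on the same data.
- DIF supports exactly two groups per comparison; ordinal-covariate
  (MIMIC-style) DIF is not implemented.
- The shipped calibration artifacts are synthetic and labelled as such;
  scoring real respondents requires a calibration fitted to real data.
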