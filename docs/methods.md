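# Methods

This note documents the models, numerical choices, and defaults behind
`bulkdecon`, and what the synthetic validation does and does not establish
about real data.

## Cell contribution scores

The deconvolution model is a linear RNA mixture: the expected linear-scale
expression of gene *g* in a bulk sample is `sum_k f_k * S_gk`, where `f` is
the cell composition and `S` the signature matrix of expected per-type
expression. Scores are the coefficients of a non-negative least squares
(NNLS) fit of each sample's CPM vector, restricted to marker genes, on
signature columns normalized to unit sum over those markers. Properties
that follow directly and are enforced by tests: non-negativity; scale
equivariance (CPM rescaling rescales scores); exact recovery of noiseless
mixtures; and agreement with an exhaustive active-set NNLS oracle on small
instances. Column unit-sum normalization makes the coefficient an
RNA-mass-style quantity in arbitrary units — comparable across samples
normalized together, not across datasets, and not an absolute cell count.
An optional `normalize="sum1"` flag projects scores onto the simplex;
scores are left un-normalized by default since the downstream models are
invariant to common rescaling within a dataset.

Marker selection: a gene is a marker of its top cell type when that value
is at least `min_fold` (default 4) times the second-highest type and at
least `min_expr` (default 1, CPM-equivalent signature units); per type the
top `max_per_type` (default 50) genes by fold are kept, with deterministic
(fold desc, gene id asc) tie-breaks. Types left without markers are flagged
unscoreable and excluded from the fit rather than silently scored zero.

## Glucocorticoid signature score (ssGSEA)

Per sample, genes are ranked by expression (average ranks on ties, highest
expression = rank N). Walking the ranking from top to bottom, in-set genes
add `rank^alpha / sum_in-set rank^alpha` to the in-set ECDF, out-of-set
genes add `1/(N - |S|)` to the out-of-set ECDF, and the score is the sum of
the running difference over all N positions — an integrated weighted
Kolmogorov–Smirnov-style statistic. `alpha = 0.25` and average-rank ties
follow common ssGSEA convention; `alpha = 0` recovers uniform `1/|S|`
steps. The score depends on expression only through within-sample ranks,
so counts, CPM and log-CPM give identical values. Scores are used raw as a
model covariate (an optional flag rescales by the max–min span across
samples); since the downstream linear models are invariant to affine
rescaling of a covariate, this choice does not affect test statistics.
The glucocorticoid gene set itself is user-supplied (GMT); synthetic runs
use the generator's planted set.

## Cell-level statistics

Treatment effects on scores use OLS per cell type:
`cells ~ subject + GC_signature + treatment`, subjects as fixed-effect
indicators (absorbing all stable between-subject differences — the
within-subject estimator), fitted per treatment arm. With two timepoints
per subject this is algebraically a regression of post−pre differences on
an intercept and the GC change; the test suite checks the identity to
1e-8. Response (EULAR responder vs non-responder) is subject-constant and
therefore enters only through a `treatment:response` interaction; the
stratified paired signed-rank contrasts within each response class are
reported at FDR < 0.1, while disease and treatment contrasts use FDR <
0.05. Two-group composition contrasts use the Wilcoxon rank-sum
(exact where available) or signed-rank test. All p-value families are
Benjamini–Hochberg corrected through one shared routine.

Degenerate inputs: all-tied contrast values give p = 1 with a warning;
unpaired subjects are dropped with a warning; rank-deficient designs raise
an error naming the aliased columns; a saturated fit (zero residual) gives
a p-value at the machine floor rather than NaN.

## DGE and attribution

Counts enter as `y = log2((count + 0.5)/(lib + 1) * 1e6)`. Precision
weights follow the mean–variance-trend approach: per-gene OLS residual
quarter-root variances are lowess-smoothed (span 0.5) against mean
log2-count, and each observation's weight is the trend value at its fitted
log2-count to the power −4. Below 10 genes the trend is meaningless and
constant weights are used with a warning.

Per-gene weighted least squares is followed by empirical-Bayes variance
moderation: the prior `(d0, s0^2)` is the method-of-moments fit on
`log s_g^2` (digamma/trigamma moments, Newton trigamma inversion), the
posterior variance is `s~^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g)`, and the
moderated t has `d0 + d_g` degrees of freedom. When the observed spread of
log-variances does not exceed its chi-square sampling floor, `d0 = +inf`
and every posterior variance equals `s0^2` (in particular, exactly equal
observed variances collapse to a common posterior constant — gene ranking
is unchanged but the scale is the pooled prior, not the per-gene value).
The implementation was cross-checked against an independent established
empirical-Bayes implementation on a fixture; the reference values are
frozen in the test suite.

Attribution fits the treatment contrast twice on identical samples: model
A (`subject + GC + percent-duplicates + treatment`) and model B (A + the
contribution scores of the adjustment cell types, default a CD4 T-cell
population, a monocyte population, and plasma cells; configurable).
Weights are re-estimated per model (a flag shares them). Genes are
classified at FDR 0.05 (configurable) into both / pre-only / post-only /
neither, and the explained fraction is `(N_before − N_both)/N_before`
(undefined, flagged, when `N_before = 0`).

## Response prediction

Baseline scores are inverse-rank normalized (Blom offsets:
`Phi^-1((r − 3/8)/(n + 1/4))`, average ranks on ties; constant features
are dropped). Nested CV: stratified 4/5 outer splits repeated
`outer_repeats` (default 100) times; within each training set, 10-fold
stratified CV selects `(l1_ratio, C)` by mean AUC from a grid (default 10
mixing values × 20 log-spaced strengths); the winner is refit on the full
training set and scored on the held-out fifth (AUC-ROC, PR-AUC; positive
class = non-responder). Ties in inner AUC — routine on separable data —
resolve to the least-regularized candidate. Threshold metrics
(Se/Sp/Pr/Re/F) pool the confusion counts over repeats at probability 0.5
(flag). The full nested scheme, not just the outer split, is repeated per
repeat, and tuning never sees held-out samples. Calibration checks run
with a reduced 3×5 grid at n = 200 with 100 repeats — grid size trades
runtime for tuning resolution and does not affect the null distribution.
Note the permutation-null PR-AUC sits slightly above the class prevalence
(~0.25 vs 0.32 at 40-sample test folds): average precision is upward-biased
in small test sets, which is why the calibration tolerance on it is ±0.1.

## Meta-analysis

Per study and cell type, the case/control standardized mean difference is
Hedges' g, `J * (m1 − m0)/sd_pooled` with `J = 1 − 3/(4m − 1)`,
`m = n1 + n0 − 2`, and variance `(n1+n0)/(n1 n0) + g^2/(2m)`. Pooling is
DerSimonian–Laird: `tau^2 = max(0, (Q − (k−1))/(sum w − sum w^2/sum w))`
with fixed-effect weights `w = 1/v`, then inverse-variance weights
`1/(v + tau^2)`. `tau^2 = 0` reduces exactly to the fixed-effect estimate;
a single study is passed through with `tau^2` undefined. The module
consumes per-study summary tables; a helper converts any scored cohort
into study effects.

## Synthetic cohort generator

The generator emulates a paired pre/post RA cohort: 30 healthy, 53
early-RA (MTX), 37 established-RA (TNFi) subjects by default, two samples
each; ~22% / ~29% non-responders per treated arm; 29 blood cell types with
a documented roster of monocyte/T/B/NK/DC subsets (a stand-in roster, not
a reconstruction of any proprietary signature collection).

Fractions: per subject a Dirichlet deviation `u_s` around the baseline
PBMC composition (`subject_concentration = 12`, giving ~40% between-subject
CV for mid-size populations — large enough that a 20%-CV flow measurement
still tracks the truth at Spearman r > 0.9); per sample a Dirichlet draw
around the tilted subject mean (`sample_concentration = 300`), which makes
pre/post fractions of one subject strongly correlated (r ≈ 0.95). Disease
and treatment act as multiplicative tilts on the Dirichlet mean (monocytes
and Th1/Th2 up and mature NK down in RA; memory-B/plasma/Th down after
MTX; mature B up after TNFi; responder-specific tilts concentrate the
treatment effect in responders). Tilting renormalizes the simplex, so the
effective direction of a type is its tilt relative to the weighted mean
tilt; the direction-consistency experiment computes planted directions
from the analytic tilted mean for exactly this reason.

Counts: expected expression is the fraction-weighted signature mixture;
cell-intrinsic effects multiply designated (gene, cell types) contributions
by `2^lfc` in post-treatment samples; glucocorticoid-set genes are scaled
by `exp(loading * exposure)` with log-normal exposure in RA samples and
zero in healthy; counts are negative-binomial with shared dispersion 0.1
(typical bulk RNA-seq overdispersion) at log-normal library sizes (mean
1e6 over a 2000-gene universe, depth-per-gene comparable to a 15M-read
run over 20k genes). Flow tables are aggregated true fractions times a
mean-one log-normal factor (`cv_noise = 0.2`), clipped to [0, 1].

What passing synthetic tests shows: the estimators recover what the
forward model planted (composition shifts, intrinsic effects, response
signal, direction of pooled effects) at realistic noise. What it does not
show: robustness to signature mismatch between reference and tissue state
(disease-altered cell states), ambient/contaminating RNA, batch structure,
library-preparation artifacts, or cell types absent from the reference —
all real-data failure modes outside the generator.

## Problem sizes used in validation

Deconvolution recovery: K = 6, 40 marker genes, 60 samples. Attribution
regimes: 200 simulations per regime of a 30-pair arm, 500 genes, 10 cell
types (composition-only plants tilts on three types and adjusts for their
scores; intrinsic-only freezes fractions and plants lfc = 1 on 50 genes).
CV calibration: n = 200, 100 outer repeats. Meta direction consistency:
three studies of 60 + 60 samples, 13 cell types. Null FDR of the cell
contrasts: 200 simulated null cohorts. These sizes were chosen as the
smallest at which the Monte-Carlo properties are stable.

## Known limitations

- NNLS-on-markers is a documented stand-in for proprietary deconvolution
  methods; scores are arbitrary-unit proxies and are not comparable across
  differently-normalized datasets.
- Subject fixed effects assume two timepoints per subject; mixed-effects
  or GEE alternatives are out of scope.
- The attribution dichotomy inherits the FDR threshold: "explained" means
  "no longer FDR-significant after adjustment", which conflates effect
  attenuation with power loss near the threshold.
- The elastic-net report estimates discrimination, not calibrated risk;
  threshold metrics at 0.5 are sensitive to class imbalance.
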