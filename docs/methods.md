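# Methods

## Statistical model

Protein *g* is modelled as a one-factor layout: sample *j* in group *i* has
mean μᵢ and residual variance σ²_g. The pooled variance
s²ₚ = Σᵢ (nᵢ−1)sᵢ² / Σᵢ (nᵢ−1) uses all groups on d_g = N − k degrees of
freedom, where N counts only the samples present in the fitted matrix.
Because the matrices are complete-case, d_g is a single integer shared by
all proteins; per-protein df heterogeneity from missing values is
deliberately out of scope.

The empirical-Bayes layer puts a scaled inverse-χ²(d₀, s₀²_g) prior on
σ²_g. Fisher's-Z theory gives, for e_g = log s²ₚ − ψ(d_g/2) + log(d_g/2),

- E(e_g) = log s₀² − ψ(d₀/2) + log(d₀/2)
- Var(e_g) = ψ′(d_g/2) + ψ′(d₀/2)

The per-protein prior mean replaces E(e_g) with the value predicted from a
loess fit of log s²ₚ on the covariate x, so
s₀²_g = exp(pred(e_g) + ψ(d₀/2) − log(d₀/2)) with
pred(e_g) = fitted(log s²ₚ) − ψ(d_g/2) + log(d_g/2). The covariate is
log₂ PSM count for labelled data and log₂ peptide count for label-free
(`covariate="count"`); `"intensity"` substitutes the mean log₂ abundance
(the limma-trend-style variant); `"constant"` reduces to a single flat
prior. Natural logs are used throughout the moment equations; only the
covariate is base-2 — each equation keeps its conventional form.

d₀ is estimated by a grid search d₀ = k/10, k = 1, 2, …, minimizing
|mean[(e_g − pred e_g)²] − ψ′(d_g/2) − ψ′(d₀/2)|, stopping at the first
increase. The absolute value is essential: without it the expression is
monotone in d₀ and "stops decreasing" would be degenerate. If the excess
spread mean[(e_g − pred)²] − ψ′(d_g/2) is ≤ 0 there is no finite solution
and d₀ = +∞ is returned (posterior variance = prior variance, normal
reference distribution); the same happens if the grid cap (500 by default)
is reached while still improving. A continuous Newton-based estimator via
the trigamma inverse (`estimate_d0_newton`) is available; the grid is the
default because its k/10 output is the documented behaviour. Parameter
recovery for d₀ ∈ {2, 4, 10} at d_g = 4, n = 5000 is within a few percent
(see `tests/test_acceptance.py`).

The posterior variance is (d_g s²ₚ + d₀ s₀²)/(d_g + d₀); the moderated t
for contrast G1 − G2 is the mean difference over
s_post·√(1/n₁ + 1/n₂) on d_g + d₀ df, and the moderated F divides the
between-group mean square by the posterior variance on (k−1, d_g + d₀) df.
All contrasts of one fit share a single (d₀, s₀²) estimated once from the
pooled variances. BH step-up adjustment (via statsmodels) is applied per
contrast.

Degenerate inputs: proteins with s²ₚ = 0 (all replicates identical) cannot
enter the log-variance regression; they are excluded from trend and d₀
estimation but retained in the output with posterior variance equal to the
prior variance evaluated at their covariate. Zero-denominator t statistics
give t = 0, p = 1 when the means also agree and ±∞, p = 0 otherwise.

The ordinary t is Welch's statistic (unpooled denominator) with
Welch–Satterthwaite df — the pooled-variance route is available through the
ANOVA/moderation path, and for balanced designs with equal group variances
the two coincide. The as-printed two-group F formula lacks the (k−1)
between-group divisor; the implementation uses the standard between-group
mean square so that F ~ F(k−1, d_g) and null p-values are uniform (for
k = 2 the two readings agree).

## Loess

`deqms.loess` implements plain Gaussian loess: at each target point the
q = floor(span·n) nearest neighbours receive tricube weights
(1 − (d/h)³)³ and a degree-1 or degree-2 weighted polynomial is solved;
no robustness iterations. Defaults span 0.75, degree 2 match the reference
local-regression defaults, and the neighbourhood rule was validated against
R's `loess(..., surface="direct")` to ~1e-6 (see `tests/test_loess.py`).
Replicated covariate values (counts) are handled natively — no jitter; if a
window collapses onto ties the local mean of the ties is used. Predictions
outside the fitted covariate range are clamped to the boundary, and fewer
distinct covariate values than degree+1 triggers a flat-prior fallback with
a warning. Fitting is done once per unique covariate value, so the count
covariate (≤ ~30 distinct values) is effectively O(unique x · n).

## Summarization and counts

Median sweep: log₂-transform; subtract each PSM row's median across
samples; per protein and sample take the median over the protein's rows;
subtract each sample column's median. Output column medians are exactly 0
(asserted to 1e-12). Even-length medians are the mean of the two central
order statistics. Rows with any missing intensity (raw 0, "NA" or empty)
are dropped rather than imputed, keeping one d_g for all proteins. One pass
of sweeping removes per-row (PSM) scale factors exactly and per-sample
scale factors exactly only for two samples; for more samples a single
column shift is removed only approximately — this is a property of the
procedure itself, and the tests assert the exact invariances only.

Reference-ratio summarization divides each row by the (mean of the)
reference-channel intensities, takes per-protein per-sample medians of the
ratios, then log₂; reference columns are excluded from the output. All rows
assigned to a protein are used (no unique-peptide filtering).

Multi-batch tables are summarized per batch and inner-joined on protein id
(a protein must be quantified in every batch). Per-batch counts are
collapsed by one of min / mean / median / sum / max; mean and median are
rounded half-up and floored at 1. The default is min: the weakest batch
limits the quantification quality of the combined profile, and on the
synthetic multi-batch data the min metric yields the smallest trend RSS.

## Diagnostics

`variance_profile` bins the pooled within-group standard deviation (pooled,
not per-group — the per-group alternative is noisier at triplicate depth)
by PSM count, with counts above `max_count` (default 20) merged into the
last bin. `rss_of_fit` reports Σ(log s²ₚ − fitted)² overall and per count
bin; for the flat prior the fitted value is the single prior log-variance.
`pauc` sweeps descending score thresholds (ties grouped into one step),
integrates the ROC over specificity ∈ [floor, 1] by trapezoid with
interpolation at the cutoff, and normalizes by (1 − floor) so 100% is
attainable; under that normalization the chance level is (1 − floor)/2·100
÷ (1 − floor) — i.e. 50·(1 − floor)% of the axis, e.g. 2.5% at floor 0.95.
pAUC is invariant to strictly monotone score transforms and only pAUC
*orderings* are used in the benchmark comparisons.

## Synthetic data

The generators define the study conditions and are bit-reproducible under
a fixed seed.

Null simulation: 6000 proteins × 9 samples, 30 count groups (1–30 PSMs) of
200 proteins; each protein's values are i.i.d. Normal(0, v(c)) with
v(c) = 0.02 + 0.20·c^(−0.8). The curve is a monotone stand-in for a fitted
real-data count–variance relation (which is not published as numbers); its
scale matches deep TMT cell-line data where single-PSM proteins show
log₂-ratio standard deviations near 0.45 falling to ~0.2 at high counts.
Null comparisons split the 9 samples into two disjoint triples: the C(9,3)
= 84 choices of the first triple, with the second triple the
lexicographically smallest triple of the remainder. This reproduces the
canonical count of 84 comparisons without repetition; full enumeration of
unordered disjoint triple pairs (840) is available via `all_pairs=True`.
Within a count group the variance is deterministic, so the true d₀ given
the trend is infinite; the estimator correctly reports +∞ there, and
false-positive rates at p < 0.01 sit in the nominal band for the
count-covariate fit, at or slightly below the flat-prior fit, with the
Welch t conservative at triplicate depth.

Spike-in benchmark: background proteins at equal expected abundance, spike
proteins multiplied by the ratio (default 2) in the second condition, in
triplicates. Counts are truncated-geometric on 1–30; each observation is
protein abundance × per-row ionization efficiency × 2^(protein-level sample
effect + per-observation noise), with defaults psm_sd = 0.45 and
protein_sd = 0.12 on the log₂ scale. Protein summaries are medians over c
rows, so protein-level variance falls with count mechanically, as in real
data — the count-dependent prior then outperforms the flat prior by ~5–7
pAUC points at specificity > 95%. What the generator does *not* model:
ratio compression from co-isolation interference, compositional bias of
median sweeping under large spike fractions (visible as mild fold-change
shrinkage at the default noise), missing values, and correlated peptides.
Passing benchmarks here show correct machinery and the expected ordering
of methods, not field performance.

Multi-batch generator: 3 batches × 3 groups, one sample per (batch, group);
per-batch counts are independent truncated-geometric and protein values in
batch b have variance v(c_b) with the steeper curve
v(c) = 0.01 + 0.25·c^(−1.5). The steeper decay encodes that per-batch
protein summaries from 1–2 PSMs are disproportionately noisy; it is what
makes the weakest batch dominate the within-group variance of profiles
assembled across batches, and hence what the min-count metric is designed
to capture. With a shallow decay the min metric has no advantage — the
min-is-best ordering is a statement about data in this regime, not a
universal fact.

## Numerical choices and defaults

| parameter | default | notes |
|---|---|---|
| loess span / degree | 0.75 / 2 | reference local-regression defaults |
| d₀ grid step / cap | 0.1 / 500 | k/10 output; +∞ past the cap |
| trigamma inverse tol | 1e-8 | Newton on 1/ψ′, start 0.5 + 1/y |
| count metric | min | weakest-batch principle |
| alpha (reporting) | 0.01 | BH-adjusted threshold in summaries |
| result TSV precision | 6 significant digits | round-trips to 1e-5 relative |

Ties in counts are left as replicated covariate values. Sample order comes
from the design when both design and matrix specify it; a mismatch is an
error, never a silent reorder. All tabular formats are single-header TSV
with "." decimals.

## Known limitations

- One grouping factor only: no arbitrary design matrices, covariates or
  mixed effects.
- Complete-case matrices only; no imputation, no per-protein df.
- No robust/winsorized moderation and no observation-level weights.
- Variance-stabilizing and quantile normalization are out of scope; the
  package summarizes by median sweep or reference ratios only.
- The test-suite problem sizes (2000–6000 proteins, 10–20 seeds or splits
  per experiment) were chosen as the smallest giving stable orderings and
  calibration bands; all experiments rerun at these sizes in
  `scripts/acceptance.py`.
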