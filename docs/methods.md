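# Methods

This note documents the statistical models and procedures implemented in
`tregscreen`, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the package's numerical conventions.

## Screen normalization and hit-calling

Each well of a screen plate reports the percent of lineage-positive cells
(e.g. %FOXP3⁺ for the T_reg lineage) and a live-cell count. Negative
controls sit at a sub-maximal differentiation level and positive controls
near-maximal (defaults 30% and 95%, matching the typical sub-/near-maximal
fractions of cytokine titrations), so a compound's *fractional enhancement*
is its effect normalized to the positive–negative span,
`Fr = (x − neg)/(pos − neg)`, and its *fractional inhibition* under
near-maximal conditions is `(dmso − x)/dmso`.

The per-batch pipeline:

1. **Median centering.** Each plate's values are centered on the median of
   all wells except positive controls. This removes additive plate effects
   without assuming anything about the (small) fraction of active compounds.
2. **Batch control statistics.** Centered controls are pooled batch-wide
   (experimental plates plus the dedicated 48+48 control plate) and
   summarized per class by median and robust standard deviation
   (1.4826 × median absolute deviation, the Gaussian-consistent MAD scale).
3. **Plate QC.** A control is in range when it lies within ±3 batch robust
   SD of its class median. A plate is excluded when ≤75% of its controls
   are in range (the boundary itself excludes) or when the plate's
   positive–negative median separation falls below 3 pooled robust SD (a
   Z′-like dynamic-range floor). Excluded plates are flagged, never
   silently dropped. The ±3 SD window and 3-SD separation floor are
   documented choices: the rules are standard but their cutoffs were open.
4. **Cellularity correction** (sub-maximal T_reg condition only). Culture
   cellularity and %FOXP3⁺ are negatively related in the sub-maximal
   condition, so cytotoxic compounds spuriously score as enhancers. The
   correction regresses centered %positive on log live-cell count over
   negative-control and compound wells and replaces each value by its
   residual plus the fitted value at the negative-control median
   cellularity. Two estimator details matter:
   * the covariate is **plate-median-centered** the same way the response
     was — regressing a plate-centered response on a raw covariate lets the
     centering operation leak into the fit and attenuates the slope by
     roughly a factor (1 − 1/n_wells);
   * the line is fitted by **Huber M-estimation** rather than ordinary
     least squares, because wells carrying real compound effects are
     extreme response outliers at arbitrary cellularity and would otherwise
     both inflate the slope's sampling noise and invalidate its confidence
     interval. `robust=False` restores OLS.
   Wells with live cells below 10% of the negative-control median are
   flagged toxic and excluded from enhancement calling by default
   (percent-positive is unstable at extreme death); the flag is public
   config because the correction itself is the interesting quantity when
   studying cytotoxicity confounding.
5. **Robust Z-scores.** Centered negative-control and compound wells on
   passing plates are pooled; wells within ±2 robust SD of the pooled
   median form the negative reference (the trimming constant k=2 is a
   documented choice; the reference set is otherwise unspecified by the
   procedure the pipeline follows). Z = (value − reference mean)/robust SD.
6. **Control calibration.** A Gaussian/identity GLM of Z on control class
   yields fitted levels ẑ_neg, ẑ_pos; fraction-of-positive activity is the
   linear interpolation `(z − ẑ_neg)/(ẑ_pos − ẑ_neg)`. Inverted controls
   (ẑ_pos ≤ ẑ_neg) are a hard error.
7. **Hit calling.** Compounds at ≥0.3 of positive-control activity are
   hits (0.3 is the fractional enhancement of the weakest validated
   enhancer, artemisinin; ties at the threshold are hits). The criterion is
   applied to the cellularity-corrected track by default; correction can be
   disabled.

## Dose–response models

Doses are modelled on the log₁₀ scale (panels span ≥1000-fold). The single
sigmoid is

    s(d; d_m, r_i, r_f, α) = r_i + (r_f − r_i) / (1 + e^{−4α(d − d_m)})

with midpoint d_m, initial/final responses r_i, r_f and midpoint slope
α·sign(r_f − r_i), α ≥ 0. The impulse (double sigmoid) is the
peak-normalized product of an onset and an offset sigmoid,

    f(d) = (1/r_p) · s(d; d_1, r_l→r_p, α_1) · s(d; d_2, r_p→r_h, α_2),

rising from r_l to the peak r_p around the onset dose d_1 and falling to
r_h around the offset dose d_2 ≥ d_1. The normalizer is interpreted as the
shared peak r_p (so the impulse degenerates exactly to the onset sigmoid
when the offset is disabled, d_2 → ∞ with r_h = r_p); normalizing by the
initial response r_l instead is selectable (`normalizer="initial"`) since
the factor's symbol is ambiguous in the model's usual shorthand.

**Fitting.** Both candidates are fitted by bounded trust-region least
squares (`scipy.optimize.least_squares`, tolerances 1e-12) from a seeded
Latin-hypercube multistart (default 10 starts) plus one data-driven
heuristic start; d_2 is parameterized as d_1 + δ, δ ≥ 0, so the ordering
constraint is built in. The reported model minimizes AICc with two
numerical guards: the RSS is floored at 1e-12 (keeping the criterion finite
on near-perfect fits, and resolving ties in favour of fewer parameters),
and the small-sample correction denominator n − k − 1 is floored at 1 so
the criterion stays defined for the saturated case of the 7-parameter
impulse on a bare 8-point panel. Synthetic panels default to 2 replicate
wells per dose (16 points/curve) — realistic for confirmatory titrations
and comfortably above saturation.

**Reverse query.** EC50 is the smallest tested dose at which the fitted
curve reaches 50% of its peak response parameter (r_f for the single
sigmoid, r_p for the impulse; the onset-side crossing is used for impulse
fits). The single sigmoid is inverted analytically,
`d = d_m + ln((y − r_i)/(r_f − y))/(4α)`; the impulse is solved by grid
bracketing plus Brent bisection (xtol 1e-10). A curve that never attains
the target within the tested range is right-censored at the highest tested
dose; one already above the target at the lowest dose reports the lowest
dose. Flat fits (range < 1e-9) are censored. LD50 applies the same query
to the viability curve (live cells normalized to the negative-control
median) at 50% of its fitted value at the lowest dose, i.e. 50%
cytotoxicity. LD50/EC50 is the therapeutic-index analogue; a censored LD50
yields the lower bound (max dose)/EC50 with a bound flag, and a censored
EC50 leaves the index undefined. A compound is a *specific* T_reg enhancer
when its maximal fitted T_reg enhancement reaches 0.3 while Th1 and Th17
enhancement stay below 0.3 at every tested dose.

## Clustering and PCA

Phenotypic feature matrices (LD50/EC50 ratio, maximal T_reg enhancement,
Th1/Th17 inhibition) are standardized per feature to mean 0 and sample
(n−1) SD 1; censored ratios enter at their lower bound. Compounds are
clustered by complete linkage on 1 − Pearson correlation between feature
rows; expression-response instances by complete linkage on Euclidean
distance between normalized principal-component scores. Rows are sorted
lexicographically by identifier before clustering so ties break
deterministically, and complete linkage guarantees non-decreasing merge
heights. PCA treats genes as features: gene columns are mean-centered, the
SVD taken, and the smallest k retained whose cumulative explained variance
reaches the target (default 0.90); "normalized" scores are each component's
scores divided by its singular-value-implied SD (`U·√(n−1)`, unit sample
variance). Replicate expression profiles are arithmetic-averaged within
caller-defined replicate groups; separate doses or cell lines must be given
separate groups and are never merged.

## Signature derivation and enrichment

Differential expression per experiment uses the two-sided pooled-variance
Student's t-test at nominal p ≤ 0.05 with no multiple-testing correction
(Welch's test is selectable). The concordant signature is the intersection
of genes flagged in both experiments with the same direction (identifiers
mapped through an explicit ortholog table when the experiments use
different namespaces — an input, not a network lookup), followed by
marker selection on the combined data: each experiment is min–max scaled
per gene to [0, 1] (zero-range genes set to 0 with a warning; the scaling
is idempotent), the samples concatenated, and genes kept when
|SNR| = |μ_A − μ_B|/(σ_A + σ_B) exceeds 1 (sample SDs; an optional
GenePattern-style floor σ ← max(σ, 0.2|μ|) is off by default).

Volcano overlays count signature genes moving up/down in an observed
comparison and test direction concordance with a 1-df χ² on the 2×2
signature-direction × observed-direction table (no continuity correction);
a zero marginal makes the statistic undefined and is reported as NaN with
a warning rather than an error.

Permutation enrichment draws |disease| genes uniformly without replacement
from the universe each iteration (default 10,000) and records the overlap
with the signature set. Fold enrichment is observed/mean(null); the
one-sided p uses add-one smoothing, `p = (1 + #{null ≥ obs})/(1 + n_iter)`,
avoiding p = 0. The null mean converges to |disease|·|sig|/|universe| and
the p agrees with the exact hypergeometric upper tail, which the tests use
as an independent oracle. The enrichment set defaults to the 127-gene
union of signature genes and associated transcription factors when
reproducing the headline figure; the 111-gene signature alone is equally
valid input.

## Synthetic-data generators

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`.

**Screens.** 96-well plates with 8 positive controls (column 1), 8 negative
controls (column 12) and 80 compound wells; one 48+48 control plate per
batch (default 10 plates/batch). Negative-control and compound wells of the
sub-maximal T_reg condition follow
`pct = β₀ + β₁·ln(live cells) + effect + plate offset + noise` truncated to
[0, 100], with β₁ = −8 %/log-cell and β₀ anchored so the expected level at
median cellularity is 30%; positive controls sit at 95% without the
confound (matching its absence in near-maximal conditions). Defaults:
Gaussian measurement noise SD 3 percentage points; per-plate additive
offsets SD 2; log-normal cellularity (median 5·10⁴ cells, log-SD 0.4);
2% planted enhancers with true fractional enhancement uniform on
[0.3, 1.0] (the effect-size distribution of a real screen is unknown —
this is configuration, not a claim); 2% purely cytotoxic compounds with
viability multipliers uniform on [0.02, 0.10]. QC-failure plates have 5 of
their 16 controls (>25%) displaced by 12 noise-SD, far beyond the ±3 SD
window. The generator does not emulate flow-cytometry event data, gating,
edge effects, or spatially structured plate artefacts — passing tests show
the pipeline's statistics behave correctly under additive plate effects and
the cellularity confound, not that they are robust to spatial gradients.

**Dose panels.** 8 log-spaced doses from 0.01 to 10 µM (1000-fold), impulse
truths with onset inside the tested range, peaks 0.5–1.2, and declining
viability truths starting at 1; measurements add Gaussian noise (default SD
0.05, replicates 2) and clip to the valid range.

**Expression.** Two paired two-group experiments (default 5 samples/group,
within-group SD 0.5 on the log₂ scale, gene baselines N(7, 1) drawn
independently per experiment). Planted signature genes shift group A by
`SNR_target × 2 × SD` with a shared random sign, so the population SNR
equals the target (default 2) in both experiments. A consequence worth
knowing: with 5 samples/group, a null gene that reaches p ≤ 0.05 in both
experiments with concordant direction (expected ≈ 25 of 20,000 genes) has a
conditionally inflated group difference (≥ ~1.5 within-group SD), and
roughly a third of those also clear the SNR > 1 filter, so the derived
signature carries an expected ≈ 9 false genes alongside essentially
complete recovery of the planted ones. The false-positive load shrinks
rapidly with replication (the conditional effect floor scales as √(2/n))
and with a stricter DE gate; it is a property of the
nominal-p + SNR chain at small n, not of the implementation.

**Universes.** A universe of the requested size embedding the signature
set, plus a disease set with an exactly specified overlap.

## Problem sizes and determinism

The test suite exercises hit-calling at the full screen scale
(3281 compounds, 42 plates) and dose-response recovery on 200 noisy panels;
the end-to-end pipeline test runs at a reduced scale (160 compounds, 1500
genes, 400 permutation iterations, 3 optimizer starts) chosen to keep the
default suite quick while touching every stage. Every stochastic stage
takes an explicit seed; the pipeline derives per-stage seeds from the run
seed, and identical configs produce byte-identical outputs.

## Known limitations

* The hit-calling GLM calibration assumes the positive-control level is
  stable across a batch; drifting positive controls would need a per-plate
  calibration.
* The impulse model's offset parameters (d₂, α₂, r_h) are weakly identified
  when the response decline lies mostly above the tested dose range; EC50
  is unaffected (it depends on the onset side) but offset-parameter
  estimates should not be interpreted in that regime.
* AICc with the saturated-model guard favours the single sigmoid strongly
  on bare 8-point panels; replicated panels are recommended when
  impulse-shaped behaviour matters.
* The permutation test treats genes as exchangeable; real disease-locus
  sets have structure (LD blocks, gene length) that a uniform null ignores.
* Cross-species identifier mapping is the caller's responsibility via the
  ortholog table; no orthology inference is attempted.
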