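# Methods

This note records the statistical model behind each component, the defaults
and why they were chosen, the numerical conventions, and what the built-in
simulations do and do not establish about real data.

## Data model and reporting tiers

A measurement is one value of one parameter from one subject's eye (side R,
L, or NA), optionally tagged with age, sex, session and replicate index.
The long CSV layout (one row per measurement) is the single schema for
population limits and serial-change analyses alike. Units are metadata
only; no conversion is attempted.

Reporting policy is a pure, monotone function of the subject count with
boundaries 10 / 20 / 40 / 120: below 10 subjects reference data should not
be reported at all; 10–19 support only a ranked table with the median;
20–39 support robust or parametric limits with CIs shown for illustration
only; 40–119 admit bootstrap limits; 120 and above support the full
nonparametric method with exact order-statistic CIs. 120 is a target *after*
outlier removal and *per partition*.

## Quantile convention

Limits use the rank index 0.5 + p·n. The default convention takes the
order statistic at this index **rounded half up** ("nearest rank"). This is
the convention under which the worked identities hold: the 2.5th percentile
of 100 values is exactly the 3rd smallest, and the 10th percentile of the
digits 0–9 is 1 no matter how many sets of digits are pooled (linear
interpolation would yield 0.5 there). Linear interpolation between adjacent
order statistics is available via `method="interpolated"`. Indices outside
[1, n] clamp to the sample extremes. A guard of 1e−9 absorbs binary
floating-point droop at exact half-ranks (e.g. 0.025·120).

A useful property of the nearest-rank convention: duplicating every value
(as the eye-duplication strategy does for unilateral subjects) leaves the
quantile estimate exactly unchanged, which is what makes the strategies
coincide at perfect inter-eye correlation.

## Nonparametric CIs

The 90% CI of the p-quantile is the minimal-width pair of order statistics
(l, u) with binomial coverage P(l ≤ Y ≤ u−1) ≥ 0.90, Y ~ Bin(n, p); ties in
width are broken by symmetry about the target rank. The search is
exhaustive and deterministic; at (n=120, p=0.025) it returns ranks (1, 7)
with coverage 0.9205.

Attainability: admitting the sample minimum as the lower bracket, the
smallest n for which a 90% CI of the 2.5th percentile exists is 91 (the
range coverage 1 − 0.975ⁿ − 0.025ⁿ first reaches 0.90 there). The
conventional recommendation of 120 subjects corresponds to a stricter
reading in which the CI should not lean on the very extremes being
simultaneously the limit estimate's neighbourhood; both numbers are
reported by `smallest_attainable_n` plus the explicit search. Where no pair
attains the confidence (e.g. n = 39, where the extremes themselves are the
limit estimates), the result is a signal, not an exception, and estimation
falls back to the sample extremes with a warning.

## Parametric limits

Normality is tested with Anderson–Darling by default (Lilliefors-corrected
KS as the option) at α = 0.05, on the candidate scale. `transform="auto"`
tries none → log → sqrt → Box-Cox and keeps the first accepted scale.
The Box-Cox λ is fitted by maximum likelihood then rounded to
{−1, −0.5, 0, 0.5, 1} for interpretability and to avoid over-fitting small
samples. If every candidate is rejected the estimate is refused — on skewed
data a Gaussian fit may still enclose 95% of values but not the *central*
95%, so it systematically misclassifies (low amplitudes called normal,
large ones called supranormal). `allow_nonnormal=True` overrides the gate
precisely to demonstrate that failure mode.

Two CIs are computed on the fitting scale and back-transformed:

* approximation: halfwidth `z₀.₉₅·√(1 + z₀.₉₇₅²/2)·s/√n = 2.811·s/√n`;
* exact: the equal-tailed noncentral-t tolerance interval for μ + z·σ,
  using quantiles of nct(df = n−1, δ = −z√n). This interval is asymmetric
  about the plug-in limit; the reported limits carry the exact interval.

The error curve compares the approximate halfwidth with **half the exact
interval's width**. Under that width comparison the error is identical for
all four CI endpoints (Gaussian symmetry) and decays as 1/n (log-log slope
−1.01 over n = 20…320). Comparing raw asymmetric endpoint offsets instead
gives two distinct errors decaying only as 1/√n; the offsets remain
available from `ci_lawless` for that purpose.

In one-tailed modes the limit cuts at the 5th/95th percentile and the exact
CI uses that cut's noncentrality; the CI/RI denominator remains the
two-tailed 2.5th–97.5th width, because a one-tailed "interval" would depend
on the sample extreme and never converges with n.

## Eye strategies and the bootstrap

`one_eye` keeps one value per subject (right by preference, deterministic;
a seeded random choice is available), `all_eyes_independent` keeps
everything, `duplicate_singletons` copies the single value of unilateral
subjects so every subject contributes a pair. Bootstrap CIs always resample
*subjects*, carrying each subject's values together: resampling eyes as if
independent produces spuriously narrow CIs exactly when the eyes are highly
correlated (duplicated values masquerade as independent evidence). The
strategy is applied once and the resulting per-subject blocks are
resampled; for the deterministic strategies this is identical to
re-applying the strategy inside each resample. Default B = 1000 resamples,
percentile CIs (5th–95th of replicate limits).

## Curation

Order is enforced by convention: transform/age-adjust first, outlier
detection second, estimation last — otherwise a genuine age trend makes the
very young and the elderly look like outliers.

* Tukey fences use the same quantile convention as the limits. Inner fence
  (1.5·IQR) only flags; removal is reserved for the far fence (3·IQR),
  which excludes ~2.3 per million from a Gaussian but ~3 per thousand from
  a skewed gamma (shape 2) — retention is the bias. Fence flags are
  invariant under affine transforms of the data.
* Grubbs (iterative) and Dixon's Q (extremes, tabulated α = 0.05 critical
  values for 3 ≤ n ≤ 30) are provided for near-Gaussian data and attach a
  warning when normality is doubtful.
* Robust location is the Tukey biweight (c = 4.685 on MAD-standardised
  residuals, ≤ 50 iterations, tolerance 1e−8, median fallback); robust
  scale is IQR/1.349.
* Age compensation is a continuous linear (or log-age) fit, robust
  (statsmodels RLM with the biweight norm) by default, residualised to the
  median age; it requires ages on ≥ 90% of measurements and at least 5
  years of age spread, otherwise it degrades to "none". Optional separate
  spread-vs-age fits for the upper and lower residual halves let the
  interval width vary with age.
* Partitioning: partition when the subgroup means differ by > 25% of the
  combined 95% RI width, when > 4% of either subgroup falls beyond *either*
  combined limit (per tail — nominal 2.5%, so identical subgroups sit well
  below threshold; judging the total outside-fraction against 4% would
  trigger under the null, since it is nominally 5%), or when the subgroup
  SD ratio is ≥ 1.5. The stricter 15% mean rule is reported but not
  decisive. The combined limits are nonparametric on the pooled data.

## Transference and verification

Transference regresses new-method on old-method values from the same
subjects: Deming regression (closed form, error-variance ratio 1) by
default since both methods are noisy, OLS as an option. Gates: n ≥ 40 and
r² ≥ 0.7, else no transfer. "Clinically significant" shift is a config
threshold: |slope − 1| > 0.05 or |intercept| > 5% of the old RI width
triggers limit adjustment `new = slope·old + intercept`; otherwise the old
limits are reused unchanged. The mapping is affine-equivariant.

Verification is count-exact: exactly 20 local subjects per stage, values on
a limit count as inside (the interval is inclusive). ≤ 2 outside → accept;
3–4 → second stage of 20 (≤ 2 outside → accept, else review protocols);
≥ 5 → review protocols directly. No third stage. When stage-2 data are not
yet supplied the report carries the pending state `stage2_required`. Under
the null with true 95% limits, stage-1 acceptance is P(X ≤ 2), X ~
Bin(20, 0.05) ≈ 0.925 — verified by simulation in the test suite. With the
full primary dataset available, Mann–Whitney U (location), Siegel–Tukey
(dispersion; ranks assigned alternately from the extremes, then the
rank-sum machinery) and Kolmogorov–Smirnov (shape) are more sensitive.

## Serial change

Pooled dispersion is √(Σ(kᵢ−1)sᵢ²/Σ(kᵢ−1)) over subject-eye units (CV
analogously); with equal kᵢ it reduces to the RMS of the per-unit values.
Eyes are never merged into one unit: under unilateral effects a merged SD
is inflated by the between-eye mean difference, which the tests reproduce.
RC = z·√2·dispersion, z = 1.96 by default (2.77×). Basis defaults by units:
CV for amplitude-like units (µV, %), SD for time-like (ms); overridable.
Delta-check verdicts require *strict* exceedance of the RC (equality is
"no_change"); the CV denominator is the previous value. RC bootstrap CIs
resample subjects (their eye-units together); ≥ 8 units expected, fewer is
flagged but still computed.

## Simulation engine

Bilateral cohorts draw per-subject Gaussian pairs with correlation r;
non-Gaussian marginals (gamma, log-normal) are obtained through a Gaussian
copula, so r = 1 still yields identical eyes. The default amplitude-like
gamma is shape 16, scale 25 (mean 400 µV, CV 25%, typical of ERG b-wave
amplitudes); generators expose analytic quantiles for oracle comparisons
and are pure functions of their seed.

The strategy experiment measures, per (r, n, strategy) cell, the lower
limit's uncertainty as a percentage of the true RI width. The default
metric is the **sampling dispersion** of the limit estimate across
replications (5th–95th percentile of replicate limits), with Monte-Carlo
SEs from 20 batch means; the three strategies share each cell's simulated
cohorts, so contrasts are paired. A per-replicate exact order-statistic CI
metric is available, but it treats duplicated eyes as independent values —
exactly the artefact subject-bootstrapping exists to avoid — so it
understates uncertainty at high correlation and cannot exhibit the
equal-at-r=1 behaviour; it also has no attainable 90% CI at 60 values.
Experiments run at 10⁴ replications per cell by default (the orderings of
interest are resolved to well within 2 MC SEs at that size); the full 10⁶
is a parameter away but not needed for the qualitative orderings.

Expected and observed behaviours: duplication is never worse than one eye
and strictly better at imperfect correlation; at r = 0 with full bilateral
coverage, using both eyes of n subjects matches one eye of 2n subjects; at
r = 1 all three strategies coincide exactly (identical estimates on shared
cohorts).

## Classification and multiplicity

Outside a monitored limit → abnormal_low/high; inside the interval but
within a limit's 90% CI band → indeterminate; otherwise normal. One-tailed
parameters never receive an abnormal verdict at the unmonitored extreme —
the report notes "not assessed" instead. Reporting n independent parameters
at 95% coverage carries familywise false-positive risk 1 − 0.95ⁿ; the risk
is reported, not corrected, because a principled correction needs the
inter-parameter correlations. Reports embed tool version, config hash,
seeds and the ordered curation log, and carry no timestamp, so identical
inputs reproduce byte-identical output.

## What the simulations do not show

Synthetic cohorts are i.i.d. across subjects with a constant marginal; real
reference data carry age structure, device and operator effects, and
non-copula dependence between eyes. Passing tests establish the estimators'
statistical properties under the stated generating models, not the
representativeness of any particular clinic's reference sample. Indirect
sampling from patient databases, multidimensional reference regions,
GEE-based CIs and clinical decision limits are out of scope.

## Problem sizes used in the checks

Strategy orderings: 10⁴ replications × (r ∈ {0, 0.5, 0.9, 1}) × (n ∈
{60, 120}) × 3 strategies, at 100% and 75% bilateral fractions. Skewed
recovery: ten seeded gamma samples of n = 10⁴ (the 2% agreement band is
asserted on the mean across seeds; a single sample's lower-tail MC error is
comparable to the band itself). Far-fence gamma rate: one 10⁷-draw Monte
Carlo against the closed form. Verification null: 10⁵ trials against the
exact binomial. All seeds are fixed in the tests.
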