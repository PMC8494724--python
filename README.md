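# visref

Reference intervals for clinical visual electrophysiology (ERG, VEP, EOG)
and other bilateral physiological measurements.

Clinical electrophysiology reports a patient's parameters — amplitudes in
µV, peak times in ms — against *reference limits* derived from disease-free
subjects. This package implements the full workflow for establishing,
transferring, verifying and monitoring such limits, with two features that
generic reference-interval tools lack:

* **correlated bilateral (two-eye) data**: explicit strategies for pooling
  right- and left-eye values (one eye per subject; all eyes as independent;
  duplicating the single eye of unilateral subjects so every subject
  contributes a pair), with subject-level — not eye-level — bootstrap CIs;
* **subject-based serial-change limits**: the repeatability coefficient
  RC = z·√2·(SD or CV) for "delta checks" on serial measurements, pooled
  over subject-eye units.

## The statistics in brief

For a reference sample x₍₁₎ ≤ … ≤ x₍ₙ₎, the p-quantile limit is the order
statistic at rank 0.5 + p·n (the 2.5th percentile of 100 values is the 3rd
smallest). Each limit carries a 90% CI:

* **nonparametric**: the pair of order statistics (x₍l₎, x₍u₎) of minimal
  width with binomial coverage P(l ≤ Y ≤ u−1) ≥ 0.90, Y ~ Bin(n, p) — at
  n = 120, p = 0.025 this is ranks (1, 7);
* **parametric** (Gaussian scale, possibly after log/sqrt/Box-Cox):
  limits x̄ ± 1.96 s, with the approximate CI halfwidth 2.81·s/√n
  (2.81 = z₀.₉₅·√(1 + z₀.₉₇₅²/2)) and the exact noncentral-t tolerance
  interval; the approximation's width error falls as 1/n;
* **bootstrap**: subjects resampled with replacement, the limit's CI taken
  as the 5th–95th percentile of replicate limits.

Quality is judged by the **CI/RI ratio** — each limit's 90% CI width over
the two-tailed 2.5th–97.5th interval width — which should be below 0.2.
Curation (Tukey fences with removal only at the far fence, robust biweight
fits, continuous age compensation *before* outlier detection, partitioning
rules) precedes estimation. External intervals are adopted via Deming
regression transference (≥ 40 paired subjects, r² ≥ 0.7) or the two-stage
20-subject verification count rule.

## Worked example

Simulate an amplitude-like bilateral cohort (150 subjects, 80% bilateral,
inter-eye correlation 0.7, gamma marginal with mean 400 µV and CV 25%),
then estimate two-tailed limits with the duplication strategy and a
subject-level bootstrap:

```python
import visref as v
from visref.cohort import write_reference_table

spec = v.BilateralCohortSpec(n_subjects=150, inter_eye_correlation=0.7,
                             fraction_bilateral=0.8, marginal="gamma",
                             marginal_params={"shape": 16, "scale": 25},
                             seed=7)
write_reference_table([v.generate_bilateral_cohort(spec)], "ref.csv")
```

```sh
visref establish --input ref.csv --parameter b_amp --method bootstrap \
    --eye-strategy duplicate --bootstrap 1000 --seed 7 --out report.json
```

The report (`result.all`) contains:

```json
{
  "method": "bootstrap",
  "lower": 219.95, "ci_lower": [203.80, 237.89],
  "upper": 551.91, "ci_upper": [529.35, 572.36],
  "n_subjects": 150, "n_values": 300,
  "ci_ri_ratios": {"lower": 0.103, "upper": 0.130},
  "quality_flag": true, "tier": "full"
}
```

Read: the estimated 95% reference interval is 220–552 µV; each limit's 90%
CI is about 10–13% of the interval width, inside the 0.2 quality goal, so
the sample is large enough to report. (The generating distribution's true
2.5th/97.5th quantiles are 228.6 and 618.5 µV; the long right tail is the
harder one to pin down, which is why its CI ratio is larger.) A patient
value of 240 µV then classifies as `normal`; a value inside a limit's CI
band would be `indeterminate`.

Other subcommands: `verify` (two-stage 20-subject count rule), `transfer`
(Deming mapping of old limits), `delta` (repeatability coefficient and
serial change verdict), `simulate` (Monte-Carlo experiment grids),
`classify`.

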