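"""Transference and verification of reference intervals.

*Transference* adapts an interval established under an old method (protocol,
electrode, stimulus) to a new one, from paired measurements of the same
subjects under both methods: with at least 40 subjects and r² ≥ 0.7, the
old limits are either reused unchanged (slope ≈ 1, negligible offset) or
mapped through the regression line.  Deming regression is the default
because both methods carry measurement error.

*Verification* checks whether an externally established interval can be
adopted locally: 20 local reference subjects are tested; up to two outside
the interval is acceptable, three or four trigger a second batch of 20, and
five or more mean the protocols need review.  When the full primary dataset
is available, two-sample tests (Mann–Whitney U for location, Siegel–Tukey
for dispersion, Kolmogorov–Smirnov for shape) are more sensitive than the
count rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError, ProtocolRefusal

__all__ = [
    "PairedComparison",
    "TransferReport",
    "VerificationReport",
    "deming_regression",
    "transference_assess",
    "verify_reference_interval",
    "verify_full_dataset",
    "siegel_tukey_ranks",
]

STAGE_N = 20  # local subjects per verification stage (count-exact protocol)


@dataclass(frozen=True)
class PairedComparison:
    """Complete pairs of one subject's value under the old and new method."""

    old: np.ndarray
    new: np.ndarray

    def __post_init__(self):
        old = np.asarray(self.old, dtype=float)
        new = np.asarray(self.new, dtype=float)
        if old.shape != new.shape or old.ndim != 1:
            raise DataError("paired values must be two equal-length vectors")
        keep = np.isfinite(old) & np.isfinite(new)
        object.__setattr__(self, "old", old[keep])
        object.__setattr__(self, "new", new[keep])

    @property
    def n(self) -> int:
        return self.old.size


@dataclass
class TransferReport:
    n: int
    r_squared: float
    slope: float
    intercept: float
    regression: str
    decision: str  # reuse_unchanged | adjust_limits | cannot_transfer
    adjusted_limits: tuple | None = None
    reasons: list = field(default_factory=list)


@dataclass
class VerificationReport:
    stage1_outside: int
    stage2_outside: int | None
    decision: str  # accept | accept_after_stage2 | review_protocols | stage2_required


def deming_regression(x, y, variance_ratio: float = 1.0) -> tuple[float, float]:
    """Deming regression slope and intercept (errors in both variables).

    ``variance_ratio`` is the ratio of the error variances (y to x); 1 gives
    orthogonal regression, appropriate when both methods are comparably
    noisy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0:
        raise DataError("zero covariance between methods")
    lam = variance_ratio
    slope = (syy - lam * sxx + np.sqrt((syy - lam * sxx) ** 2
                                       + 4.0 * lam * sxy**2)) / (2.0 * sxy)
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def transference_assess(
    pairs: PairedComparison,
    old_limits: tuple,
    regression: str = "deming",
    min_n: int = 40,
    min_r2: float = 0.7,
    slope_tolerance: float = 0.05,
    intercept_tolerance: float = 0.05,
) -> TransferReport:
    """Decide whether old-method reference limits carry over to the new
    method, and map them through the regression if needed.

    ``slope_tolerance`` is the allowed deviation of the slope from unity and
    ``intercept_tolerance`` the allowed offset as a fraction of the old RI
    width before the limits are considered clinically shifted and adjusted
    via ``new = slope·old + intercept``.
    """
    if pairs.n < 2:
        raise DataError("need at least two complete pairs")
    if np.var(pairs.old) == 0 or np.var(pairs.new) == 0:
        raise DataError("zero variance in one method's results")
    if regression == "deming":
        slope, intercept = deming_regression(pairs.old, pairs.new)
    elif regression == "ols":
        slope, intercept = np.polyfit(pairs.old, pairs.new, 1)
        slope, intercept = float(slope), float(intercept)
    else:
        raise ValueError(f"unknown regression {regression!r}")
    r2 = float(stats.pearsonr(pairs.old, pairs.new)[0] ** 2)

    reasons = []
    if pairs.n < min_n:
        reasons.append(f"only {pairs.n} pairs (< {min_n})")
    if r2 < min_r2:
        reasons.append(f"r²={r2:.3f} < {min_r2}")
    if reasons:
        return TransferReport(pairs.n, r2, slope, intercept, regression,
                              decision="cannot_transfer", reasons=reasons)

    lims = [lim for lim in old_limits if lim is not None]
    ri_width = max(lims) - min(lims) if len(lims) == 2 else None
    scale = ri_width if ri_width else float(np.ptp(pairs.old)) or 1.0
    shifted = (abs(slope - 1.0) > slope_tolerance
               or abs(intercept) > intercept_tolerance * scale)
    if not shifted:
        return TransferReport(pairs.n, r2, slope, intercept, regression,
                              decision="reuse_unchanged")
    adjusted = tuple(None if lim is None else slope * lim + intercept
                     for lim in old_limits)
    return TransferReport(pairs.n, r2, slope, intercept, regression,
                          decision="adjust_limits", adjusted_limits=adjusted,
                          reasons=["slope/offset clinically significant"])


def _count_outside(values, interval: tuple) -> int:
    x = np.asarray(values, dtype=float)
    lo, hi = interval
    out = np.zeros(x.size, dtype=bool)
    if lo is not None:
        out |= x < lo
    if hi is not None:
        out |= x > hi
    return int(out.sum())


def verify_reference_interval(stage1_values, interval: tuple,
                              stage2_values=None) -> VerificationReport:
    """Two-stage count rule for adopting an external reference interval.

    Exactly 20 local reference values per stage (the protocol is
    count-exact; values on a limit count as inside, the interval being
    inclusive).  Stage 1: ≤ 2 outside → accept; 3–4 outside → a second
    stage of 20 subjects is required; ≥ 5 outside → review protocols.
    Stage 2: ≤ 2 outside → accept, otherwise review protocols.
    """
    s1 = np.asarray(stage1_values, dtype=float)
    if s1.size != STAGE_N:
        raise ProtocolRefusal(f"stage 1 needs exactly {STAGE_N} values, got {s1.size}")
    n1 = _count_outside(s1, interval)
    if n1 <= 2:
        return VerificationReport(n1, None, "accept")
    if n1 >= 5:
        return VerificationReport(n1, None, "review_protocols")
    if stage2_values is None:
        return VerificationReport(n1, None, "stage2_required")
    s2 = np.asarray(stage2_values, dtype=float)
    if s2.size != STAGE_N:
        raise ProtocolRefusal(f"stage 2 needs exactly {STAGE_N} values, got {s2.size}")
    n2 = _count_outside(s2, interval)
    if n2 <= 2:
        return VerificationReport(n1, n2, "accept_after_stage2")
    return VerificationReport(n1, n2, "review_protocols")


def siegel_tukey_ranks(n: int) -> np.ndarray:
    """Siegel–Tukey rank scores for ``n`` sorted values: extremes get the
    low ranks, alternating ends in pairs (1; 2,3; 4,5; …)."""
    ranks = np.empty(n, dtype=float)
    lo, hi = 0, n - 1
    rank = 1
    take_low, pair = True, 1  # first assignment is a singleton at the low end
    while lo <= hi:
        for _ in range(pair):
            if lo > hi:
                break
            if take_low:
                ranks[lo] = rank
                lo += 1
            else:
                ranks[hi] = rank
                hi -= 1
            rank += 1
        take_low = not take_low
        pair = 2
    return ranks


def verify_full_dataset(local, primary, alpha: float = 0.05) -> dict:
    """Compare a local reference sample against the full primary dataset.

    Runs Mann–Whitney U (location), Siegel–Tukey (dispersion) and
    Kolmogorov–Smirnov (shape) and reports p-values with a one-line
    interpretation per test.  Heavy ties degrade the Siegel–Tukey test and
    are reported as a warning.
    """
    x = np.asarray(local, dtype=float)
    y = np.asarray(primary, dtype=float)
    if x.size < 20 or y.size < 20:
        raise ProtocolRefusal("each dataset needs n >= 20")

    mwu = stats.mannwhitneyu(x, y, alternative="two-sided")

    combined = np.concatenate([x, y])
    order = np.argsort(combined, kind="mergesort")
    st_scores = np.empty(combined.size)
    st_scores[order] = siegel_tukey_ranks(combined.size)
    # rank-sum test on Siegel–Tukey scores: reuse the Mann–Whitney machinery
    st = stats.mannwhitneyu(st_scores[: x.size], st_scores[x.size:],
                            alternative="two-sided")
    warnings = []
    n_ties = combined.size - np.unique(combined).size
    if n_ties > 0.1 * combined.size:
        warnings.append(f"{n_ties} tied values; Siegel–Tukey ranks unstable")

    ks = stats.ks_2samp(x, y)

    def verdict(p, what):
        sig = p < alpha
        return (f"{what} differs (p={p:.3g})" if sig
                else f"no {what} difference detected (p={p:.3g})")

    return {
        "n_local": int(x.size),
        "n_primary": int(y.size),
        "mann_whitney": {"statistic": float(mwu.statistic),
                         "p_value": float(mwu.pvalue),
                         "interpretation": verdict(mwu.pvalue, "location")},
        "siegel_tukey": {"statistic": float(st.statistic),
                         "p_value": float(st.pvalue),
                         "interpretation": verdict(st.pvalue, "dispersion")},
        "kolmogorov_smirnov": {"statistic": float(ks.statistic),
                               "p_value": float(ks.pvalue),
                               "interpretation": verdict(ks.pvalue, "shape")},
        "warnings": warnings,
    }
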