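"""Reference-limit estimation.

Implements the three estimation routes for population reference limits:

* **nonparametric** — rank-based percentiles with exact order-statistic
  confidence intervals derived from binomial coverage;
* **parametric** — mean ± z·s on a (possibly transformed) scale that passes
  a normality test, with both the z-approximation CI and the exact
  noncentral-t (Lawless) tolerance-limit CI;
* **bootstrap** — subject-level resampling, which respects the within-subject
  correlation of the two eyes and is usable from about 40 subjects.

Bilateral (two-eye) data are reduced to an analysis set by an explicit eye
strategy: use one eye per subject, use all eyes as if independent, or
duplicate the single available eye of unilateral subjects so that every
subject contributes a pair.

Every estimate carries, for each limit, the ratio of its 90% CI width to the
two-tailed 95% reference-interval width.  This CI/RI ratio should be below
0.2; by convention the denominator is always the 2.5th–97.5th interval, even
when only a single one-tailed limit is being reported, because the one-tailed
"interval" would depend on the sample extreme and never converges.
"""

from __future__ import annotations

import enum
import warnings as _warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .cohort import ReferenceSample, Tier, reporting_tier
from .errors import DataError, NormalityRefusal, TierRefusal

__all__ = [
    "TailMode",
    "EyeStrategy",
    "ReferenceLimitEstimate",
    "OrderStatisticCI",
    "LawlessCI",
    "rank_index",
    "quantile_nonparametric",
    "min_n_for_separation",
    "order_statistic_ci",
    "smallest_attainable_n",
    "ci_approx_halfwidth",
    "ci_approx_constant",
    "ci_lawless",
    "normality_pvalue",
    "parametric_limits",
    "apply_eye_strategy",
    "nonparametric_limits",
    "bootstrap_limits",
    "ci_ri_ratio",
]


class TailMode(str, enum.Enum):
    """Which reference limits are clinically monitored.

    Two-tailed limits cut at the 2.5th and 97.5th percentiles; a single
    one-tailed limit cuts at the 5th or 95th percentile.
    """

    TWO_TAILED = "two_tailed"
    LOWER_ONLY = "lower_only"
    UPPER_ONLY = "upper_only"

    @property
    def percentiles(self) -> dict:
        if self is TailMode.TWO_TAILED:
            return {"lower": 0.025, "upper": 0.975}
        if self is TailMode.LOWER_ONLY:
            return {"lower": 0.05}
        return {"upper": 0.95}


class EyeStrategy(str, enum.Enum):
    ONE_EYE = "one_eye"
    ALL_EYES = "all_eyes_independent"
    DUPLICATE = "duplicate_singletons"


# ---------------------------------------------------------------------------
# rank arithmetic
# ---------------------------------------------------------------------------

def rank_index(p: float, n: int) -> float:
    """Rank of the p-quantile in a sample of size n: ``0.5 + p·n``.

    E.g. the 2.5th percentile of 100 ranked values sits at rank 3.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 0.5 + p * n


def _nearest_rank(x: float, n: int) -> int:
    # round half up, with a guard against binary-float droop at exact halves
    k = int(np.floor(x + 0.5 + 1e-9))
    return min(max(k, 1), n)


def quantile_nonparametric(values, p: float, method: str = "nearest") -> float:
    """Rank-based quantile at the index ``0.5 + p·n``.

    ``method="nearest"`` takes the order statistic at the index rounded half
    up (so the 10th percentile of the digits 0–9 is 1, however many sets of
    digits are pooled).  ``method="interpolated"`` interpolates linearly
    between the two adjacent order statistics.  Indices outside [1, n] clamp
    to the sample extremes.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise DataError("empty sample")
    r = rank_index(p, n)
    if method == "nearest":
        return float(x[_nearest_rank(r, n) - 1])
    if method == "interpolated":
        if r <= 1:
            return float(x[0])
        if r >= n:
            return float(x[-1])
        f = int(np.floor(r))
        g = r - f
        return float(x[f - 1] + g * (x[f] - x[f - 1]))
    raise ValueError(f"unknown method {method!r}")


def min_n_for_separation(P: float) -> int:
    """Minimum sample size distinguishing percentiles separated by ``P``
    percent: ``n = 100/P − 1`` (39 points to separate the 2.5th from the
    5th percentile)."""
    if not 0.0 < P <= 100.0:
        raise ValueError("P must be in (0, 100]")
    return int(np.ceil(100.0 / P - 1.0 - 1e-12))


# ---------------------------------------------------------------------------
# order-statistic confidence intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrderStatisticCI:
    """Rank pair (l, u) whose order statistics bracket the p-quantile with
    at least the requested confidence, or a not-attainable signal."""

    n: int
    p: float
    confidence: float
    lower_rank: int | None
    upper_rank: int | None
    coverage: float
    attainable: bool


def _pair_coverage_table(n: int, p: float) -> np.ndarray:
    # cdf[k] = P(Y <= k-1), Y ~ Bin(n, p); coverage(l,u) = P(l <= Y <= u-1)
    return stats.binom.cdf(np.arange(-1, n + 1), n, p)


def order_statistic_ci(n: int, p: float, confidence: float = 0.90) -> OrderStatisticCI:
    """Smallest-width rank pair (l, u), 1 ≤ l < u ≤ n, such that
    P(X₍l₎ ≤ ξ_p ≤ X₍u₎) ≥ confidence under the binomial law.

    Ties in width are broken by the pair most symmetric about the target
    rank ``0.5 + p·n``.  If no pair reaches the confidence the result is a
    not-attainable signal (the sample extremes then serve as the only
    available bracket).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cdf = _pair_coverage_table(n, p)
    target = rank_index(p, n)
    for width in range(1, n):
        best = None
        for l in range(1, n - width + 1):
            u = l + width
            cov = cdf[u] - cdf[l]  # = P(Y<=u-1) - P(Y<=l-1)
            if cov >= confidence:
                sym = abs((l + u) / 2.0 - target)
                if best is None or sym < best[0]:
                    best = (sym, l, u, cov)
        if best is not None:
            _, l, u, cov = best
            return OrderStatisticCI(n, p, confidence, l, u, float(cov), True)
    cov = float(cdf[n] - cdf[1]) if n > 1 else 0.0
    return OrderStatisticCI(n, p, confidence, None, None, cov, False)


def smallest_attainable_n(p: float, confidence: float = 0.90,
                          n_max: int = 1000) -> int | None:
    """Smallest sample size for which an exact order-statistic CI of the
    p-quantile is attainable at the given confidence.

    The widest usable bracket is the sample range, so attainability reduces
    to ``1 − (1−p)ⁿ − pⁿ ≥ confidence``; the scan confirms it by the same
    exhaustive search used for estimation.
    """
    for n in range(2, n_max + 1):
        if order_statistic_ci(n, p, confidence).attainable:
            return n
    return None


# ---------------------------------------------------------------------------
# parametric CIs: z-approximation and exact noncentral-t (Lawless)
# ---------------------------------------------------------------------------

def ci_approx_constant(coverage: float = 0.95, confidence: float = 0.90) -> float:
    """The z-approximation constant ``z_conf·√(1 + z_cov²/2)``.

    For a 90% CI of a 95% reference limit this is 2.811… ≈ 2.81.
    """
    z_cov = stats.norm.ppf((1.0 + coverage) / 2.0)
    z_conf = stats.norm.ppf((1.0 + confidence) / 2.0)
    return float(z_conf * np.sqrt(1.0 + z_cov**2 / 2.0))


def ci_approx_halfwidth(s: float, n: int, coverage: float = 0.95,
                        confidence: float = 0.90) -> float:
    """Halfwidth of the approximate 90% CI of a Gaussian 95% reference
    limit: ``2.81 · s / √n`` at the default coverage/confidence."""
    if s < 0:
        raise ValueError("s must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    return ci_approx_constant(coverage, confidence) * s / np.sqrt(n)


@dataclass(frozen=True)
class LawlessCI:
    """Exact equal-tailed CI offsets for both Gaussian reference limits,
    in units of the sample SD.

    For the upper limit x̄ + z·s the exact CI is
    ``[x̄ − q₀.₉₅·s/√n, x̄ − q₀.₀₅·s/√n]`` with q the quantiles of the
    noncentral t distribution (df n−1, noncentrality −z√n); the lower limit
    mirrors it.  The interval is asymmetric about the plug-in limit;
    ``halfwidth`` is half its total width, which is what the 2.81/√n
    approximation estimates.
    """

    n: int
    coverage: float
    confidence: float
    upper_limit_below: float  # distance from x̄+z·s down to the CI's lower end
    upper_limit_above: float  # distance up to the CI's upper end
    lower_limit_below: float
    lower_limit_above: float

    @property
    def width(self) -> float:
        return self.upper_limit_below + self.upper_limit_above

    @property
    def halfwidth(self) -> float:
        return 0.5 * self.width


def ci_lawless(s: float = 1.0, n: int = 120, coverage: float = 0.95,
               confidence: float = 0.90) -> LawlessCI:
    """Exact tolerance-limit CI for Gaussian reference limits via the
    noncentral t distribution, scaled by the sample SD ``s``.

    The relative deviation of the approximate halfwidth from half this
    exact interval's width decays as 1/n.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    z = stats.norm.ppf((1.0 + coverage) / 2.0)
    alpha = 1.0 - confidence
    q_lo, q_hi = stats.nct.ppf([alpha / 2.0, 1.0 - alpha / 2.0],
                               n - 1, -z * np.sqrt(n))
    below = s * (z + q_hi / np.sqrt(n))     # Û − lower CI end
    above = s * (-z - q_lo / np.sqrt(n))    # upper CI end − Û
    # Gaussian symmetry: the lower limit's offsets mirror the upper's
    return LawlessCI(n=n, coverage=coverage, confidence=confidence,
                     upper_limit_below=float(below), upper_limit_above=float(above),
                     lower_limit_below=float(above), lower_limit_above=float(below))


# ---------------------------------------------------------------------------
# normality testing and transforms
# ---------------------------------------------------------------------------

_BOXCOX_GRID = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])


def normality_pvalue(values, test: str = "anderson") -> float:
    """p-value of a composite normality test (Anderson–Darling by default,
    Lilliefors-corrected Kolmogorov–Smirnov as the option)."""
    from statsmodels.stats.diagnostic import kstest_normal, normal_ad

    x = np.asarray(values, dtype=float)
    if test == "anderson":
        return float(normal_ad(x)[1])
    if test == "ks":
        return float(kstest_normal(x, dist="norm")[1])
    raise ValueError(f"unknown normality test {test!r}")


def _fit_boxcox_lambda(x: np.ndarray) -> float:
    lam = stats.boxcox(x)[1]
    return float(_BOXCOX_GRID[np.argmin(np.abs(_BOXCOX_GRID - lam))])


class _Transform:
    """Monotone variance-stabilising transform with its inverse."""

    def __init__(self, name: str, lam: float | None = None):
        self.name = name
        self.lam = lam

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.name == "none":
            return x
        if np.any(x <= 0):
            raise DataError(f"{self.name} transform requires positive values")
        if self.name == "log":
            return np.log(x)
        if self.name == "sqrt":
            return np.sqrt(x)
        if self.name == "boxcox":
            lam = self.lam
            return np.log(x) if lam == 0 else (np.power(x, lam) - 1.0) / lam
        raise ValueError(self.name)

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        if self.name == "none":
            out = y
        elif self.name == "log":
            out = np.exp(y)
        elif self.name == "sqrt":
            out = np.square(y)
        else:  # boxcox
            lam = self.lam
            if lam == 0:
                out = np.exp(y)
            else:
                base = lam * y + 1.0
                out = np.where(base > 0, np.power(np.abs(base), 1.0 / lam), np.nan)
        return out


# ---------------------------------------------------------------------------
# estimate container
# ---------------------------------------------------------------------------

@dataclass
class ReferenceLimitEstimate:
    """A reference limit (or pair of limits) with 90% CIs and quality
    metrics.

    ``ri_width`` is always the two-tailed 2.5th–97.5th interval width of the
    analysis values — the fixed denominator of every CI/RI ratio.
    """

    method: str
    tail: TailMode
    lower: float | None = None
    upper: float | None = None
    ci_lower: tuple | None = None
    ci_upper: tuple | None = None
    transform: str = "none"
    boxcox_lambda: float | None = None
    n_subjects: int = 0
    n_values: int = 0
    ri_width: float | None = None
    ci_ri_ratios: dict = field(default_factory=dict)
    quality_flag: bool = False
    confidence: float = 0.90
    coverage: float = 0.95
    seed: int | None = None
    normality: dict | None = None
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tail"] = self.tail.value
        return d


def _two_tailed_ri_width(values, method: str = "nearest") -> float:
    lo = quantile_nonparametric(values, 0.025, method)
    hi = quantile_nonparametric(values, 0.975, method)
    return hi - lo


def ci_ri_ratio(estimate: ReferenceLimitEstimate) -> dict:
    """Per-limit ratio of 90% CI width to the two-tailed RI width.

    A zero-width CI has ratio 0 regardless of the denominator; a degenerate
    (zero-width) RI with a non-degenerate CI leaves the ratio undefined
    (``None``).  The estimate's quality flag is true iff every defined ratio
    is below 0.2 and none is undefined.
    """
    ratios: dict = {}
    for name, ci in (("lower", estimate.ci_lower), ("upper", estimate.ci_upper)):
        if ci is None:
            continue
        width = float(ci[1]) - float(ci[0])
        if width == 0.0:
            ratios[name] = 0.0
        elif not estimate.ri_width:
            ratios[name] = None
        else:
            ratios[name] = width / estimate.ri_width
    return ratios


def _finalise_quality(est: ReferenceLimitEstimate) -> ReferenceLimitEstimate:
    est.ci_ri_ratios = ci_ri_ratio(est)
    vals = list(est.ci_ri_ratios.values())
    est.quality_flag = bool(vals) and all(v is not None and v < 0.2 for v in vals)
    if any(v is None for v in vals):
        est.warnings.append("degenerate reference interval: CI/RI ratio undefined")
    return est


# ---------------------------------------------------------------------------
# eye strategies
# ---------------------------------------------------------------------------

def apply_eye_strategy(
    sample: ReferenceSample,
    strategy: EyeStrategy | str = EyeStrategy.DUPLICATE,
    rng: np.random.Generator | None = None,
    prefer_side: str | None = "R",
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a bilateral sample to an analysis set of values.

    Returns ``(values, subject_ids)`` aligned arrays; the subject grouping is
    what the subject-level bootstrap resamples.  ``one_eye`` keeps one value
    per subject (preferring ``prefer_side``, or a seeded random eye when
    ``prefer_side`` is None); ``all_eyes_independent`` keeps every value;
    ``duplicate_singletons`` copies the single available value of unilateral
    subjects so that every subject contributes exactly two values.
    """
    strategy = EyeStrategy(strategy)
    df = sample.data
    sizes = df.groupby("subject_id", sort=False)["value"].size()
    if (sizes > 2).any():
        bad = sizes[sizes > 2].index.tolist()
        raise DataError(f"subjects with more than two values: {bad}")

    values, subjects = [], []
    for sid, grp in df.groupby("subject_id", sort=False):
        v = grp["value"].to_numpy(dtype=float)
        side = grp["side"].to_numpy()
        if strategy is EyeStrategy.ONE_EYE:
            if len(v) == 1:
                pick = 0
            elif prefer_side is None:
                if rng is None:
                    raise ValueError("random one-eye choice needs an rng")
                pick = int(rng.integers(len(v)))
            else:
                hit = np.flatnonzero(side == prefer_side)
                pick = int(hit[0]) if hit.size else 0
            values.append(v[pick:pick + 1])
        elif strategy is EyeStrategy.ALL_EYES:
            values.append(v)
        else:  # DUPLICATE
            values.append(v if len(v) == 2 else np.repeat(v, 2))
        subjects.append(np.repeat(sid, len(values[-1])))
    return np.concatenate(values), np.concatenate(subjects)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _as_values(sample_or_values):
    if isinstance(sample_or_values, ReferenceSample):
        return sample_or_values.values, sample_or_values.n_subjects
    x = np.asarray(sample_or_values, dtype=float)
    return x, x.size


def nonparametric_limits(
    sample_or_values,
    tail: TailMode | str = TailMode.TWO_TAILED,
    confidence: float = 0.90,
    method: str = "nearest",
) -> ReferenceLimitEstimate:
    """Rank-based reference limits with exact order-statistic CIs.

    Where the exact CI is not attainable at the sample size, the sample
    extremes are reported as the bracket and a warning is attached.
    """
    tail = TailMode(tail)
    values, n_subjects = _as_values(sample_or_values)
    x = np.sort(values)
    n = x.size
    if n == 0:
        raise DataError("empty sample")
    est = ReferenceLimitEstimate(method="nonparametric", tail=tail,
                                 n_subjects=n_subjects, n_values=n,
                                 confidence=confidence)
    est.ri_width = _two_tailed_ri_width(x, method)
    for name, p in tail.percentiles.items():
        limit = quantile_nonparametric(x, p, method)
        osci = order_statistic_ci(n, p, confidence)
        if osci.attainable:
            ci = (float(x[osci.lower_rank - 1]), float(x[osci.upper_rank - 1]))
        else:
            ci = (float(x[0]), float(x[-1]))
            est.warnings.append(
                f"exact {int(confidence*100)}% CI for the {name} limit is not "
                f"attainable at n={n}; sample extremes reported")
        setattr(est, name, float(limit))
        setattr(est, f"ci_{name}", ci)
    return _finalise_quality(est)


def parametric_limits(
    sample_or_values,
    transform: str = "auto",
    coverage: float = 0.95,
    confidence: float = 0.90,
    alpha: float = 0.05,
    normality_test: str = "anderson",
    tail: TailMode | str = TailMode.TWO_TAILED,
    allow_nonnormal: bool = False,
) -> ReferenceLimitEstimate:
    """Gaussian reference limits ``mean ± z·s`` on a scale that passes a
    normality test, back-transformed to measurement units.

    ``transform`` may be one of none/log/sqrt/boxcox or "auto", which tries
    them in that order and keeps the first accepted scale.  If normality is
    rejected (p < alpha) on every candidate scale the estimate is refused —
    nonparametric or bootstrap limits should be used instead.  Passing
    ``allow_nonnormal=True`` computes the limits anyway (for illustrating
    the systematic misclassification a Gaussian fit produces on skewed
    data) with the failed test recorded in the warnings.  Both the
    z-approximation CI and the exact Lawless CI are computed on the
    transformed scale; the exact CI is what the reported limits carry.
    """
    tail = TailMode(tail)
    values, n_subjects = _as_values(sample_or_values)
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 20:
        raise TierRefusal(f"parametric limits need n >= 20, got {n}")

    candidates = (["none", "log", "sqrt", "boxcox"] if transform == "auto"
                  else [transform])
    chosen = None
    tried = {}
    for name in candidates:
        lam = None
        if name == "boxcox":
            if np.any(x <= 0):
                continue
            lam = _fit_boxcox_lambda(x)
        tr = _Transform(name, lam)
        try:
            y = tr.forward(x)
        except DataError:
            continue
        p = normality_pvalue(y, normality_test)
        tried[name] = p
        if p >= alpha:
            chosen = (tr, y, p)
            break
    extra_warnings: list = []
    if chosen is None:
        if not allow_nonnormal:
            raise NormalityRefusal(
                f"normality rejected at alpha={alpha} for transforms {tried}; "
                "use nonparametric or bootstrap limits")
        name = candidates[0]
        lam = _fit_boxcox_lambda(x) if name == "boxcox" else None
        tr = _Transform(name, lam)
        chosen = (tr, tr.forward(x), tried.get(name, float("nan")))
        extra_warnings.append(
            f"normality rejected (p={tried.get(name)}); limits computed on "
            "request and will systematically misclassify skewed data")

    tr, y, pval = chosen
    m, s = float(np.mean(y)), float(np.std(y, ddof=1))
    z = stats.norm.ppf((1.0 + coverage) / 2.0)
    law = ci_lawless(s, n, coverage, confidence)
    approx_hw = ci_approx_halfwidth(s, n, coverage, confidence)

    est = ReferenceLimitEstimate(
        method="parametric" if tr.name == "none" else "parametric_transformed",
        tail=tail, transform=tr.name, boxcox_lambda=tr.lam,
        n_subjects=n_subjects, n_values=n, confidence=confidence,
        coverage=coverage,
        normality={"test": normality_test, "p_value": pval,
                   "alpha": alpha, "tried": tried,
                   "ci_approx_halfwidth_transformed": approx_hw},
        warnings=extra_warnings,
    )
    lower_t, upper_t = m - z * s, m + z * s
    est.ri_width = float(tr.inverse(upper_t) - tr.inverse(lower_t))
    if tail is not TailMode.TWO_TAILED:
        # one-tailed limits cut at the 5th/95th percentile; the exact CI
        # uses the noncentrality of that one-sided cut
        law = ci_lawless(s, n, 2.0 * coverage - 1.0, confidence)
    z_cut = z if tail is TailMode.TWO_TAILED else stats.norm.ppf(coverage)
    if "lower" in tail.percentiles:
        lim = m - z_cut * s
        est.lower = float(tr.inverse(lim))
        est.ci_lower = tuple(tr.inverse([lim - law.lower_limit_below,
                                         lim + law.lower_limit_above]))
    if "upper" in tail.percentiles:
        lim = m + z_cut * s
        est.upper = float(tr.inverse(lim))
        est.ci_upper = tuple(tr.inverse([lim - law.upper_limit_below,
                                         lim + law.upper_limit_above]))
    return _finalise_quality(est)


def bootstrap_limits(
    sample: ReferenceSample,
    tail: TailMode | str = TailMode.TWO_TAILED,
    strategy: EyeStrategy | str = EyeStrategy.DUPLICATE,
    B: int = 1000,
    seed: int | None = None,
    confidence: float = 0.90,
    method: str = "nearest",
) -> ReferenceLimitEstimate:
    """Nonparametric limits with subject-level bootstrap CIs.

    Subjects — not individual eyes — are resampled with replacement, which
    keeps each subject's correlated pair together and avoids the overly
    narrow CIs that eye-level resampling produces when the eyes are highly
    correlated.  The reported limit is the rank-based quantile of the
    original analysis set; its 90% CI is the 5th–95th percentile of the
    bootstrap replicate limits.
    """
    tail = TailMode(tail)
    tier = sample.tier()
    if tier.tier is Tier.REFUSE:
        raise TierRefusal(f"{tier.n} subjects: reference data should not be reported")
    est_warnings = []
    if sample.n_subjects < 40:
        est_warnings.append(
            f"bootstrap limits from only {sample.n_subjects} subjects; "
            "intended for n >= 40")
    if B < 100:
        est_warnings.append(f"B={B} bootstrap resamples is very small")

    rng = np.random.default_rng(seed)
    values, subjects = apply_eye_strategy(sample, strategy)
    # per-subject value blocks, resampled as whole subjects
    uniq, inv = np.unique(subjects, return_inverse=True)
    blocks = [values[inv == i] for i in range(uniq.size)]
    n_subj = len(blocks)

    ps = sorted(set(TailMode(tail).percentiles.values()) | {0.025, 0.975})
    reps = np.empty((B, len(ps)))
    for b in range(B):
        take = rng.integers(n_subj, size=n_subj)
        xb = np.concatenate([blocks[i] for i in take])
        xb.sort()
        nb = xb.size
        for j, p in enumerate(ps):
            if method == "nearest":
                reps[b, j] = xb[_nearest_rank(rank_index(p, nb), nb) - 1]
            else:
                reps[b, j] = quantile_nonparametric(xb, p, method)

    est = ReferenceLimitEstimate(method="bootstrap", tail=tail,
                                 n_subjects=n_subj, n_values=values.size,
                                 confidence=confidence, seed=seed,
                                 warnings=est_warnings)
    est.ri_width = _two_tailed_ri_width(values, method)
    a = (1.0 - confidence) / 2.0
    for name, p in tail.percentiles.items():
        j = ps.index(p)
        setattr(est, name, float(quantile_nonparametric(values, p, method)))
        setattr(est, f"ci_{name}",
                (float(np.quantile(reps[:, j], a)),
                 float(np.quantile(reps[:, j], 1.0 - a))))
    return _finalise_quality(est)
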