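"""Curation applied before limit estimation: outlier handling, robust
location/scale, age compensation and partitioning decisions.

The curation order matters: transform and age-adjust first, detect outliers
second, estimate limits last.  Detecting outliers before an age adjustment
makes the very young and the elderly erroneously more likely to be flagged,
because their genuine age trend looks like an excursion.

Outlier policy is deliberately conservative — the emphasis is on retaining
data: values beyond the inner Tukey fence (1.5 IQR beyond a quartile) are
only flagged; removal is reserved for the far fence (3 IQR), which excludes
about two values per million from a Gaussian but around two per thousand
from a markedly skewed gamma.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import ReferenceSample
from .errors import DataError, ProtocolRefusal
from .limits import quantile_nonparametric

__all__ = [
    "OutlierFlag",
    "OutlierReport",
    "tukey_fences",
    "fence_exceedance",
    "grubbs_test",
    "dixon_q",
    "robust_location_scale",
    "AgeModel",
    "fit_age_model",
    "age_adjust",
    "PartitionDecision",
    "partition_check",
]

#: IQR → Gaussian SD conversion (IQR of a standard normal is 1.349)
IQR_TO_SD = 1.0 / (stats.norm.ppf(0.75) - stats.norm.ppf(0.25))


class OutlierFlag(str, enum.Enum):
    KEPT = "kept"
    INNER = "outside_inner_fence"
    FAR = "outside_far_fence"


@dataclass
class OutlierReport:
    method: str
    flags: np.ndarray  # of OutlierFlag
    constants: dict
    warnings: list = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return int(np.sum(self.flags != OutlierFlag.KEPT))

    def removal_mask(self, policy: str = "far") -> np.ndarray:
        """Rows the default policy would remove (far-fence violators only)."""
        if policy == "far":
            return self.flags == OutlierFlag.FAR
        if policy == "inner":
            return self.flags != OutlierFlag.KEPT
        raise ValueError(f"unknown policy {policy!r}")


def tukey_fences(values, inner: float = 1.5, far: float = 3.0,
                 method: str = "nearest") -> OutlierReport:
    """Tukey's fences: flag values beyond Q1 − k·IQR or Q3 + k·IQR.

    Quartiles use the same rank convention as the nonparametric limits.
    Values beyond the inner fence (k=1.5) are flagged for inspection; only
    far-fence (k=3) violators are candidates for removal.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise DataError("Tukey fences need at least 4 values")
    q1 = quantile_nonparametric(x, 0.25, method)
    q3 = quantile_nonparametric(x, 0.75, method)
    iqr = q3 - q1
    flags = np.full(x.size, OutlierFlag.KEPT, dtype=object)
    warn = []
    if iqr == 0.0:
        warn.append("IQR is zero; fences degenerate, no values flagged")
    else:
        flags[(x < q1 - inner * iqr) | (x > q3 + inner * iqr)] = OutlierFlag.INNER
        flags[(x < q1 - far * iqr) | (x > q3 + far * iqr)] = OutlierFlag.FAR
    return OutlierReport(
        method="tukey", flags=flags,
        constants={"inner": inner, "far": far, "q1": q1, "q3": q3, "iqr": iqr},
        warnings=warn)


def fence_exceedance(dist, multiplier: float = 3.0) -> float:
    """Two-sided probability that a draw from a scipy distribution falls
    beyond its Tukey fences (population quartiles, k·IQR).

    For the standard normal at the far fence this is 2.34 × 10⁻⁶ — "two per
    million"; for a markedly skewed gamma it is of order per-thousand.
    """
    q1, q3 = dist.ppf([0.25, 0.75])
    iqr = q3 - q1
    return float(dist.sf(q3 + multiplier * iqr) + dist.cdf(q1 - multiplier * iqr))


def _gaussian_warning(values, alpha: float = 0.05) -> list:
    from .limits import normality_pvalue

    try:
        p = normality_pvalue(values)
    except Exception:
        return []
    if p < alpha:
        return [f"normality rejected (p={p:.3g}); this test assumes a "
                "near-Gaussian distribution"]
    return []


def grubbs_test(values, alpha: float = 0.05, max_outliers: int | None = None
                ) -> OutlierReport:
    """Iterative Grubbs test for single outliers in near-Gaussian data.

    The most extreme value is tested against the Grubbs critical value and,
    if flagged, removed from the working set before re-testing.  Flags only;
    removal remains an explicit separate step.
    """
    x = np.asarray(values, dtype=float)
    n0 = x.size
    if n0 < 3:
        raise ProtocolRefusal("Grubbs test needs at least 3 values")
    flags = np.full(n0, OutlierFlag.KEPT, dtype=object)
    active = np.arange(n0)
    limit = max_outliers if max_outliers is not None else n0 - 3
    for _ in range(max(limit, 0)):
        xa = x[active]
        n = xa.size
        if n < 3:
            break
        s = xa.std(ddof=1)
        if s == 0:
            break
        g = np.abs(xa - xa.mean()) / s
        i = int(np.argmax(g))
        t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))
        if g[i] <= g_crit:
            break
        flags[active[i]] = OutlierFlag.FAR
        active = np.delete(active, i)
    return OutlierReport(method="grubbs", flags=flags,
                         constants={"alpha": alpha},
                         warnings=_gaussian_warning(x, alpha))


#: Dixon's Q critical values at alpha = 0.05 for n = 3..30 (two-sided, r10)
_DIXON_Q95 = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.493,
    10: 0.466, 11: 0.444, 12: 0.426, 13: 0.410, 14: 0.396, 15: 0.384,
    16: 0.374, 17: 0.365, 18: 0.356, 19: 0.349, 20: 0.342, 21: 0.337,
    22: 0.331, 23: 0.326, 24: 0.321, 25: 0.317, 26: 0.312, 27: 0.308,
    28: 0.305, 29: 0.301, 30: 0.290,
}


def dixon_q(values, alpha: float = 0.05) -> OutlierReport:
    """Dixon's Q test applied to both sample extremes (r10 ratio).

    Tabulated critical values cover 3 ≤ n ≤ 30 at α = 0.05.
    """
    if alpha != 0.05:
        raise ProtocolRefusal("Dixon Q critical values tabulated for alpha=0.05 only")
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3 or n > 30:
        raise ProtocolRefusal(f"Dixon Q needs 3 <= n <= 30, got {n}")
    order = np.argsort(x)
    xs = x[order]
    rng = xs[-1] - xs[0]
    flags = np.full(n, OutlierFlag.KEPT, dtype=object)
    if rng > 0:
        q_crit = _DIXON_Q95[n]
        if (xs[1] - xs[0]) / rng > q_crit:
            flags[order[0]] = OutlierFlag.FAR
        if (xs[-1] - xs[-2]) / rng > q_crit:
            flags[order[-1]] = OutlierFlag.FAR
    return OutlierReport(method="dixon_q", flags=flags,
                         constants={"alpha": alpha},
                         warnings=_gaussian_warning(x, alpha))


def robust_location_scale(values, c: float = 4.685, max_iter: int = 50,
                          tol: float = 1e-8) -> tuple[float, float]:
    """Tukey-biweight location and IQR-based scale.

    The location is the iteratively reweighted biweight estimate (tuning
    constant ``c`` on MAD-standardised residuals); the scale is IQR/1.349,
    which matches the SD for Gaussian data.  Falls back to median/IQR with
    a warning if the iteration fails to converge.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise DataError("robust estimation needs at least 5 values")
    q1 = quantile_nonparametric(x, 0.25)
    q3 = quantile_nonparametric(x, 0.75)
    scale = (q3 - q1) * IQR_TO_SD
    loc = float(np.median(x))
    mad_scale = stats.median_abs_deviation(x, scale="normal")
    if mad_scale == 0:
        return loc, float(scale)
    for _ in range(max_iter):
        u = (x - loc) / (c * mad_scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            break
        new = float(np.sum(w * x) / np.sum(w))
        if abs(new - loc) <= tol * max(1.0, abs(loc)):
            return new, float(scale)
        loc = new
    import warnings as _w
    _w.warn("biweight location did not converge; falling back to median")
    return float(np.median(x)), float(scale)


# ---------------------------------------------------------------------------
# age compensation
# ---------------------------------------------------------------------------

@dataclass
class AgeModel:
    """Continuous age compensation: value ~ age (or log age).

    ``intercept + slope·g(age)`` with g identity or log.  Optional separate
    linear fits of residual spread against age for the upper and lower
    halves allow the reference interval width to change with age.
    """

    form: str  # none | linear | log_age
    intercept: float = 0.0
    slope: float = 0.0
    slope_ci: tuple | None = None
    fit_method: str = "tukey_biweight"
    reference_age: float | None = None
    scale_fits: dict | None = None
    n_used: int = 0
    n_excluded: int = 0

    def _g(self, age):
        age = np.asarray(age, dtype=float)
        return np.log(age) if self.form == "log_age" else age

    def predict(self, age):
        if self.form == "none":
            return np.full_like(np.asarray(age, dtype=float), self.intercept)
        return self.intercept + self.slope * self._g(age)

    def adjust(self, value, age):
        """Residualise to the reference age: value − fit(age) + fit(ref)."""
        if self.form == "none":
            return np.asarray(value, dtype=float)
        return (np.asarray(value, dtype=float) - self.predict(age)
                + self.predict(self.reference_age))


def fit_age_model(sample: ReferenceSample, form: str = "linear",
                  method: str = "tukey_biweight",
                  min_age_range: float = 5.0,
                  fit_scale: bool = False) -> AgeModel:
    """Fit a continuous age-compensation model to a reference sample.

    Robust (Tukey-biweight) fitting is the default so that age compensation
    can precede outlier removal.  Requires ages for at least 90% of the
    measurements and a usable age spread; otherwise the model degrades to
    ``form="none"``.
    """
    import statsmodels.api as sm

    if form == "none":
        return AgeModel(form="none", intercept=float(np.median(sample.values)))
    if form not in ("linear", "log_age"):
        raise ValueError(f"unknown age model form {form!r}")

    df = sample.data
    age = np.asarray(df["age"], dtype=float)
    value = sample.values
    ok = np.isfinite(age)
    if ok.mean() < 0.90:
        raise ProtocolRefusal(
            f"ages available for only {100*ok.mean():.0f}% of measurements "
            "(>= 90% required)")
    n_excluded = int((~ok).sum())
    age, value = age[ok], value[ok]
    if form == "log_age" and np.any(age <= 0):
        raise DataError("log-age model requires positive ages")
    if np.ptp(age) < min_age_range:
        return AgeModel(form="none", intercept=float(np.median(value)),
                        n_used=age.size, n_excluded=n_excluded)

    g = np.log(age) if form == "log_age" else age
    X = sm.add_constant(g)
    if method == "tukey_biweight":
        fit = sm.RLM(value, X, M=sm.robust.norms.TukeyBiweight()).fit()
    elif method == "least_squares":
        fit = sm.OLS(value, X).fit()
    else:
        raise ValueError(f"unknown fit method {method!r}")
    ci = fit.conf_int()
    model = AgeModel(form=form, intercept=float(fit.params[0]),
                     slope=float(fit.params[1]),
                     slope_ci=(float(ci[1][0]), float(ci[1][1])),
                     fit_method=method,
                     reference_age=float(np.median(age)),
                     n_used=age.size, n_excluded=n_excluded)
    if fit_scale:
        resid = value - model.predict(age)
        fits = {}
        for name, mask in (("upper", resid >= 0), ("lower", resid < 0)):
            if mask.sum() >= 5:
                beta = np.polyfit(age[mask], np.abs(resid[mask]), 1)
                fits[name] = {"slope": float(beta[0]), "intercept": float(beta[1])}
        model.scale_fits = fits
    return model


def age_adjust(sample: ReferenceSample, model: AgeModel) -> ReferenceSample:
    """Return a sample with values residualised to the model's reference
    age; subjects without an age are dropped with a warning entry."""
    if model.form == "none":
        return sample
    age = np.asarray(sample.data["age"], dtype=float)
    ok = np.isfinite(age)
    out = sample
    if not ok.all():
        out = out.drop_rows(~ok, step="drop_missing_age")
        age = age[ok]
    adjusted = model.adjust(out.values, age)
    return out.replace_values(adjusted, step="age_adjust", form=model.form,
                              slope=model.slope, reference_age=model.reference_age)


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionDecision:
    """Outcome of the standard partitioning rules for two subgroups.

    The decisive rules are the 25% mean-difference rule, the 4% outside-rate
    rule and the 1.5 SD-ratio rule; the stricter 15% mean rule is reported
    but not decisive.
    """

    mean_rule_25pct: bool
    mean_rule_15pct: bool
    outside_4pct_rule: bool
    sd_ratio_rule: bool
    recommendation: str  # combine | partition
    details: dict = field(default_factory=dict, hash=False, compare=False)


def partition_check(group_a, group_b, method: str = "nearest") -> PartitionDecision:
    """Decide whether two subgroups need separate reference intervals.

    Partition if (i) the subgroup means differ by more than 25% of the
    combined 95% reference-interval width, or (ii) more than 4% of either
    subgroup falls beyond either combined nonparametric limit (per tail;
    the nominal per-tail fraction is 2.5%, so identically distributed
    subgroups stay safely below the threshold), or (iii) the subgroup SD
    ratio is at least 1.5 regardless of the means.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 20 or b.size < 20:
        raise ProtocolRefusal("each subgroup needs n >= 20 for partition rules")
    pooled = np.concatenate([a, b])
    lo = quantile_nonparametric(pooled, 0.025, method)
    hi = quantile_nonparametric(pooled, 0.975, method)
    ri = hi - lo
    if ri == 0:
        raise ProtocolRefusal("degenerate combined reference interval")
    gap = abs(a.mean() - b.mean())
    frac_out = [{"below": float(np.mean(g < lo)),
                 "above": float(np.mean(g > hi))} for g in (a, b)]
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    sd_ratio = max(sa, sb) / min(sa, sb) if min(sa, sb) > 0 else np.inf
    r25 = gap > 0.25 * ri
    r15 = gap > 0.15 * ri
    r4 = max(max(f.values()) for f in frac_out) > 0.04
    rsd = sd_ratio >= 1.5
    return PartitionDecision(
        mean_rule_25pct=bool(r25), mean_rule_15pct=bool(r15),
        outside_4pct_rule=bool(r4), sd_ratio_rule=bool(rsd),
        recommendation="partition" if (r25 or r4 or rsd) else "combine",
        details={"mean_gap": float(gap), "combined_ri_width": float(ri),
                 "fraction_outside": frac_out, "sd_ratio": float(sd_ratio),
                 "combined_limits": (float(lo), float(hi))})
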