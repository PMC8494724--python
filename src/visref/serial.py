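"""Subject-based reference values for serial measurements.

When a patient is followed over time, the question is not whether a value
sits inside the population reference interval but whether it has *changed*
by more than test–retest noise.  The critical difference is the
repeatability coefficient

    RC = z·√2·CV   or   RC = z·√2·SD,

with z = 1.96 by default, i.e. RC = 2.77 × the within-unit dispersion.
SD (absolute units) is the natural basis for peak times; CV (percent) for
amplitudes.

Replicates are pooled over units with a weighted average that credits units
with more replicates:  SD = √( Σ(kᵢ−1)sᵢ² / Σ(kᵢ−1) ).  A unit is one
subject-eye: the two eyes of one subject are *never* averaged or pooled into
one unit, because when their expected values differ (e.g. unilateral
disease) a combined SD is artificially inflated.  Bootstrap uncertainty for
the RC resamples subjects, carrying both of a subject's eye-units together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ProtocolRefusal

__all__ = [
    "ReplicateSet",
    "RepeatabilityEstimate",
    "replicate_sets_from_table",
    "pooled_dispersion",
    "repeatability_coefficient",
    "estimate_rc",
    "rc_uncertainty",
    "delta_check",
]

#: units treated as amplitude-like → CV basis; time-like → SD basis
AMPLITUDE_UNITS = {"uv", "µv", "μv", "nv", "%"}
TIME_UNITS = {"ms", "s"}


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate measurements of one unit (one subject-eye)."""

    unit_id: str          # subject-eye composite, e.g. "S01:R"
    subject_id: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size < 2:
            raise DataError(f"unit {self.unit_id}: needs >= 2 replicates")
        object.__setattr__(self, "values", v)

    @property
    def k(self) -> int:
        return self.values.size

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    @property
    def cv(self) -> float:
        m = float(np.mean(self.values))
        if m == 0:
            raise DataError(f"unit {self.unit_id}: zero mean, CV undefined")
        return 100.0 * self.sd / abs(m)

    def dispersion(self, basis: str) -> float:
        return self.sd if basis == "sd" else self.cv


@dataclass
class RepeatabilityEstimate:
    """Repeatability coefficient with its basis and provenance."""

    rc: float
    basis: str                  # "sd" (parameter units) or "cv" (percent)
    z: float
    pooled_dispersion: float
    n_units: int
    n_subjects: int
    ci90: tuple | None = None
    warnings: list = field(default_factory=list)


def replicate_sets_from_table(df: pd.DataFrame, parameter: str | None = None
                              ) -> list[ReplicateSet]:
    """Build subject-eye replicate sets from a long-format table.

    Rows are grouped by (subject, side); sides are kept separate by design.
    Units with fewer than two replicates are dropped.
    """
    if parameter is not None:
        df = df[df["parameter"] == parameter]
    if "side" not in df.columns:
        df = df.assign(side="NA")
    sets = []
    for (sid, side), grp in df.groupby(["subject_id", "side"], dropna=False):
        v = pd.to_numeric(grp["value"], errors="coerce").dropna().to_numpy()
        if v.size >= 2:
            sets.append(ReplicateSet(unit_id=f"{sid}:{side}",
                                     subject_id=str(sid), values=v))
    return sets


def pooled_dispersion(sets: list[ReplicateSet], basis: str = "sd") -> float:
    """Replicate-weighted pooled dispersion across units:
    √( Σ(kᵢ−1)·dᵢ² / Σ(kᵢ−1) ), with dᵢ the per-unit SD or CV."""
    if basis not in ("sd", "cv"):
        raise ValueError("basis must be 'sd' or 'cv'")
    if not sets:
        raise ProtocolRefusal("no units with >= 2 replicates")
    w = np.array([s.k - 1 for s in sets], dtype=float)
    d = np.array([s.dispersion(basis) for s in sets], dtype=float)
    return float(np.sqrt(np.sum(w * d**2) / np.sum(w)))


def repeatability_coefficient(dispersion: float, z: float = 1.96) -> float:
    """RC = z·√2·dispersion (2.77 × dispersion at z = 1.96)."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    return float(z * np.sqrt(2.0) * dispersion)


def basis_for_units(units: str | None) -> str:
    """Default dispersion basis from parameter units: CV for amplitudes
    (µV, %), SD for times (ms).  Unknown units default to SD."""
    if units is None:
        return "sd"
    u = units.strip().lower()
    if u in AMPLITUDE_UNITS:
        return "cv"
    return "sd"


def estimate_rc(sets: list[ReplicateSet], basis: str = "sd", z: float = 1.96,
                B: int = 1000, seed: int | None = None,
                min_units: int = 8) -> RepeatabilityEstimate:
    """Pool replicate dispersion and form the repeatability coefficient,
    with a subject-level bootstrap 90% CI.

    Fewer than 8 units is flagged (the RC can be measured with as few as
    eight subjects, not fewer)."""
    disp = pooled_dispersion(sets, basis)
    rc = repeatability_coefficient(disp, z)
    n_subjects = len({s.subject_id for s in sets})
    est = RepeatabilityEstimate(rc=rc, basis=basis, z=z,
                                pooled_dispersion=disp, n_units=len(sets),
                                n_subjects=n_subjects)
    if len(sets) < min_units:
        est.warnings.append(
            f"only {len(sets)} units (< {min_units}); RC is unreliable")
    est.ci90 = rc_uncertainty(sets, basis=basis, z=z, B=B, seed=seed)
    return est


def rc_uncertainty(sets: list[ReplicateSet], basis: str = "sd",
                   z: float = 1.96, B: int = 1000,
                   seed: int | None = None) -> tuple:
    """Percentile-bootstrap 90% CI of the RC, resampling subjects (each
    carrying all its eye-units) to respect inter-eye correlation."""
    rng = np.random.default_rng(seed)
    by_subject: dict = {}
    for s in sets:
        by_subject.setdefault(s.subject_id, []).append(s)
    subjects = list(by_subject.values())
    n = len(subjects)
    reps = np.empty(B)
    for b in range(B):
        take = rng.integers(n, size=n)
        resampled = [u for i in take for u in subjects[i]]
        reps[b] = repeatability_coefficient(pooled_dispersion(resampled, basis), z)
    return (float(np.quantile(reps, 0.05)), float(np.quantile(reps, 0.95)))


def delta_check(previous: float, current: float,
                rc: RepeatabilityEstimate) -> str:
    """Has the parameter changed by more than test–retest noise?

    CV basis compares the percent change ``100·|Δ|/previous`` to the RC;
    SD basis compares ``|Δ|`` directly.  Change must strictly exceed the RC;
    a change exactly equal to the RC is still "no_change".  Returns one of
    ``no_change``, ``changed_up``, ``changed_down``.
    """
    if rc.basis == "cv":
        if previous <= 0:
            raise DataError("CV-based delta check needs a positive previous value")
        magnitude = 100.0 * abs(current - previous) / previous
    else:
        magnitude = abs(current - previous)
    if magnitude <= rc.rc:
        return "no_change"
    return "changed_up" if current > previous else "changed_down"
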