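"""Data model for reference samples of visual-electrophysiology measurements.

A reference sample is a curated set of measurements of one parameter
(e.g. DA 3.0 ERG b-wave amplitude in µV) from reference individuals, each
measurement tagged with the eye it came from.  The long (tidy) CSV layout —
one row per measurement — serves every downstream module, including serial
measurements with session/replicate columns.

Reporting policy scales with the number of subjects: below 10 subjects no
reference data should be reported at all; 10–19 support only a ranked table
with a median; 20–39 support robust or parametric limits with illustrative
CIs; 40–119 support bootstrap limits; 120 and above support the full
nonparametric method with exact order-statistic confidence intervals.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

#: canonical column order of the long CSV layout
COLUMNS = [
    "subject_id",
    "side",
    "parameter",
    "value",
    "units",
    "age",
    "sex",
    "session_id",
    "replicate_index",
]

MANDATORY = ["subject_id", "value", "parameter"]

SIDES = ("R", "L", "NA")


class Tier(str, enum.Enum):
    """Reporting tier as a function of subject count."""

    REFUSE = "refuse"
    RANKED_TABLE = "ranked_table"
    ROBUST_SMALL = "robust_small"
    TRANSFER_SCALE = "transfer_scale"
    FULL = "full"


@dataclass(frozen=True)
class ReportingTier:
    tier: Tier
    n: int


def reporting_tier(n: int) -> ReportingTier:
    """Reporting policy for a sample of ``n`` subjects.

    Boundaries at 10, 20, 40 and 120 subjects: fewer than 10 subjects should
    not be reported; 120 after outlier removal is the target for full
    nonparametric estimation with exact CIs.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n < 10:
        tier = Tier.REFUSE
    elif n < 20:
        tier = Tier.RANKED_TABLE
    elif n < 40:
        tier = Tier.ROBUST_SMALL
    elif n < 120:
        tier = Tier.TRANSFER_SCALE
    else:
        tier = Tier.FULL
    return ReportingTier(tier=tier, n=int(n))


@dataclass
class RowError:
    """A malformed CSV row, reported with its 1-based line number."""

    line: int
    message: str


@dataclass
class ReferenceSample:
    """Measurements of one parameter for one partition.

    ``data`` holds one row per measurement in the canonical long layout.
    ``partition`` records the factor levels that define this partition
    (e.g. ``{"sex": "F"}``).  ``curation_log`` accumulates an ordered record
    of every adjustment applied (outlier removal, age adjustment, transform).
    """

    parameter: str
    data: pd.DataFrame
    partition: dict = field(default_factory=dict)
    curation_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in MANDATORY if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory columns: {missing}")
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        params = df["parameter"].dropna().unique()
        if len(params) > 1:
            raise DataError(f"mixed parameters in one sample: {sorted(params)}")
        bad_side = set(df["side"].dropna().unique()) - set(SIDES)
        if bad_side:
            raise DataError(f"unknown side labels: {sorted(bad_side)}")
        values = pd.to_numeric(df["value"], errors="coerce")
        if values.isna().any() or not np.isfinite(values).all():
            raise DataError("non-finite measurement values")
        self.data = df.reset_index(drop=True)
        self.data["value"] = values.to_numpy(dtype=float)

    # -- basic accessors -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(dtype=float)

    @property
    def subjects(self) -> np.ndarray:
        return self.data["subject_id"].to_numpy()

    @property
    def n_measurements(self) -> int:
        return len(self.data)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def units(self) -> str | None:
        u = self.data["units"].dropna().unique()
        return str(u[0]) if len(u) else None

    def tier(self) -> ReportingTier:
        return reporting_tier(self.n_subjects)

    def log(self, step: str, **details) -> None:
        """Append one curation step to the ordered log."""
        self.curation_log.append({"step": step, **details})

    def replace_values(self, values: np.ndarray, step: str, **details) -> "ReferenceSample":
        """Return a copy with new values and the step recorded."""
        df = self.data.copy()
        df["value"] = np.asarray(values, dtype=float)
        out = ReferenceSample(self.parameter, df, dict(self.partition),
                              list(self.curation_log))
        out.log(step, **details)
        return out

    def drop_rows(self, mask: np.ndarray, step: str, **details) -> "ReferenceSample":
        """Return a copy without the rows where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        df = self.data.loc[~mask].reset_index(drop=True)
        out = ReferenceSample(self.parameter, df, dict(self.partition),
                              list(self.curation_log))
        out.log(step, n_removed=int(mask.sum()), **details)
        return out


def read_reference_table(
    source,
    partition_by: Sequence[str] = (),
) -> tuple[list[ReferenceSample], list[RowError]]:
    """Read a long-format CSV into one :class:`ReferenceSample` per
    parameter × partition.

    Rows with non-numeric values are collected as :class:`RowError`\\ s rather
    than aborting the read; the read fails only if every row is unusable or a
    mandatory column is absent.
    """
    df = pd.read_csv(source, dtype={"subject_id": str, "session_id": str})
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    for col in partition_by:
        if col not in df.columns:
            raise SchemaError(f"partition column not in table: {col!r}")

    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() | ~np.isfinite(values.fillna(np.inf))
    errors = [
        RowError(line=int(i) + 2, message=f"non-numeric value: {df['value'].iloc[i]!r}")
        for i in np.flatnonzero(bad.to_numpy())
    ]
    if bad.all():
        raise DataError("no usable rows in table")
    df = df.loc[~bad].copy()
    df["value"] = pd.to_numeric(df["value"])

    keys = ["parameter", *partition_by]
    samples = []
    for key, grp in df.groupby(keys, dropna=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        partition = dict(zip(partition_by, (str(k) for k in key[1:])))
        samples.append(
            ReferenceSample(parameter=str(key[0]), data=grp.reset_index(drop=True),
                            partition=partition)
        )
    return samples, errors


def write_reference_table(samples: Iterable[ReferenceSample], target) -> None:
    """Write samples back to one long-format CSV (inverse of
    :func:`read_reference_table` for finite decimal values)."""
    frames = [s.data.reindex(columns=COLUMNS) for s in samples]
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(target, index=False)


def round_trip(samples: Iterable[ReferenceSample],
               partition_by: Sequence[str] = ()) -> list[ReferenceSample]:
    """Write then re-read (used to assert the round-trip invariant)."""
    buf = io.StringIO()
    write_reference_table(samples, buf)
    buf.seek(0)
    out, _ = read_reference_table(buf, partition_by=partition_by)
    return out
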