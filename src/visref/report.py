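"""Classification semantics, multiplicity accounting and JSON reports.

A patient value is classified against a reference-limit estimate: outside a
limit → abnormal (low or high); inside the interval but within a limit's 90%
CI band → indeterminate, because at that distance the classification is
dominated by the uncertainty of the limit itself; otherwise normal.  In a
one-tailed mode the unmonitored tail never produces an abnormal verdict —
an extreme value there is reported as outside the monitored tail and not
assessed.

Reporting n independent parameters at 95% coverage carries a familywise
false-positive risk of 1 − 0.95ⁿ; the toolkit reports that risk rather than
widening limits, since a correction would need the inter-parameter
correlations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

from .limits import ReferenceLimitEstimate, TailMode

__version__ = "0.1.0"

__all__ = ["ClassificationResult", "classify", "familywise_risk",
           "MultiplicityNote", "build_report", "config_hash"]


@dataclass(frozen=True)
class ClassificationResult:
    verdict: str  # normal | abnormal_low | abnormal_high | indeterminate
    distance_to_nearer_limit: float | None
    limits: dict
    notes: list = field(default_factory=list, hash=False, compare=False)


def classify(value: float, estimate: ReferenceLimitEstimate) -> ClassificationResult:
    """Classify one measurement against an estimate's limits and CI bands."""
    tail = TailMode(estimate.tail)
    notes: list = []
    limits = {"lower": estimate.lower, "upper": estimate.upper,
              "ci_lower": estimate.ci_lower, "ci_upper": estimate.ci_upper,
              "tail": tail.value}

    monitored: dict = {}
    if "lower" in tail.percentiles:
        monitored["lower"] = (estimate.lower, estimate.ci_lower)
    if "upper" in tail.percentiles:
        monitored["upper"] = (estimate.upper, estimate.ci_upper)
    if not monitored:
        raise ValueError("estimate carries no limits")

    distances = {name: abs(value - lim) for name, (lim, _) in monitored.items()
                 if lim is not None}
    nearer = min(distances, key=distances.get) if distances else None
    dist = distances.get(nearer)

    verdict = "normal"
    lo = monitored.get("lower", (None, None))[0]
    hi = monitored.get("upper", (None, None))[0]
    if lo is not None and value < lo:
        verdict = "abnormal_low"
    elif hi is not None and value > hi:
        verdict = "abnormal_high"
    else:
        for name, (lim, ci) in monitored.items():
            if ci is not None and ci[0] <= value <= ci[1]:
                verdict = "indeterminate"
                notes.append(f"value lies within the 90% CI of the {name} limit")
                break

    if tail is TailMode.LOWER_ONLY and estimate.ci_lower is not None:
        pass
    if tail is not TailMode.TWO_TAILED:
        # report, but never judge, the unmonitored extreme
        other = "upper" if tail is TailMode.LOWER_ONLY else "lower"
        notes_needed = ((other == "upper" and estimate.upper is None)
                        or (other == "lower" and estimate.lower is None))
        if notes_needed:
            notes.append(f"{other} tail not monitored for this parameter: "
                         "not assessed")
    return ClassificationResult(verdict=verdict,
                                distance_to_nearer_limit=dist,
                                limits=limits, notes=notes)


@dataclass(frozen=True)
class MultiplicityNote:
    n_parameters: int
    familywise_risk: float
    caveat: str = ("risk assumes the parameters are mutually independent; "
                   "correlated parameters carry a lower joint risk")


def familywise_risk(n: int) -> float:
    """Chance of at least one false-positive among n independent parameters
    each judged at 95% coverage: 1 − 0.95ⁿ (0.05 at n = 1)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return float(1.0 - 0.95**n)


def multiplicity_note(n: int) -> MultiplicityNote:
    return MultiplicityNote(n_parameters=n, familywise_risk=familywise_risk(n))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_report(kind: str, payload: dict, config: dict | None = None,
                 seed: int | None = None, curation_log: list | None = None,
                 warnings: list | None = None) -> dict:
    """Assemble a reproducible JSON-serialisable report.

    Embeds the tool version, the configuration hash, every seed, and the
    ordered curation log; deliberately carries no timestamp so re-running
    with identical inputs reproduces the report byte-for-byte.
    """
    config = config or {}
    return {
        "tool": "visref",
        "version": __version__,
        "kind": kind,
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "curation_log": curation_log or [],
        "warnings": warnings or [],
        "result": payload,
    }


def to_jsonable(obj):
    """Recursively convert dataclasses/arrays/enums for json.dumps."""
    import enum

    import numpy as np

    if isinstance(obj, dict):
        return {k: to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return to_jsonable(asdict(obj))
    return obj
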