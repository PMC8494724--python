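import io

import numpy as np
import pandas as pd
import pytest

from visref import ReferenceSample


@pytest.fixture
def rng():
    return np.random.default_rng(20210421)


def make_sample(values, subjects=None, sides=None, parameter="b_amp",
                units="uV", **extra) -> ReferenceSample:
    """Build a ReferenceSample from plain arrays."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if subjects is None:
        subjects = [f"S{i:04d}" for i in range(n)]
    df = pd.DataFrame({"subject_id": subjects, "value": values,
                       "parameter": parameter, "units": units})
    if sides is not None:
        df["side"] = sides
    for k, v in extra.items():
        df[k] = v
    return ReferenceSample(parameter=parameter, data=df)


def make_bilateral(pairs, parameter="b_amp") -> ReferenceSample:
    """One subject per (right, left) pair; a scalar entry means one eye."""
    rows = []
    for i, p in enumerate(pairs):
        sid = f"S{i:04d}"
        if np.isscalar(p):
            rows.append((sid, "R", float(p)))
        else:
            rows.append((sid, "R", float(p[0])))
            rows.append((sid, "L", float(p[1])))
    df = pd.DataFrame(rows, columns=["subject_id", "side", "value"])
    df["parameter"] = parameter
    return ReferenceSample(parameter=parameter, data=df)


def csv_stream(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")
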