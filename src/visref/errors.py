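"""Exception hierarchy.

Data errors (malformed input) and protocol refusals (inputs that are valid
but fail a methodological gate, e.g. too few subjects) are distinguished so
the CLI can map them to distinct exit codes.
"""


class VisrefError(Exception):
    """Base class for all package errors."""


class DataError(VisrefError):
    """Malformed or inconsistent input data."""


class SchemaError(DataError):
    """Input table is missing mandatory columns or has an unusable layout."""


class ProtocolRefusal(VisrefError):
    """Input is well-formed but fails a methodological gate."""


class TierRefusal(ProtocolRefusal):
    """Too few subjects for the requested reporting tier."""


class NormalityRefusal(ProtocolRefusal):
    """Parametric limits requested but normality is rejected for every
    available transform."""
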