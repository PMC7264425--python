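"""Exception types shared across the package."""


class NlrMethylomeError(Exception):
    """Base class for package errors."""


class GffParseError(NlrMethylomeError):
    """A malformed GFF3 line; the message names the 1-based line number."""


class ReportParseError(NlrMethylomeError):
    """A malformed cytosine-report line; the message names the line number."""


class CoordinateError(NlrMethylomeError):
    """A coordinate falls outside the sequence it refers to."""


class ConfigurationError(NlrMethylomeError):
    """Inconsistent inputs: duplicate region specs, mismatched gene lists,
    infeasible simulation packing, and similar."""
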