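"""Exception hierarchy shared across the toolkit."""


class BcrtraceError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(BcrtraceError):
    """An input table is missing required columns for its dialect."""


class ValidationError(BcrtraceError):
    """Record-level invariant violation (duplicate ids, bad locus, ...)."""


class ParameterError(BcrtraceError):
    """A user-supplied parameter is outside its admissible range."""


class AnnotationError(BcrtraceError):
    """A per-record annotation (gene call, alignment, bounds) is unusable."""


class InsufficientDataError(BcrtraceError):
    """Too few observations for the requested statistic."""
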