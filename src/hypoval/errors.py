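"""Exception hierarchy shared across the package."""


class HypovalError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HypovalError, ValueError):
    """A configuration value is out of range or inconsistent; the message names the field."""


class TraceFormatError(HypovalError, ValueError):
    """A trace or manifest file does not match the documented dialect."""


class TraceDataError(HypovalError, ValueError):
    """Trace contents violate a hard invariant (e.g. non-monotone time)."""


class AlignmentError(HypovalError, ValueError):
    """A series is not aligned to the expected sampling grid."""


class CohortError(HypovalError, ValueError):
    """A cohort-level operation received empty or inconsistent input."""


class PipelineError(HypovalError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""
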