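"""Exception hierarchy shared across the package."""


class DistillrctError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DistillrctError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ParseError(DistillrctError, ValueError):
    """A trial table could not be parsed; the message names column/row."""


class FitError(DistillrctError, RuntimeError):
    """A model fit could not be carried out (e.g. no outcome variation)."""


class DistillationError(DistillrctError, ValueError):
    """Stage-two subsetting failed (bad fraction, unscored subject, ...)."""


class EstimationError(DistillrctError, RuntimeError):
    """Stage-three effect estimation failed structurally (e.g. arm exhausted)."""
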