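"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`OrdsurveyError`, so callers can catch the package's own failures
without swallowing programming errors.
"""


class OrdsurveyError(Exception):
    """Base class for all errors raised by ordsurvey."""


class SchemaError(OrdsurveyError):
    """Input file structure does not match the declared schema."""


class ValidationError(OrdsurveyError):
    """A record violates a dataset invariant (bad code, range, duplicate)."""


class ParameterError(OrdsurveyError):
    """Model parameters violate their support (e.g. unordered thresholds)."""


class EmptyStratumError(OrdsurveyError):
    """A fit was requested on a stratum with zero usable respondents."""


class InitializationError(OrdsurveyError):
    """An MCMC chain was started at a point with zero posterior density."""


class SamplerError(OrdsurveyError):
    """The target density returned NaN during sampling."""


class UndefinedDiagnosticError(OrdsurveyError):
    """A convergence diagnostic is undefined (e.g. zero within-chain variance)."""
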