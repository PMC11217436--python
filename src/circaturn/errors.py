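"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`CircaturnError` so that the
orchestration layer can distinguish validation problems (bad inputs,
malformed tables) from runtime failures.
"""


class CircaturnError(Exception):
    """Base class for all package errors."""


class FormatError(CircaturnError):
    """An input file does not have the expected layout (e.g. a missing column)."""


class DesignError(CircaturnError):
    """A study design is internally inconsistent or does not match the data."""


class NormalizationError(CircaturnError):
    """Sample-loading normalization cannot be performed (e.g. an empty channel)."""


class InsufficientDesignError(CircaturnError):
    """A statistical test cannot run on the given sampling design."""


class TransformError(CircaturnError):
    """A value transform failed (e.g. log of a non-positive intensity)."""


class FitError(CircaturnError):
    """A model fit failed to converge from every start."""


class SolverError(CircaturnError):
    """The kinetic ODE solver was asked to run outside its accuracy envelope."""


class ConfigError(CircaturnError):
    """A pipeline configuration is invalid."""
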