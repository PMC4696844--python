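"""Exception hierarchy for :mod:`twolocus`."""


class TwoLocusError(Exception):
    """Base class for all package errors."""


class ParameterError(TwoLocusError, ValueError):
    """A model parameter violates its mathematical preconditions."""


class ValidationError(TwoLocusError, ValueError):
    """A sample configuration is malformed for the given model."""


class SolverError(TwoLocusError, RuntimeError):
    """The linear system could not be solved to the required accuracy."""
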