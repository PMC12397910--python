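"""Exception hierarchy for the g4condense pipeline."""


class G4CondenseError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(G4CondenseError, ValueError):
    """A generator or analysis parameter is outside its valid domain."""


class InvalidInputError(G4CondenseError, ValueError):
    """Malformed input data (intervals, tables, traces)."""


class InvalidSequenceError(InvalidInputError):
    """A nucleotide sequence contains illegal characters."""


class DegenerateCurveError(G4CondenseError, ValueError):
    """A rank curve cannot be scaled (all values identical)."""


class NoTangentError(G4CondenseError, ValueError):
    """No slope-1 tangent point exists on the scaled rank curve."""


class EmptyResultError(G4CondenseError, ValueError):
    """An operation retained no records (e.g. no promoter above threshold)."""


class FitFailureError(G4CondenseError, RuntimeError):
    """Nonlinear fit failed to converge after multi-start."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnidentifiableFitError(FitFailureError):
    """The data carry no information about the requested rate (flat trace)."""


class CorrectionError(G4CondenseError, ValueError):
    """FRAP trace correction hit a non-positive denominator."""


class IntegrationError(G4CondenseError, RuntimeError):
    """ODE integration failed within tolerance."""
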