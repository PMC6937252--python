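"""Exception hierarchy for the pcp package."""


class PCPError(Exception):
    """Base class for all package errors."""


class InvalidElementError(PCPError, ValueError):
    """Unknown element symbol or invalid neutral electron count."""


class DomainError(PCPError, ValueError):
    """Quantity evaluated outside its mathematical domain (e.g. N <= 0)."""


class XYZParseError(PCPError, ValueError):
    """Malformed XYZ file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class DegenerateGeometryError(PCPError, ValueError):
    """Two atoms at (numerically) identical coordinates."""


class MissingParameterError(PCPError, KeyError):
    """A required element or pair parameter is absent from the ParameterSet."""

    def __str__(self) -> str:  # KeyError quotes its args; keep message readable
        return self.args[0] if self.args else ""


class NonConvergenceError(PCPError, RuntimeError):
    """Newton iteration failed to converge; carries the residual-norm history."""

    def __init__(self, message: str, history: list[float] | None = None):
        self.history = history or []
        super().__init__(message)


class SingularJacobianError(PCPError, RuntimeError):
    """Singular Newton system; retry with damping/regularization or check geometry."""
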