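"""Structured exceptions shared across the package."""


class TraitLVError(Exception):
    """Base class for all errors raised by traitlv."""


class DimensionError(TraitLVError, ValueError):
    """Array shapes or identifier sets do not line up."""


class InvalidValueError(TraitLVError, ValueError):
    """An input violates a domain precondition (non-finite, out of range...)."""


class SolverError(TraitLVError, RuntimeError):
    """ODE integration failed; carries partial diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConvergenceError(TraitLVError, RuntimeError):
    """An iterative procedure could not reach its target tolerance."""


class DataError(TraitLVError, ValueError):
    """Input tables are malformed or inconsistent (missing species, bad schema)."""
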