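"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`HammettError`
so callers (and the CLI) can catch one base class.
"""


class HammettError(Exception):
    """Base class for all hammettfit errors."""


class SchemaError(HammettError):
    """Input file does not match the declared schema (missing columns, bad header)."""


class IntegrityError(HammettError):
    """Table-level constraint violated (duplicate rows, vocabulary mismatch)."""


class DegenerateInputError(HammettError):
    """Input is degenerate for the requested operation (all x equal, zero variance)."""


class ConnectivityError(HammettError):
    """The reaction graph is disconnected; components are reported in ``components``."""

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components or []


class SignError(HammettError):
    """A pairwise slope violates the strict-positivity assumption."""


class ConvergenceError(HammettError):
    """Iterative refinement failed to converge; ``last_residual`` holds the final change."""

    def __init__(self, message, last_residual=None):
        super().__init__(message)
        self.last_residual = last_residual


class IdentifiabilityError(HammettError):
    """Rank-deficient design; ``unresolved`` lists the parameters that cannot be fit."""

    def __init__(self, message, unresolved=None):
        super().__init__(message)
        self.unresolved = unresolved or []


class GeometryError(HammettError):
    """Invalid or degenerate scaffold geometry (collinear triangle, bad distance)."""


class UnknownLabelError(HammettError, KeyError):
    """Lookup of a reaction, group or substituent set not covered by a fitted model."""

    def __str__(self):  # KeyError quotes its payload; keep the plain message
        return self.args[0] if self.args else ""


class EncodingError(HammettError):
    """One-hot encoding failure (unknown label, dimension mismatch)."""


class SolverError(HammettError):
    """Linear solver failure (singular kernel system)."""


class EvaluationError(HammettError):
    """Model/table overlap is empty; nothing to score."""


class ConfigurationError(HammettError):
    """Invalid run configuration (bad reference reaction, empty grid, bad sizes)."""
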