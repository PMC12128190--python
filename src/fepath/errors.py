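"""Exception hierarchy for fepath.

Every error raised by the library derives from :class:`FepathError`, so CLI
code can map library failures to distinct exit codes without enumerating
call sites.
"""

from __future__ import annotations


class FepathError(Exception):
    """Base class for all fepath errors."""

    exit_code = 1


class InvalidParameterError(FepathError, ValueError):
    """A numeric parameter is outside its admissible range."""

    exit_code = 2


class ConfigError(FepathError, ValueError):
    """A configuration file is malformed or fails schema validation."""

    exit_code = 3


class SelectionError(FepathError, KeyError):
    """An atom/residue selection is empty, ambiguous, or invalid."""

    exit_code = 4


class GeometryError(FepathError, ValueError):
    """Degenerate geometry (collinear dihedral atoms, coincident points)."""

    exit_code = 5


class IntegrationInstabilityError(FepathError, RuntimeError):
    """A sampler trajectory diverged; carries the offending step index."""

    exit_code = 6

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class InsufficientDataError(FepathError, ValueError):
    """Not enough samples to carry out the requested estimate."""

    exit_code = 7


class ParseError(FepathError, ValueError):
    """A structure/trajectory file is malformed; carries the line number."""

    exit_code = 8

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ValidationError(FepathError, ValueError):
    """Input data violates a structural contract (duplicate serials, ...)."""

    exit_code = 9


class DegenerateStringError(FepathError, ValueError):
    """A string has identical endpoints or zero total arc length."""

    exit_code = 10


class ConvergenceError(FepathError, RuntimeError):
    """An iterative solver exhausted its iteration budget; carries residual."""

    exit_code = 11

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ShapeError(FepathError, ValueError):
    """Array arguments have mismatched lengths or dimensions."""

    exit_code = 12
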