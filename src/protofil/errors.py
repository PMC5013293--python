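"""Exception and warning types shared across the package."""


class ProtofilError(Exception):
    """Base class for all protofil errors."""


class PDBParseError(ProtofilError):
    """Malformed fixed-column PDB content; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class StructureError(ProtofilError):
    """Inconsistent structure content (e.g. atom-count drift between models)."""


class ConfigurationError(ProtofilError):
    """Invalid user configuration (chain mapping, block widths, ...)."""


class GeometryError(ProtofilError):
    """Degenerate geometry: too few points, collinear sets, zero axes."""


class TrajectorySpecError(ProtofilError):
    """Invalid synthetic-trajectory specification."""


class AxisAmbiguityWarning(UserWarning):
    """Principal axes ill-defined (near-degenerate covariance eigenvalues)."""


class UndefinedTwistWarning(UserWarning):
    """Twist undefined for a frame (principal axis parallel to the filament axis)."""


class AltlocDroppedWarning(UserWarning):
    """Alternate-location atoms beyond the first altloc were dropped."""


class PartialBlockWarning(UserWarning):
    """A trailing partial occupancy block was dropped."""


class TieFallbackWarning(UserWarning):
    """Exact rank-test enumeration refused due to ties; normal approximation used."""
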