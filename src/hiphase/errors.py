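"""Exception taxonomy shared across the package."""


class HiphaseError(Exception):
    """Base class for all package-specific errors."""


class TableLookupError(HiphaseError, KeyError):
    """A requested element/subshell/material is absent from a data table."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it plain
        return self.args[0] if self.args else ""


class TableParseError(HiphaseError, ValueError):
    """A shipped or user-supplied data table is malformed."""


class DomainError(HiphaseError, ValueError):
    """An argument is outside the physically meaningful domain."""


class UnsupportedProfileError(DomainError):
    """Operation not defined for this spatial profile kind."""


class GeometryError(HiphaseError, ValueError):
    """Invalid geometry (scattering angle, region outside a grid, ...)."""


class CoverageError(HiphaseError, ValueError):
    """A site or region is not covered by the map grid with enough margin."""


class CalibrationError(HiphaseError, ValueError):
    """Reference-based calibration is impossible (e.g. nonpositive integral)."""


class ComparisonError(HiphaseError, ValueError):
    """Two results use incompatible conventions and cannot be compared."""


class ConfigError(HiphaseError, ValueError):
    """A configuration file violates the documented schema."""


class NumericalStabilityError(HiphaseError, RuntimeError):
    """An integrator violated a conservation invariant."""
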