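"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration/validation problems -> 2,
missing or malformed inputs -> 3, numerical failures -> 4.
"""


class PenosomeError(Exception):
    """Base class for all package errors."""


class ConfigError(PenosomeError):
    """Invalid configuration or argument values (CLI exit code 2)."""


class InputError(PenosomeError):
    """Missing or malformed input files (CLI exit code 3)."""


class FormatError(InputError):
    """Malformed file contents; carries the offending row where known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class NumericalError(PenosomeError):
    """Numerical failure during integration or fitting (CLI exit code 4)."""


class IntegrationError(NumericalError):
    """Non-finite or strongly negative state during ODE integration."""

    def __init__(self, t: float, detail: str = "non-finite state"):
        self.t = t
        super().__init__(f"integration failed at t = {t:g} min: {detail}")


class LayoutError(ConfigError):
    """Invalid compartment layout (e.g. volume fraction >= 1)."""


class PlacementError(ConfigError):
    """Could not place compartments in the synthetic frame without overlap."""


class NormalizationError(NumericalError):
    """Trace normalization impossible (zero reference, reference <= background)."""


class WindowError(NumericalError):
    """Fit window contains too few samples."""


class UnidentifiableError(NumericalError):
    """Model parameters not identifiable from the data (e.g. no bleach)."""
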