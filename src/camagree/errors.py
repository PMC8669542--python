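"""Exception types shared across the package."""


class CamagreeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CamagreeError):
    """An input table is missing required columns or has a malformed header."""


class ValidationError(CamagreeError):
    """A row-level value violates the data contract.

    ``row`` is the 1-based line number in the source file (header is line 1)
    when the table came from a file, otherwise the 0-based frame index.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class DuplicateRecordError(CamagreeError):
    """Two rows share the same (patient, occasion, instrument) key."""


class PairingError(CamagreeError):
    """Concurrent CAM/3D-CAM administrations cannot be paired as requested."""


class SeparationError(CamagreeError):
    """The binary response is constant within an instrument; the mixed-model
    likelihood has no interior maximum for the method contrast."""


class ConvergenceError(CamagreeError):
    """The marginal-likelihood optimizer failed to converge."""


class UndefinedStatisticError(CamagreeError):
    """A summary statistic (ICC, kappa) is undefined for the given inputs."""


class IntegrationDimensionError(CamagreeError):
    """The brute-force integrator refuses: random-effect dimension too large."""
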