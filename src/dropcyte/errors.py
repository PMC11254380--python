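"""Exception hierarchy for the dropcyte pipeline."""


class DropcyteError(Exception):
    """Base class for all dropcyte errors."""


class ConfigurationError(DropcyteError):
    """Invalid constants, grid, panel, or calibration parameters."""


class SchemaError(DropcyteError):
    """An on-disk table does not have the declared columns/channels."""


class IntegrityError(DropcyteError):
    """A table is structurally valid but internally inconsistent (e.g. ragged grid)."""


class EstimationError(DropcyteError):
    """A required estimate cannot be formed (e.g. no blank droplets)."""


class PairingError(DropcyteError):
    """Measurement sets of two conditions cannot be paired."""


class DegenerateTestError(DropcyteError):
    """A statistical test is undefined on the given data (e.g. zero-variance differences)."""
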