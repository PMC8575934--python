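"""Exception hierarchy used across the package."""


class ChiroSenseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChiroSenseError):
    """A file does not follow the expected dialect (missing header keys, bad columns)."""


class DataError(ChiroSenseError):
    """Parsed data violate an invariant (duplicates, empty tables, non-finite values)."""


class RangeError(ChiroSenseError):
    """A requested wavelength range falls outside the available data (no extrapolation)."""


class UnsupportedDialectError(FormatError):
    """JCAMP-DX feature outside the supported minimal subset."""


class AlignmentError(ChiroSenseError):
    """Blocks or datasets disagree on sample identity/ordering."""


class DimensionError(ChiroSenseError):
    """Requested component/latent-variable count incompatible with the data shape."""


class DegenerateInputError(ChiroSenseError):
    """Input too small or too degenerate for the operation (e.g. single-sample block)."""


class ConfigurationError(ChiroSenseError):
    """Inconsistent pipeline/design configuration."""


class IllPosedDesignError(ConfigurationError):
    """Experiment design with fewer training samples than response channels."""


class PresetLookupError(ChiroSenseError, KeyError):
    """Unknown analyte requested from the preset basis table."""


class ConvergenceError(ChiroSenseError):
    """Iterative algorithm hit its iteration limit."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class RankDeficiencyError(ChiroSenseError):
    """Singular normal equations; refusing a silent pseudo-inverse."""


class CalibrationError(ChiroSenseError):
    """Univariate calibration impossible (degenerate design, zero slope)."""
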