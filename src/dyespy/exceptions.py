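"""Exception hierarchy for dyespy.

All package errors derive from :class:`DyeSpyError` so callers can catch one
base class; the subclasses mirror the failure modes of the pipeline stages
(schema / parse / coverage problems on input, alignment problems between
grids, degenerate numerical input, and missing model assets).
"""


class DyeSpyError(Exception):
    """Base class for all dyespy errors."""


class SchemaError(DyeSpyError):
    """Input table lacks a required column or has an invalid header."""


class SpectrumParseError(DyeSpyError):
    """A cell of an input table could not be parsed as an intensity."""


class CoverageError(DyeSpyError):
    """Wavenumber coverage does not span the required analysis range."""


class GridRangeError(DyeSpyError):
    """A resampling grid extends beyond the support of a spectrum."""


class AlignmentError(DyeSpyError):
    """Spectra expected to share a wavenumber grid do not."""


class NormalizationError(DyeSpyError):
    """Area normalization is undefined (non-positive total intensity)."""


class DataError(DyeSpyError):
    """Numerically invalid data (non-finite values, vector too short)."""


class TrainingError(DyeSpyError):
    """A model cannot be fitted on the provided data."""


class CalibrationError(DyeSpyError):
    """A statistical calibration step received degenerate input."""


class ConfigurationError(DyeSpyError):
    """A required model asset or configuration entry is missing."""


class UsageError(DyeSpyError):
    """An operation was called with arguments its contract forbids."""
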