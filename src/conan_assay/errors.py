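"""Exception and warning hierarchy for the assay pipeline.

Hard failures derive from :class:`ConanError`; recoverable data-quality
issues are emitted as :class:`AssayWarning` (via ``warnings.warn``) or
collected as string flags on result objects.
"""


class ConanError(Exception):
    """Base class for all assay-pipeline errors."""


class SpectrumError(ConanError):
    """Malformed spectrum: wrong shape, non-monotone grid, missing coverage."""


class LayoutError(ConanError):
    """Invalid plate layout or layout/spectra mismatch."""


class PeakDetectionError(ConanError):
    """LSPR peak search failed (window not covered by the grid)."""


class UndefinedAIError(ConanError):
    """Aggregation index undefined: non-positive red-shift denominator."""


class WavelengthMismatchError(ConanError):
    """AI ratio requested between results computed on different wavelength sets."""


class CalibrationError(ConanError):
    """Calibration cannot be fitted or is being misused."""


class ExtrapolationError(CalibrationError):
    """AI ratio outside the calibrated window (inverse prediction refused)."""


class PurityError(ConanError):
    """Reference points missing/invalid or a dilution series cannot be graded."""


class TitrationError(ConanError):
    """Stoichiometric titration received invalid parameters."""


class TitrationRefusedError(TitrationError):
    """Titration gatekeeper: the purity verdict does not allow quantification."""


class SimulationError(ConanError):
    """Synthetic-plate generator received an invalid scenario."""


class AssayWarning(UserWarning):
    """Non-fatal data-quality warning raised by the pipeline."""
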