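"""Exception hierarchy shared across the pipeline stages."""


class HopchemError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HopchemError, ValueError):
    """Invalid generator or run configuration."""


class CatalogueError(HopchemError, KeyError):
    """A compound required by the forward model is missing from the catalogue."""


class InputError(HopchemError, ValueError):
    """Malformed chromatogram, window, or value list."""


class DegenerateDesignError(HopchemError, ValueError):
    """Calibration design with no concentration spread."""


class CurveError(HopchemError, ValueError):
    """Calibration curve unusable for quantitation (e.g. non-positive slope)."""


class RangeError(HopchemError, ValueError):
    """Measured response above the calibrated range; dilute and re-run."""


class StandardMixtureError(HopchemError, ValueError):
    """Reference-standard areas incomplete or inconsistent."""


class FixtureIntegrityError(HopchemError, ValueError):
    """Packaged trait-table fixture fails its structural invariants."""


class SummaryError(HopchemError, ValueError):
    """Group summary requested for an empty group."""
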