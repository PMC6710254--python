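"""Exception hierarchy for the gelswitch pipeline."""


class GelSwitchError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(GelSwitchError, ValueError):
    """A parameter is outside its documented domain."""


class DetectionFailureError(GelSwitchError):
    """An image-feature detector (circle, reference object) found nothing."""


class TrackingFailureError(GelSwitchError):
    """Too many frames of a series failed to yield an area measurement."""


class NoTransitionError(GelSwitchError):
    """No transition signature (negative derivative excursion) was found."""


class AlignmentError(GelSwitchError):
    """Frames and temperature log (or spectra grids) cannot be aligned."""


class FormatError(GelSwitchError):
    """A data file violates the expected dialect."""


class FitError(GelSwitchError):
    """A least-squares fit is ill-posed (e.g. rank-deficient components)."""


class FeatureExtractionError(GelSwitchError):
    """No usable samples remain for spectral feature extraction."""
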