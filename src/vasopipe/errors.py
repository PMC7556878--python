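"""Exception hierarchy shared across the pipeline."""


class VasopipeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(VasopipeError, ValueError):
    """A parameter is outside its valid domain (non-positive rate, bad shape, ...)."""


class NoVesselError(VasopipeError):
    """No vessel signal detectable in a profile, frame or ROI."""


class EdgeTruncationError(VasopipeError):
    """A half-maximum crossing falls outside the sampled profile."""


class InvalidRateError(InvalidParameterError):
    """Sampling rate too low for the requested filter or analysis band."""


class NoStationaryPeriodError(VasopipeError):
    """A basal value was requested but no stationary period exists."""


class DegenerateDesignError(VasopipeError):
    """The experimental design cannot identify the requested model
    (e.g. a mixed model with a single animal)."""
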