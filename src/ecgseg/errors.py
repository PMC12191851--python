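"""Exception hierarchy for the ECG page digitization pipeline."""


class EcgSegError(Exception):
    """Base class for all ecgseg errors."""


class BoxOutOfBounds(EcgSegError):
    """A crop box extends beyond the image extent."""


class InvalidSigma(EcgSegError):
    """Gaussian blur requested with a non-positive standard deviation."""


class DegenerateImage(EcgSegError):
    """All pixels share one intensity; no Otsu threshold exists."""


class InsufficientPeaks(EcgSegError):
    """Fewer projection-histogram peaks survive suppression than requested."""


class EmptyPatch(EcgSegError):
    """A patch column span collapsed after margin trimming."""


class NoSignalFound(EcgSegError):
    """No foreground pixel found in the seed search window of any column."""


class LayoutMismatch(EcgSegError):
    """A layout model is inconsistent with the mask it is applied to."""


class ShapeMismatch(EcgSegError):
    """Two images being compared or composed have different shapes."""


class SpecInvalid(EcgSegError):
    """A synthetic page specification violates its invariants."""


class InvalidBeatParams(EcgSegError):
    """Beat waveform parameters are out of range."""
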