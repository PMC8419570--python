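"""Exception hierarchy shared across the pipeline stages."""


class PhylosongError(Exception):
    """Base class for all package-specific errors."""


class DegenerateSignalError(PhylosongError):
    """A waveform or spectrogram carries no usable signal (zero power/sd)."""


class DegenerateMatrixError(PhylosongError):
    """A distance matrix has no off-diagonal variation to work with."""


class DegenerateTraitError(PhylosongError):
    """A trait vector is constant across tips."""


class LabelAlignmentError(PhylosongError):
    """Two labelled objects do not share the same label set."""

    def __init__(self, message, missing=(), extra=()):
        super().__init__(message)
        self.missing = tuple(missing)
        self.extra = tuple(extra)


class InvalidTreeError(PhylosongError):
    """A tree violates a structural requirement (missing lengths, unrooted...)."""


class UndefinedDistanceError(PhylosongError):
    """A pairwise distance cannot be computed (e.g. zero comparable sites)."""


class UnidentifiableError(PhylosongError):
    """A model parameter is not identifiable on the given input (star tree)."""
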