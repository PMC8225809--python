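"""Exception hierarchy for the spherotrack pipeline."""


class SpherotrackError(Exception):
    """Base class for all package-specific errors."""


class ImageInputError(SpherotrackError):
    """A file could not be read or decoded as an image."""


class ImageFormatError(SpherotrackError):
    """An image decoded, but not into the expected RGB(A) layout."""


class LayoutError(SpherotrackError):
    """An experiment layout is inconsistent with the files on disk."""


class DegenerateInputError(SpherotrackError):
    """An input is too degenerate for the requested operation."""


class NoForegroundError(SpherotrackError):
    """A mask operation that needs foreground pixels received an empty mask."""


class NormalisationError(SpherotrackError):
    """Area normalisation against a zero or missing reference."""


class BorderPixelError(SpherotrackError):
    """A neighbourhood query at a pixel whose window leaves the image."""


class RoleAssignmentError(SpherotrackError):
    """The centroid-to-role rule failed to produce a bijection."""
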