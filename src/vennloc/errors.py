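"""Exception hierarchy.

Every error raised by the package derives from :class:`VennlocError` so callers
can catch the library's failures without catching unrelated ones.
"""


class VennlocError(Exception):
    """Base class for all vennloc errors."""


class ParameterError(VennlocError, ValueError):
    """An invalid configuration or function parameter; the message names the field."""


class StackIOError(VennlocError, IOError):
    """Reading or writing image stacks failed (missing file, shape or plane-count mismatch)."""


class DegenerateThresholdError(VennlocError, ValueError):
    """Automatic thresholding cannot separate a constant-intensity plane.

    Raised by Otsu on a plane with a single intensity value; the message
    suggests switching to a fixed threshold.
    """


class RegionError(VennlocError, ValueError):
    """A region specification is inconsistent with the available channels."""
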