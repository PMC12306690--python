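"""Exception hierarchy for retvasc.

All domain errors derive from :class:`RetvascError` so callers can catch the
package's failures with a single except clause while letting programming
errors (TypeError etc.) propagate.
"""


class RetvascError(Exception):
    """Base class for all retvasc domain errors."""


class NoFundusDetected(RetvascError):
    """No candidate field-of-view region large enough was found in the image."""


class DegenerateBounds(RetvascError):
    """The bounded field-of-view region collapses to zero area."""


class InvalidLabel(RetvascError):
    """An artery/vein label raster contains values outside {0, 1, 2, 3}."""


class FrameMismatch(RetvascError):
    """Two rasters or points expected in the same frame have different shapes."""


# Alias used by the evaluation interface; identical semantics.
ShapeMismatch = FrameMismatch


class EmptyDisc(RetvascError):
    """Disc mask contains no foreground pixels."""


class EmptyRegion(RetvascError):
    """A region mask used as a denominator contains no pixels."""


class ZeroChord(RetvascError):
    """A segment's endpoints coincide, so arc/chord tortuosity is undefined."""


class EmptyHeatmap(RetvascError):
    """Heatmap raster is empty or all-invalid."""


class OutOfFrame(RetvascError):
    """Keypoint lies outside the raster it is to be encoded into."""


class ArcadeNotFound(RetvascError):
    """No vessel crossing of the arcade sampling circle on one side."""


class NoPoints(RetvascError):
    """No centerline points available in the requested region."""


class LengthMismatch(RetvascError):
    """Paired sequences have different lengths."""


class ConfigInfeasible(RetvascError):
    """Requested synthetic geometry cannot fit in the frame."""


class UnknownMode(RetvascError):
    """Unrecognised degradation mode."""
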