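"""Exception hierarchy for the alpha-shape complexity toolkit."""


class AlphaComplexityError(Exception):
    """Base class for all package errors."""


class InvalidShapeSpec(AlphaComplexityError):
    """A synthetic-shape specification violates its geometric invariants."""


class Unsupported(AlphaComplexityError):
    """Requested quantity has no closed form for this shape kind."""


class EmptyForeground(AlphaComplexityError):
    """A binary volume contains no foreground voxels."""


class InvalidParameter(AlphaComplexityError):
    """A numeric argument is outside its valid range."""


class DegenerateInput(AlphaComplexityError):
    """Point set is too small, coplanar or otherwise untriangulable."""


class NoCrossing(AlphaComplexityError):
    """Raw volume exceeds the convex-hull volume: no alpha shape can match it."""


class InvalidMesh(AlphaComplexityError):
    """Surface mesh is not watertight (or otherwise unusable)."""
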