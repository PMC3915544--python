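"""Exception types raised across the grading pipeline."""


class PomogradeError(Exception):
    """Base class for all package-specific errors."""


class ScaleError(PomogradeError, ValueError):
    """Pixel values or scale tag inconsistent with the declared scale."""


class TransferTagError(PomogradeError, ValueError):
    """Operation applied to an image with the wrong transfer-function tag."""


class ColorDomainError(PomogradeError, ValueError):
    """Colorimetric quantity outside its valid domain (e.g. negative XYZ)."""


class MaskShapeError(PomogradeError, ValueError):
    """Plane / mask shapes do not agree."""


class NoAppleFoundError(PomogradeError, RuntimeError):
    """Segmentation produced an empty mask: no fruit in the frame."""
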