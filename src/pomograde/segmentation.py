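"""Background removal and apple-region extraction.

The fruit sits on a dark, desaturated conveyor background.  Each of three
planes — HSV saturation S, tristimulus Y, and CIELAB a* — is thresholded
with a strict ``value > T`` rule, the per-plane masks are OR-combined (red
regions fire the a* rule, bright yellow regions the Y rule, and both fire
the S rule against the desaturated background), the mask is cleaned of
speckle, and the largest 8-connected component is taken as the apple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .colorspace import PlaneStack
from .errors import MaskShapeError, NoAppleFoundError

__all__ = [
    "ThresholdRule",
    "BinaryMask",
    "AppleRegion",
    "threshold_plane",
    "build_background_mask",
    "clean_mask",
    "extract_apple",
    "write_mask_png",
    "read_mask_png",
]

#: 8-connectivity structuring element, also used for the opening step.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ThresholdRule:
    """Keep pixels whose plane value strictly exceeds ``threshold``."""

    plane: str
    threshold: float
    direction: str = "greater"

    def __post_init__(self) -> None:
        if self.direction != "greater":
            raise ValueError("only direction='greater' rules are supported")

    def describe(self) -> str:
        return f"{self.plane}>{self.threshold:g}"


@dataclass
class BinaryMask:
    """H x W boolean raster with a record of the steps that produced it."""

    pixels: np.ndarray
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            px = px.astype(bool)
        if px.ndim != 2:
            raise MaskShapeError(f"mask must be 2-D, got shape {px.shape}")
        self.pixels = px

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass
class AppleRegion:
    """A single connected component assumed to be the fruit.

    ``bbox`` is (row_min, col_min, row_max, col_max), 0-based and half-open,
    so bbox height = row_max - row_min and width = col_max - col_min.
    """

    mask: BinaryMask
    bbox: Tuple[int, int, int, int]
    area_px: int

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise NoAppleFoundError("apple region has zero area")

    @property
    def height_px(self) -> int:
        return self.bbox[2] - self.bbox[0]

    @property
    def width_px(self) -> int:
        return self.bbox[3] - self.bbox[1]


def threshold_plane(plane: np.ndarray, rule: ThresholdRule) -> BinaryMask:
    """Binary mask of pixels whose value strictly exceeds the rule threshold."""
    plane = np.asarray(plane, dtype=float)
    if np.isnan(plane).any():
        raise ValueError(f"plane {rule.plane!r} contains NaN")
    return BinaryMask(plane > rule.threshold, provenance=[rule.describe()])


def build_background_mask(stack: PlaneStack,
                          rules: Sequence[ThresholdRule]) -> BinaryMask:
    """OR-combine per-plane threshold masks into one foreground mask."""
    if not rules:
        raise ValueError("at least one threshold rule is required")
    combined = np.zeros(stack.shape, dtype=bool)
    provenance: List[str] = []
    for rule in rules:
        if rule.plane not in stack:
            raise KeyError(f"plane {rule.plane!r} not present in the stack")
        part = threshold_plane(stack[rule.plane], rule)
        combined |= part.pixels
        provenance.extend(part.provenance)
    return BinaryMask(combined, provenance=provenance + ["union"])


def clean_mask(mask: BinaryMask, min_area_px: int = 64,
               fill_holes: bool = True, open_radius: int = 1) -> BinaryMask:
    """Remove segmentation speckle.  Idempotent.

    Applies, in order: a binary opening with a (2r+1) square element
    (``open_radius=0`` disables it) that detaches and erases thin noise
    chains; removal of 8-connected components below ``min_area_px``; and
    hole filling.  The opening also suppresses background speckle touching
    the fruit outline, which would otherwise stretch its bounding box.
    """
    px = mask.pixels
    steps: List[str] = []
    if open_radius > 0:
        se = np.ones((2 * open_radius + 1,) * 2, dtype=bool)
        px = ndimage.binary_opening(px, structure=se)
        steps.append(f"open(r={open_radius})")
    if min_area_px > 0:
        labels, n = ndimage.label(px, structure=_STRUCT8)
        if n:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                       index=np.arange(1, n + 1))
            keep = 1 + np.flatnonzero(sizes >= min_area_px)
            px = np.isin(labels, keep)
        steps.append(f"min_area({min_area_px})")
    if fill_holes:
        px = ndimage.binary_fill_holes(px)
        steps.append("fill_holes")
    return BinaryMask(px, provenance=mask.provenance + steps)


def extract_apple(mask: BinaryMask) -> AppleRegion:
    """Largest 8-connected component with its tight bounding box.

    Ties in component area resolve to the component whose first pixel comes
    earliest in row-major scan order (the lowest label, since labels are
    assigned in scan order).
    """
    labels, n = ndimage.label(mask.pixels, structure=_STRUCT8)
    if n == 0:
        raise NoAppleFoundError("mask is empty: no apple found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    best = 1 + int(np.argmax(sizes))  # argmax keeps the first (lowest) label
    component = labels == best
    rows = np.flatnonzero(component.any(axis=1))
    cols = np.flatnonzero(component.any(axis=0))
    bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
    region_mask = BinaryMask(component,
                             provenance=mask.provenance + ["largest_component"])
    return AppleRegion(mask=region_mask, bbox=bbox, area_px=int(sizes[best - 1]))


def write_mask_png(mask: BinaryMask, path) -> None:
    """Write a mask as a single-channel 0/255 PNG."""
    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))


def read_mask_png(path) -> BinaryMask:
    """Read a 0/255 single-channel PNG back into a mask."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(arr > 127, provenance=[f"read({path})"])
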