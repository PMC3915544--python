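"""Color and size grading of a single segmented apple.

Red surface pixels are those with CIELAB a* above a threshold (a* spans
green to red/magenta; the default 15 excludes both the yellow flesh tones,
a* ~ -5, and the background).  Yellow pixels are the bright ones: Y above a
threshold after normalizing the tristimulus Y plane by its maximum inside
the fruit (``y_norm="apple_max"``; set ``"none"`` to threshold raw unit Y).
Variety follows from the red/yellow area fractions — Golden carries no red,
Starking is predominantly red with no yellow, Jonagold mixes both — and the
commercial grade is the (color group, size class) pair.  Physical size
comes from the bounding-box extents times the pixel calibration length.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from . import colorspace as cs
from . import segmentation as seg
from .errors import MaskShapeError, NoAppleFoundError

__all__ = [
    "GradingConfig",
    "GradeRecord",
    "default_rules",
    "red_region_mask",
    "yellow_region_mask",
    "classify_variety",
    "classify_color_group",
    "measure_size",
    "classify_size",
    "grade_image",
]

VARIETIES = ("Golden", "Starking", "Jonagold")
COLOR_GROUPS = ("red", "yellow")
SIZE_CLASSES = ("regular", "large")


@dataclass(frozen=True)
class GradingConfig:
    """Thresholds and calibration constants for the whole pipeline.

    Attributes
    ----------
    a_star_threshold : CIELAB a* units; red pixels satisfy a* > this.
    y_threshold : normalized Y units; yellow pixels satisfy Y > this.
    y_norm : "apple_max" divides the Y plane by its maximum inside the
        fruit before thresholding; "none" uses raw unit-scale Y.
    s_threshold : HSV saturation threshold for background removal.
    saturation_mode : "hsi" or "hexcone" S convention for segmentation.
    pixel_length_mm : physical length of one pixel on the conveyor.
    size_cutoff_mm : fruit whose larger extent reaches this are "large".
    red_presence_min : red area fraction below which no red is deemed
        present (Golden); also the yellow-absence cutoff for Starking.
    starking_red_min : minimum red fraction for Starking.
    min_area_px, fill_holes, open_radius : mask cleanup (see clean_mask).
    cone_model : chromatic-adaptation cone model name.
    input_transfer : "linear" for raw camera frames (default: the rig's
        sensor is linear), "srgb" for gamma-encoded images.
    """

    a_star_threshold: float = 15.0
    y_threshold: float = 0.5
    y_norm: str = "apple_max"
    s_threshold: float = 0.5
    saturation_mode: str = "hsi"
    pixel_length_mm: float = 0.312
    size_cutoff_mm: float = 75.0
    red_presence_min: float = 0.01
    starking_red_min: float = 0.50
    min_area_px: int = 64
    fill_holes: bool = True
    open_radius: int = 1
    cone_model: str = "von-kries"
    input_transfer: str = "linear"

    def __post_init__(self) -> None:
        if self.pixel_length_mm <= 0:
            raise ValueError("pixel_length_mm must be > 0")
        for name in ("a_star_threshold", "y_threshold", "s_threshold",
                     "size_cutoff_mm", "red_presence_min", "starking_red_min"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.y_norm not in ("apple_max", "none"):
            raise ValueError(f"unknown y_norm {self.y_norm!r}")
        if self.cone_model not in cs.CONE_MODELS:
            raise ValueError(f"unknown cone model {self.cone_model!r}")

    def replace(self, **kwargs) -> "GradingConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "GradingConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class GradeRecord:
    """Per-apple grading result."""

    variety: str
    color_group: str
    size_class: str
    width_mm: float
    height_mm: float
    red_fraction: float
    yellow_fraction: float

    def __post_init__(self) -> None:
        if self.variety not in VARIETIES:
            raise ValueError(f"unknown variety {self.variety!r}")
        if self.color_group not in COLOR_GROUPS:
            raise ValueError(f"unknown color group {self.color_group!r}")
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {self.size_class!r}")
        if not (0 <= self.red_fraction <= 1 and 0 <= self.yellow_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("physical extents must be positive")

    @property
    def group(self) -> str:
        """The commercial group label, e.g. ``"red/large"``."""
        return f"{self.color_group}/{self.size_class}"


def default_rules(cfg: GradingConfig) -> Tuple[seg.ThresholdRule, ...]:
    """The three background-removal rules: S, Y and a* planes."""
    return (
        seg.ThresholdRule("S", cfg.s_threshold),
        seg.ThresholdRule("Y", cfg.y_threshold),
        seg.ThresholdRule("a", cfg.a_star_threshold),
    )


def _masked_rule(plane: np.ndarray, apple: seg.AppleRegion,
                 threshold: float, label: str) -> seg.BinaryMask:
    plane = np.asarray(plane, dtype=float)
    if plane.shape != apple.mask.shape:
        raise MaskShapeError(
            f"plane shape {plane.shape} != mask shape {apple.mask.shape}")
    return seg.BinaryMask((plane > threshold) & apple.mask.pixels,
                          provenance=[label, "inside_apple"])


def red_region_mask(a_plane: np.ndarray, apple: seg.AppleRegion,
                    cfg: GradingConfig) -> seg.BinaryMask:
    """Pixels with a* strictly above the red threshold, inside the fruit."""
    return _masked_rule(a_plane, apple, cfg.a_star_threshold,
                        f"a>{cfg.a_star_threshold:g}")


def yellow_region_mask(y_plane: np.ndarray, apple: seg.AppleRegion,
                       cfg: GradingConfig) -> seg.BinaryMask:
    """Pixels with (normalized) Y strictly above the yellow threshold, inside the fruit."""
    return _masked_rule(y_plane, apple, cfg.y_threshold,
                        f"Y>{cfg.y_threshold:g}")


def classify_variety(red_fraction: float, yellow_fraction: float,
                     cfg: GradingConfig = GradingConfig()) -> str:
    """Variety from the red/yellow surface fractions.

    No red present -> Golden; predominantly red with no yellow -> Starking;
    anything mixing the two -> Jonagold.
    """
    if red_fraction < cfg.red_presence_min:
        return "Golden"
    if red_fraction >= cfg.starking_red_min and yellow_fraction < cfg.red_presence_min:
        return "Starking"
    return "Jonagold"


def classify_color_group(red_fraction: float, yellow_fraction: float) -> str:
    """Commercial color group; ties resolve to red."""
    return "red" if red_fraction >= yellow_fraction else "yellow"


def measure_size(apple: seg.AppleRegion,
                 cfg: GradingConfig = GradingConfig()) -> Tuple[float, float]:
    """Bounding-box extents in millimetres: (width_mm, height_mm)."""
    if apple.width_px <= 0 or apple.height_px <= 0:
        raise ValueError("degenerate bounding box")
    return (apple.width_px * cfg.pixel_length_mm,
            apple.height_px * cfg.pixel_length_mm)


def classify_size(width_mm: float, height_mm: float,
                  cfg: GradingConfig = GradingConfig()) -> str:
    """"large" when the larger extent reaches the cutoff (inclusive)."""
    return "large" if max(width_mm, height_mm) >= cfg.size_cutoff_mm else "regular"


def grade_image(image: cs.ColorImage,
                cfg: GradingConfig = GradingConfig(),
                return_details: bool = False):
    """Run the full pipeline on one frame.

    Converts the frame to the S, Y and a* planes, removes the background,
    cleans the mask, extracts the largest component, quantifies the red and
    yellow regions and returns a :class:`GradeRecord` (plus a details dict
    with the region, masks and planes when ``return_details`` is true).

    Raises :class:`NoAppleFoundError` when segmentation finds nothing.
    """
    if image.scale == "8bit":
        image = cs.ColorImage(image.pixels, scale="8bit",
                              transfer=cfg.input_transfer)
    stack = cs.compute_planes(image,
                              cone_model=cs.CONE_MODELS[cfg.cone_model],
                              saturation=cfg.saturation_mode,
                              names=("S", "Y", "a"))
    fg = seg.build_background_mask(stack, default_rules(cfg))
    fg = seg.clean_mask(fg, min_area_px=cfg.min_area_px,
                        fill_holes=cfg.fill_holes, open_radius=cfg.open_radius)
    apple = seg.extract_apple(fg)

    y_plane = stack["Y"]
    if cfg.y_norm == "apple_max":
        peak = float(y_plane[apple.mask.pixels].max())
        if peak > 0:
            y_plane = y_plane / peak
    red = red_region_mask(stack["a"], apple, cfg)
    yellow = yellow_region_mask(y_plane, apple, cfg)
    red_fraction = red.area_px / apple.area_px
    yellow_fraction = yellow.area_px / apple.area_px

    width_mm, height_mm = measure_size(apple, cfg)
    record = GradeRecord(
        variety=classify_variety(red_fraction, yellow_fraction, cfg),
        color_group=classify_color_group(red_fraction, yellow_fraction),
        size_class=classify_size(width_mm, height_mm, cfg),
        width_mm=width_mm,
        height_mm=height_mm,
        red_fraction=red_fraction,
        yellow_fraction=yellow_fraction,
    )
    if return_details:
        return record, {"apple": apple, "red_mask": red, "yellow_mask": yellow,
                        "planes": stack, "foreground": fg}
    return record
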