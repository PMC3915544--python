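"""Labeled synthetic apple scenes for end-to-end testing without a camera.

Each scene is an elliptical fruit on a dark bluish conveyor background.
The fruit surface is tiled with red and yellow blotches (nearest-seed
Voronoi cells of random interior points) at requested area fractions, and
every pixel's RGB is drawn from a per-class Gaussian — mean and standard
deviation measured, per class, from real conveyor frames of red and yellow
apples under the D55-like fluorescent lamps:

    class        R              G              B
    red          0.099 +- 0.040 0.009 +- 0.004 0.010 +- 0.004
    yellow       0.347 +- 0.128 0.288 +- 0.108 0.010 +- 0.004
    background   0.013 +- 0.004 0.011 +- 0.003 0.023 +- 0.006

Values are unit-scale linear camera RGB; draws are clipped to [0, 1] and
quantized to 8 bits.  Channels within a pixel share a common shading
factor (correlation 0.99 by default): on a curved glossy fruit the
per-pixel scatter is dominated by illumination/shading, which moves R, G
and B together.  Independent channel draws at these standard deviations
would scatter the hue far more than real frames do (e.g. yellow-class
CIELAB a* spread ~19 instead of the measured ~2.8) and are not what the
class measurements describe.  The generator reproduces the statistical
structure
those measurements imply (dark desaturated background, saturated red
regions with large positive a*, bright yellow regions with large b* and
negative a*) but not photometric realism: no specular highlights, shading
gradient, stem/calyx, or motion blur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .colorspace import ColorImage
from .grading import GradeRecord, GradingConfig, classify_color_group
from .segmentation import BinaryMask

__all__ = [
    "CLASS_COLOR_STATS",
    "GROUPS",
    "SceneSpec",
    "LabeledScene",
    "generate_scene",
    "generate_batch",
    "write_batch",
]

#: Per-class (mean, standard deviation) of unit-scale RGB.
CLASS_COLOR_STATS: Dict[str, Tuple[Tuple[float, float, float],
                                   Tuple[float, float, float]]] = {
    "red": ((0.099, 0.009, 0.010), (0.040, 0.004, 0.004)),
    "yellow": ((0.347, 0.288, 0.010), (0.128, 0.108, 0.004)),
    "background": ((0.013, 0.011, 0.023), (0.004, 0.003, 0.006)),
}

#: Within-pixel correlation between channel fluctuations (shared shading).
CHANNEL_CORRELATION = 0.99

#: The four commercial groups, in reporting order.
GROUPS = ("red/regular", "red/large", "yellow/regular", "yellow/large")

#: Default per-size-class diameter ranges (mm), clear of the 75 mm cutoff.
DEFAULT_SIZE_RANGES_MM: Dict[str, Tuple[float, float]] = {
    "regular": (60.0, 70.0),
    "large": (80.0, 90.0),
}

_N_PATCHES = 12  # Voronoi seeds per fruit


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene.

    ``apple_axes`` is (semi-height, semi-width) in pixels.  A Golden fruit
    must have ``red_patch_fraction == 0`` (the variety has no red surface).
    """

    image_size: Tuple[int, int]
    apple_center: Tuple[float, float]
    apple_axes: Tuple[float, float]
    variety: str
    red_patch_fraction: float
    yellow_patch_fraction: float
    seed: int
    class_color_stats: Mapping = field(default_factory=lambda: CLASS_COLOR_STATS)
    channel_correlation: float = CHANNEL_CORRELATION
    pixel_length_mm: float = 0.312

    def __post_init__(self) -> None:
        h, w = self.image_size
        cy, cx = self.apple_center
        ay, ax = self.apple_axes
        if ay <= 0 or ax <= 0:
            raise ValueError("apple axes must be positive")
        if not (cy - ay >= 0 and cy + ay <= h - 1 and cx - ax >= 0
                and cx + ax <= w - 1):
            raise ValueError("apple does not fit inside the frame")
        for f in (self.red_patch_fraction, self.yellow_patch_fraction):
            if not 0 <= f <= 1:
                raise ValueError("patch fractions must lie in [0, 1]")
        if not 0 <= self.channel_correlation <= 1:
            raise ValueError("channel_correlation must lie in [0, 1]")
        if self.variety == "Golden" and self.red_patch_fraction != 0:
            raise ValueError("a Golden apple has no red surface region")


@dataclass
class LabeledScene:
    """A rendered scene with its ground truth."""

    image: ColorImage
    truth_mask: BinaryMask
    truth_record: GradeRecord
    spec: SceneSpec


def _voronoi_red_assignment(points: np.ndarray, target_fraction: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Boolean per-pixel flag marking red blotches covering ~target_fraction."""
    if target_fraction <= 0:
        return np.zeros(len(points), dtype=bool)
    if target_fraction >= 1:
        return np.ones(len(points), dtype=bool)
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    seeds = rng.uniform(lo, hi, size=(_N_PATCHES, 2))
    d2 = ((points[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=-1)
    nearest = d2.argmin(axis=1)
    cell_area = np.bincount(nearest, minlength=_N_PATCHES)
    # Greedily accumulate shuffled cells until the red target is reached.
    red_cells: List[int] = []
    covered = 0
    for cell in rng.permutation(_N_PATCHES):
        if covered >= target_fraction * len(points):
            break
        red_cells.append(int(cell))
        covered += int(cell_area[cell])
    return np.isin(nearest, red_cells)


def _draw_class(rng: np.random.Generator, mean, sd, n: int,
                rho: float) -> np.ndarray:
    """n Gaussian RGB draws with per-channel (mean, sd) and a shared
    shading component giving within-pixel channel correlation rho."""
    shared = rng.standard_normal((n, 1))
    resid = rng.standard_normal((n, 3))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * resid
    return np.asarray(mean) + np.asarray(sd) * z


def generate_scene(spec: SceneSpec,
                   cfg: GradingConfig = GradingConfig()) -> LabeledScene:
    """Render one scene; bit-identical for identical spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    cy, cx = spec.apple_center
    ay, ax = spec.apple_axes
    yy, xx = np.mgrid[0:h, 0:w]
    inside = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    stats = spec.class_color_stats
    rho = spec.channel_correlation
    mean, sd = stats["background"]
    img = _draw_class(rng, mean, sd, h * w, rho).reshape(h, w, 3)

    pts = np.argwhere(inside)
    red_flag = _voronoi_red_assignment(pts, spec.red_patch_fraction, rng)
    red_mask = np.zeros((h, w), dtype=bool)
    red_mask[pts[:, 0], pts[:, 1]] = red_flag
    for cls, m in (("red", inside & red_mask), ("yellow", inside & ~red_mask)):
        n = int(m.sum())
        if n:
            mean, sd = stats[cls]
            img[m] = _draw_class(rng, mean, sd, n, rho)
    img8 = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)

    area = int(inside.sum())
    red_fraction = float((inside & red_mask).sum()) / area
    yellow_fraction = 1.0 - red_fraction
    rows = np.flatnonzero(inside.any(axis=1))
    cols = np.flatnonzero(inside.any(axis=0))
    height_mm = (rows[-1] - rows[0] + 1) * spec.pixel_length_mm
    width_mm = (cols[-1] - cols[0] + 1) * spec.pixel_length_mm
    record = GradeRecord(
        variety=spec.variety,
        color_group=classify_color_group(red_fraction, yellow_fraction),
        size_class=("large" if max(width_mm, height_mm) >= cfg.size_cutoff_mm
                    else "regular"),
        width_mm=width_mm,
        height_mm=height_mm,
        red_fraction=red_fraction,
        yellow_fraction=yellow_fraction,
    )
    image = ColorImage(img8, scale="8bit", transfer="linear")
    return LabeledScene(image=image,
                        truth_mask=BinaryMask(inside, provenance=["ellipse"]),
                        truth_record=record, spec=spec)


def _apportion(n: int, proportions: Sequence[float]) -> List[int]:
    """Largest-remainder apportionment of n among the groups."""
    raw = np.asarray(proportions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts.tolist()


def generate_batch(n: int,
                   group_mix: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                   size_ranges_mm: Optional[Mapping[str, Tuple[float, float]]] = None,
                   seed: int = 0,
                   cfg: GradingConfig = GradingConfig(),
                   margin_px: int = 12) -> List[LabeledScene]:
    """Render ``n`` labeled scenes spanning the four commercial groups.

    ``group_mix`` gives the proportions of red/regular, red/large,
    yellow/regular, yellow/large (the order of :data:`GROUPS`); group
    counts follow by largest-remainder rounding.  Per-group fruit
    diameters are drawn uniformly from ``size_ranges_mm`` and converted to
    pixel axes with ``cfg.pixel_length_mm``.  Yellow-group fruit are
    Golden; red-group fruit alternate Starking (fully red) and Jonagold
    (65-85 % red blotches).  Frames are sized to the fruit plus
    ``margin_px`` on each side.
    """
    if n <= 0:
        raise ValueError("batch size must be positive")
    mix = np.asarray(group_mix, dtype=float)
    if mix.shape != (4,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("group_mix must be four non-negative proportions summing to 1")
    ranges = dict(DEFAULT_SIZE_RANGES_MM)
    if size_ranges_mm:
        ranges.update(size_ranges_mm)

    counts = _apportion(n, mix)
    master = np.random.default_rng(seed)
    scenes: List[LabeledScene] = []
    red_rank = 0
    for group, count in zip(GROUPS, counts):
        color, size_class = group.split("/")
        lo, hi = ranges[size_class]
        for _ in range(count):
            d_mm = master.uniform(lo, hi)
            # mild eccentricity: height within +-4 % of width
            ecc = master.uniform(0.96, 1.04)
            ax = d_mm / cfg.pixel_length_mm / 2.0
            ay = ax * ecc
            if color == "red":
                if red_rank % 2 == 0:
                    variety, red_frac = "Starking", 1.0
                else:
                    variety, red_frac = "Jonagold", float(master.uniform(0.65, 0.85))
                red_rank += 1
            else:
                variety, red_frac = "Golden", 0.0
            h = int(np.ceil(2 * ay)) + 2 * margin_px
            w = int(np.ceil(2 * ax)) + 2 * margin_px
            spec = SceneSpec(
                image_size=(h, w),
                apple_center=(h / 2.0, w / 2.0),
                apple_axes=(ay, ax),
                variety=variety,
                red_patch_fraction=red_frac,
                yellow_patch_fraction=1.0 - red_frac,
                seed=int(master.integers(0, 2**31 - 1)),
                pixel_length_mm=cfg.pixel_length_mm,
            )
            scene = generate_scene(spec, cfg)
            # the requested group is the ground truth by construction
            assert scene.truth_record.group == group, (
                scene.truth_record.group, group)
            scenes.append(scene)
    return scenes


def write_batch(scenes: Sequence[LabeledScene], outdir) -> Path:
    """Write scenes as PNGs plus a ground-truth CSV; returns the CSV path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, scene in enumerate(scenes):
        name = f"scene_{i:04d}.png"
        iio.imwrite(outdir / name, scene.image.pixels)
        r = scene.truth_record
        rows.append({
            "file": name, "variety": r.variety, "color_group": r.color_group,
            "size_class": r.size_class, "width_mm": r.width_mm,
            "height_mm": r.height_mm, "red_fraction": r.red_fraction,
            "yellow_fraction": r.yellow_fraction,
        })
    csv_path = outdir / "truth.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path
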