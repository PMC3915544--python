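"""Color space conversions for the grading pipeline.

The chain implemented here takes 8-bit camera RGB to the device-independent
planes the segmentation and grading stages threshold:

    8-bit RGB --/255--> unit RGB --(optional sRGB linearization)-->
    linear RGB --M_sRGB--> XYZ under D65 --von Kries--> XYZ under D55
    --CIELAB--> L*, a*, b* with the D55 reference white

plus an HSV decomposition of the unit RGB.  The conveyor rig is lit by
fluorescent lamps with a correlated color temperature of ~5300 K
(approximately CIE D55), while the published RGB->XYZ matrix is defined for
D65; the von Kries chromatic adaptation bridges the two illuminants by
scaling cone responses independently.

Camera sensors respond linearly to radiance, so frames straight from the
rig carry ``transfer="linear"`` and skip the sRGB gamma step; images saved
through a normal sRGB pipeline should be tagged ``transfer="srgb"`` so the
IEC 61966-2-1 linearization is applied first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
from skimage import color as _skcolor

from .errors import ColorDomainError, MaskShapeError, ScaleError, TransferTagError

__all__ = [
    "ColorImage",
    "WhitePoint",
    "ConeModel",
    "AdaptationMatrix",
    "PlaneStack",
    "SRGB_TO_XYZ_D65",
    "D65_WHITE",
    "D55_WHITE",
    "VON_KRIES_CONES",
    "BRADFORD_CONES",
    "CONE_MODELS",
    "normalize_rgb",
    "srgb_linearize",
    "rgb_to_hsv",
    "linear_rgb_to_xyz_d65",
    "von_kries_matrix",
    "adapt_xyz",
    "xyz_to_lab",
    "rgb_to_lab_d55",
    "compute_planes",
]

# sRGB (reference white D65) -> CIE XYZ, 2-degree observer.
SRGB_TO_XYZ_D65 = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: Threshold/slope of the IEC 61966-2-1 piecewise transfer function.
_SRGB_KNEE = 0.04045
_SRGB_SLOPE = 12.92

#: CIELAB branch point and linear-branch slope.
_LAB_EPS = 0.008856
_LAB_SLOPE = 7.787


@dataclass(frozen=True)
class WhitePoint:
    """Illuminant tristimulus values with luminance normalized to 1."""

    X: float
    Y: float
    Z: float

    def __post_init__(self) -> None:
        if not (self.X > 0 and self.Y > 0 and self.Z > 0):
            raise ColorDomainError(f"white point components must be > 0, got {self}")
        if abs(self.Y - 1.0) > 1e-9:
            raise ColorDomainError(f"white point must have Y = 1.0, got Y={self.Y}")

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z], dtype=float)


#: D65 white implied by the column sums of ``SRGB_TO_XYZ_D65``.
D65_WHITE = WhitePoint(0.95047, 1.00000, 1.08883)
#: D55 white (2-degree observer), the rig's lamp illuminant.
D55_WHITE = WhitePoint(0.95682, 1.00000, 0.92149)


@dataclass(frozen=True)
class ConeModel:
    """A 3x3 matrix mapping XYZ to an LMS-like cone response (rho, gamma, beta)."""

    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("cone matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise np.linalg.LinAlgError(f"cone matrix {self.name!r} is singular")
        object.__setattr__(self, "matrix", m)


#: Classic von Kries cone matrix (Hunt--Pointer--Estevez, D65-normalized).
VON_KRIES_CONES = ConeModel(
    "von-kries",
    np.array(
        [
            [0.40024, 0.70760, -0.08081],
            [-0.22630, 1.16532, 0.04570],
            [0.00000, 0.00000, 0.91822],
        ]
    ),
)

#: Bradford sharpened cone matrix, selectable alternative.
BRADFORD_CONES = ConeModel(
    "bradford",
    np.array(
        [
            [0.8951, 0.2664, -0.1614],
            [-0.7502, 1.7135, 0.0367],
            [0.0389, -0.0685, 1.0296],
        ]
    ),
)

CONE_MODELS: Dict[str, ConeModel] = {
    VON_KRIES_CONES.name: VON_KRIES_CONES,
    BRADFORD_CONES.name: BRADFORD_CONES,
}


@dataclass(frozen=True)
class AdaptationMatrix:
    """Chromatic adaptation matrix with the whites and cone model it was built from.

    Invariant: ``matrix @ source.as_array() == destination.as_array()`` within
    5e-4 componentwise (checked at construction).
    """

    matrix: np.ndarray
    source: WhitePoint
    destination: WhitePoint
    cone_model: ConeModel

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        mapped = m @ self.source.as_array()
        if np.max(np.abs(mapped - self.destination.as_array())) > 5e-4:
            raise ColorDomainError(
                "adaptation matrix does not carry the source white to the "
                f"destination white: got {mapped}"
            )


@dataclass
class ColorImage:
    """An H x W x 3 raster with a declared value scale and transfer function.

    Parameters
    ----------
    pixels
        The raster.  ``scale="8bit"`` means integer values in [0, 255];
        ``scale="unit"`` means floating values in [0, 1].
    scale
        ``"8bit"`` or ``"unit"``.
    transfer
        ``"srgb"`` for gamma-encoded values, ``"linear"`` for values
        proportional to radiance (raw camera output).
    """

    pixels: np.ndarray
    scale: str = "8bit"
    transfer: str = "srgb"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected an H x W x 3 raster, got shape {px.shape}")
        if self.scale == "8bit":
            if px.min() < 0 or px.max() > 255:
                raise ScaleError("8-bit image has values outside [0, 255]")
        elif self.scale == "unit":
            px = px.astype(float, copy=False)
            if px.min() < 0 or px.max() > 1:
                raise ScaleError("unit-scale image has values outside [0, 1]")
        else:
            raise ScaleError(f"unknown scale {self.scale!r}")
        if self.transfer not in ("srgb", "linear"):
            raise TransferTagError(f"unknown transfer tag {self.transfer!r}")
        self.pixels = px

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class PlaneStack:
    """Named single-channel planes derived from one image.

    Plane names are drawn from {H, S, V, X, Y, Z, L, a, b}.  S and V lie in
    [0, 1] and H in [0, 1) (fraction of a turn, red at 0).  ``white`` is the
    reference white used for the L, a, b planes.
    """

    planes: Dict[str, np.ndarray]
    white: Optional[WhitePoint] = None

    _ALLOWED = frozenset("HSVXYZLab")

    def __post_init__(self) -> None:
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) > 1:
            raise MaskShapeError(f"planes disagree in shape: {shapes}")
        unknown = set(self.planes) - self._ALLOWED
        if unknown:
            raise ValueError(f"unknown plane names {sorted(unknown)}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.planes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.planes

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.planes.values())).shape


# ---------------------------------------------------------------------------
# scalar transfer helpers (vectorized below)
# ---------------------------------------------------------------------------

def _linearize(channel: np.ndarray) -> np.ndarray:
    c = np.asarray(channel, dtype=float)
    return np.where(c <= _SRGB_KNEE, c / _SRGB_SLOPE, ((c + 0.055) / 1.055) ** 2.4)


def _lab_f(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.where(q > _LAB_EPS, np.cbrt(q), _LAB_SLOPE * q + 16.0 / 116.0)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize_rgb(image: ColorImage) -> ColorImage:
    """Rescale an 8-bit image to unit scale by dividing every channel by 255."""
    if image.scale != "8bit":
        raise ScaleError(f"expected an 8-bit image, got scale={image.scale!r}")
    return ColorImage(image.pixels.astype(float) / 255.0, scale="unit",
                      transfer=image.transfer)


def srgb_linearize(image: ColorImage) -> ColorImage:
    """Undo the IEC 61966-2-1 sRGB gamma on a unit-scale nonlinear image."""
    if image.scale != "unit":
        raise ScaleError("srgb_linearize expects a unit-scale image")
    if image.transfer != "srgb":
        raise TransferTagError("image is already linear")
    return ColorImage(_linearize(image.pixels), scale="unit", transfer="linear")


def rgb_to_hsv(image: ColorImage, saturation: str = "hexcone"
               ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose unit-scale RGB into hue, saturation, value planes.

    ``saturation="hexcone"`` is the convention of the usual ``rgb2hsv``
    routines: S = (max - min) / max (0 for black), V = max.  The
    ``"hsi"`` variant substitutes the HSI-form S = 1 - 3 min/(R+G+B),
    which normalizes by total intensity instead of the peak channel and
    stays low on dark near-neutral backgrounds; hue and value are
    unchanged.  H is a fraction of a turn in [0, 1), red at 0.
    """
    if image.scale != "unit":
        raise ScaleError("rgb_to_hsv expects a unit-scale image")
    hsv = _skcolor.rgb2hsv(image.pixels)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    h = np.where(h >= 1.0, 0.0, h)  # keep the half-open [0, 1) convention
    if saturation == "hexcone":
        pass
    elif saturation == "hsi":
        total = image.pixels.sum(axis=-1)
        mn = image.pixels.min(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(total > 0, 1.0 - 3.0 * mn / total, 0.0)
    else:
        raise ValueError(f"unknown saturation convention {saturation!r}")
    return h, s, v


def linear_rgb_to_xyz_d65(image: ColorImage
                          ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the sRGB-to-XYZ matrix (reference white D65) per pixel."""
    if image.transfer != "linear":
        raise TransferTagError("linear_rgb_to_xyz_d65 expects linear RGB")
    xyz = image.pixels.astype(float) @ SRGB_TO_XYZ_D65.T
    return xyz[..., 0], xyz[..., 1], xyz[..., 2]


def von_kries_matrix(source: WhitePoint, destination: WhitePoint,
                     cone_model: ConeModel = VON_KRIES_CONES) -> AdaptationMatrix:
    """Build the chromatic adaptation matrix between two illuminants.

    Following the von Kries hypothesis, both whites are carried into the
    cone response domain by ``cone_model``, each cone channel is scaled by
    the ratio of destination to source response, and the result is carried
    back:

        M = M_A^-1 . diag(rho_D/rho_S, gamma_D/gamma_S, beta_D/beta_S) . M_A
    """
    m_a = cone_model.matrix
    cones_src = m_a @ source.as_array()
    cones_dst = m_a @ destination.as_array()
    if np.any(cones_src == 0):
        raise ColorDomainError("source white has a zero cone response")
    gain = np.diag(cones_dst / cones_src)
    m = np.linalg.solve(m_a, gain @ m_a)
    return AdaptationMatrix(m, source=source, destination=destination,
                            cone_model=cone_model)


def adapt_xyz(x: np.ndarray, y: np.ndarray, z: np.ndarray,
              adaptation: AdaptationMatrix
              ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply a chromatic adaptation matrix to X, Y, Z planes per pixel."""
    x, y, z = (np.asarray(p, dtype=float) for p in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise MaskShapeError("X, Y, Z planes must share one shape")
    xyz = np.stack([x, y, z], axis=-1) @ adaptation.matrix.T
    return xyz[..., 0], xyz[..., 1], xyz[..., 2]


def xyz_to_lab(x: np.ndarray, y: np.ndarray, z: np.ndarray,
               white: WhitePoint = D55_WHITE
               ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standard CIELAB from tristimulus planes and a reference white.

    L* = 116 f(Y/Yn) - 16, a* = 500 (f(X/Xn) - f(Y/Yn)),
    b* = 200 (f(Y/Yn) - f(Z/Zn)), with f(q) the cube root above
    q = 0.008856 and the 7.787 q + 16/116 linear branch below.
    """
    x, y, z = (np.asarray(p, dtype=float) for p in (x, y, z))
    if min(x.min(), y.min(), z.min()) < 0:
        raise ColorDomainError("tristimulus values must be non-negative")
    fx = _lab_f(x / white.X)
    fy = _lab_f(y / white.Y)
    fz = _lab_f(z / white.Z)
    return 116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)


def rgb_to_lab_d55(image: ColorImage,
                   cone_model: ConeModel = VON_KRIES_CONES) -> PlaneStack:
    """Full chain from 8-bit RGB to CIELAB under the D55 lamp illuminant.

    Normalizes to unit scale, linearizes when the image is tagged
    ``transfer="srgb"`` (linear-tagged camera frames skip the gamma step),
    converts to XYZ under D65, adapts to D55 with the requested cone model,
    and evaluates CIELAB against the D55 white.  The returned stack carries
    the adapted X, Y, Z planes alongside L, a, b.
    """
    unit = normalize_rgb(image) if image.scale == "8bit" else image
    lin = srgb_linearize(unit) if unit.transfer == "srgb" else unit
    x, y, z = linear_rgb_to_xyz_d65(lin)
    adaptation = von_kries_matrix(D65_WHITE, D55_WHITE, cone_model)
    x, y, z = adapt_xyz(x, y, z, adaptation)
    l_, a, b = xyz_to_lab(x, y, z, D55_WHITE)
    return PlaneStack({"X": x, "Y": y, "Z": z, "L": l_, "a": a, "b": b},
                      white=D55_WHITE)


def compute_planes(image: ColorImage,
                   cone_model: ConeModel = VON_KRIES_CONES,
                   saturation: str = "hsi",
                   names: Optional[Iterable[str]] = None) -> PlaneStack:
    """Derive the named planes used by segmentation and grading.

    HSV is computed from the unit-scale values as stored (before any gamma
    handling); X, Y, Z are the D55-adapted tristimulus planes and L, a, b
    the CIELAB planes from :func:`rgb_to_lab_d55`.  ``names=None`` yields
    all nine planes.
    """
    wanted = set(names) if names is not None else set("HSVXYZLab")
    unit = normalize_rgb(image) if image.scale == "8bit" else image
    planes: Dict[str, np.ndarray] = {}
    if wanted & set("HSV"):
        h, s, v = rgb_to_hsv(unit, saturation=saturation)
        planes.update({"H": h, "S": s, "V": v})
    if wanted & set("XYZLab"):
        stack = rgb_to_lab_d55(unit, cone_model=cone_model)
        planes.update(stack.planes)
    return PlaneStack({k: v for k, v in planes.items() if k in wanted},
                      white=D55_WHITE)
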