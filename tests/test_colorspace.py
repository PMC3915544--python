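import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from skimage import color as skcolor

import pomograde as pg
from pomograde.errors import (ColorDomainError, MaskShapeError, ScaleError,
                              TransferTagError)

from _scalar_oracle import scalar_hsv, scalar_lab_d55

# The published D65->D55 adaptation matrix this system is built around.
PUBLISHED_ADAPTATION = np.array([
    [1.0096, 0.0331, -0.0330],
    [0.0036, 0.9973, -0.0007],
    [0.0000, 0.0000, 0.8463],
])


def img(px, scale="unit", transfer="srgb"):
    return pg.ColorImage(np.asarray(px, dtype=float)[None, None, :]
                         if np.ndim(px) == 1 else np.asarray(px),
                         scale=scale, transfer=transfer)


# ---------------------------------------------------------------- normalize

@pytest.mark.parametrize("rgb8,expected", [
    ((255, 255, 255), (1.0, 1.0, 1.0)),
    ((0, 0, 0), (0.0, 0.0, 0.0)),
    ((51, 102, 204), (0.2, 0.4, 0.8)),
])
def test_normalize_divides_by_255(rgb8, expected):
    out = pg.normalize_rgb(img(np.array(rgb8, float), scale="8bit"))
    assert out.scale == "unit"
    np.testing.assert_allclose(out.pixels[0, 0], expected, rtol=0, atol=1e-12)


def test_normalize_rejects_wrong_scale_or_range():
    with pytest.raises(ScaleError):
        pg.normalize_rgb(img((0.5, 0.5, 0.5), scale="unit"))
    with pytest.raises(ScaleError):
        pg.ColorImage(np.full((2, 2, 3), 300.0), scale="8bit")


# ---------------------------------------------------------------- linearize

def test_linearize_fixed_points_and_knee():
    x = img(np.array([[[0.0] * 3, [1.0] * 3, [0.04045] * 3, [0.5] * 3]]))
    out = pg.srgb_linearize(x).pixels[0]
    assert out[0, 0] == 0.0
    assert abs(out[1, 0] - 1.0) < 1e-12
    assert abs(out[2, 0] - 0.04045 / 12.92) < 1e-12
    assert abs(out[3, 0] - ((0.5 + 0.055) / 1.055) ** 2.4) < 1e-12


def test_linearize_monotone_and_continuous():
    grid = np.linspace(0, 1, 2001)
    out = pg.srgb_linearize(img(np.tile(grid[:, None, None], (1, 1, 3)))).pixels
    assert np.all(np.diff(out[:, 0, 0]) >= 0)
    eps = 1e-8
    below = pg.srgb_linearize(img((0.04045 - eps,) * 3)).pixels[0, 0, 0]
    above = pg.srgb_linearize(img((0.04045 + eps,) * 3)).pixels[0, 0, 0]
    assert abs(above - below) < 1e-6


def test_linearize_rejects_already_linear():
    with pytest.raises(TransferTagError):
        pg.srgb_linearize(img((0.5, 0.5, 0.5), transfer="linear"))


# ---------------------------------------------------------------- HSV

@pytest.mark.parametrize("rgb,h,s,v", [
    ((1.0, 0.0, 0.0), 0.0, 1.0, 1.0),
    ((0.5, 0.5, 0.5), None, 0.0, 0.5),
    ((0.0, 1.0, 0.0), 1 / 3, 1.0, 1.0),
])
def test_hsv_hexcone_examples(rgb, h, s, v):
    H, S, V = pg.rgb_to_hsv(img(rgb))
    if h is not None:
        assert abs(H[0, 0] - h) < 1e-12
    assert abs(S[0, 0] - s) < 1e-12 and abs(V[0, 0] - v) < 1e-12


def test_hsv_matches_scalar_oracle(rng):
    px = rng.uniform(0, 1, (8, 8, 3))
    H, S, V = pg.rgb_to_hsv(img(px))
    for i in range(8):
        for j in range(8):
            h, s, v = scalar_hsv(*px[i, j])
            assert abs(H[i, j] - h) < 1e-9
            assert abs(S[i, j] - s) < 1e-9
            assert abs(V[i, j] - v) < 1e-9


def test_hsv_hsi_saturation_variant(rng):
    px = rng.uniform(0.01, 1, (5, 5, 3))
    _, S, _ = pg.rgb_to_hsv(img(px), saturation="hsi")
    expected = 1 - 3 * px.min(-1) / px.sum(-1)
    np.testing.assert_allclose(S, expected, atol=1e-12)
    # dark desaturated background scores low on the HSI form
    _, s_bg, _ = pg.rgb_to_hsv(img((0.013, 0.011, 0.023)), saturation="hsi")
    assert s_bg[0, 0] < 0.5


def test_hsv_requires_unit_scale():
    with pytest.raises(ScaleError):
        pg.rgb_to_hsv(img(np.array([10.0, 20.0, 30.0]), scale="8bit"))


# ---------------------------------------------------------------- XYZ matrix

def test_xyz_of_unit_white_is_d65():
    x, y, z = pg.linear_rgb_to_xyz_d65(img((1.0, 1.0, 1.0), transfer="linear"))
    np.testing.assert_allclose(
        [x[0, 0], y[0, 0], z[0, 0]], [0.95047, 1.00000, 1.08883], atol=1e-5)
    assert abs(y[0, 0] - 1.0) < 1e-5


def test_xyz_matrix_columns_and_zero():
    x, y, z = pg.linear_rgb_to_xyz_d65(img((1.0, 0.0, 0.0), transfer="linear"))
    np.testing.assert_allclose([x[0, 0], y[0, 0], z[0, 0]],
                               [0.4124564, 0.2126729, 0.0193339], atol=1e-12)
    x, y, z = pg.linear_rgb_to_xyz_d65(img((0.0, 0.0, 0.0), transfer="linear"))
    assert x[0, 0] == y[0, 0] == z[0, 0] == 0.0


def test_xyz_rejects_nonlinear_input():
    with pytest.raises(TransferTagError):
        pg.linear_rgb_to_xyz_d65(img((0.5, 0.5, 0.5), transfer="srgb"))


# ---------------------------------------------------------------- von Kries

def test_von_kries_identity_when_whites_equal():
    m = pg.von_kries_matrix(pg.D65_WHITE, pg.D65_WHITE)
    np.testing.assert_allclose(m.matrix, np.eye(3), atol=1e-12)


def test_von_kries_reproduces_published_matrix():
    m = pg.von_kries_matrix(pg.D65_WHITE, pg.D55_WHITE, pg.VON_KRIES_CONES)
    assert np.max(np.abs(m.matrix - PUBLISHED_ADAPTATION)) < 5e-4


def test_von_kries_maps_source_white_to_destination():
    m = pg.von_kries_matrix(pg.D65_WHITE, pg.D55_WHITE)
    mapped = m.matrix @ pg.D65_WHITE.as_array()
    np.testing.assert_allclose(mapped, [0.95682, 1.0000, 0.92149], atol=5e-4)


def test_bradford_alternative_preserves_white_but_differs():
    m = pg.von_kries_matrix(pg.D65_WHITE, pg.D55_WHITE, pg.BRADFORD_CONES)
    np.testing.assert_allclose(m.matrix @ pg.D65_WHITE.as_array(),
                               pg.D55_WHITE.as_array(), atol=5e-4)
    assert np.max(np.abs(m.matrix - PUBLISHED_ADAPTATION)) > 1e-3


def test_von_kries_domain_errors():
    with pytest.raises(ColorDomainError):
        pg.WhitePoint(-0.1, 1.0, 0.9)
    with pytest.raises(ColorDomainError):
        pg.WhitePoint(0.9, 0.5, 0.9)  # luminance not normalized
    with pytest.raises(np.linalg.LinAlgError):
        pg.ConeModel("broken", np.ones((3, 3)))


@given(st.floats(0.5, 1.5), st.floats(0.5, 1.5),
       st.floats(0.5, 1.5), st.floats(0.5, 1.5),
       st.sampled_from(["von-kries", "bradford"]))
def test_adaptation_conserves_white_for_any_illuminants(xs, zs, xd, zd, cones):
    src = pg.WhitePoint(xs, 1.0, zs)
    dst = pg.WhitePoint(xd, 1.0, zd)
    m = pg.von_kries_matrix(src, dst, pg.CONE_MODELS[cones])
    np.testing.assert_allclose(m.matrix @ src.as_array(), dst.as_array(),
                               atol=5e-4)


# ---------------------------------------------------------------- adapt_xyz

def test_adapt_identity_and_white_pixel():
    ident = pg.von_kries_matrix(pg.D55_WHITE, pg.D55_WHITE)
    x = np.full((3, 4), 0.3)
    out = pg.adapt_xyz(x, x * 2, x * 3, ident)
    np.testing.assert_allclose(out[0], x, atol=1e-12)
    m = pg.von_kries_matrix(pg.D65_WHITE, pg.D55_WHITE)
    w = pg.D65_WHITE.as_array()
    out = pg.adapt_xyz(*(np.full((1, 1), c) for c in w), m)
    np.testing.assert_allclose([p[0, 0] for p in out],
                               pg.D55_WHITE.as_array(), atol=5e-4)


def test_adapt_is_linear(rng):
    m = pg.von_kries_matrix(pg.D65_WHITE, pg.D55_WHITE)
    x, y, z = rng.uniform(0, 1, (3, 6, 6))
    once = pg.adapt_xyz(x, y, z, m)
    twice = pg.adapt_xyz(2 * x, 2 * y, 2 * z, m)
    for a, b in zip(once, twice):
        np.testing.assert_allclose(2 * a, b, rtol=1e-12)


def test_adapt_shape_mismatch():
    m = pg.von_kries_matrix(pg.D65_WHITE, pg.D55_WHITE)
    with pytest.raises(MaskShapeError):
        pg.adapt_xyz(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2)), m)


# ---------------------------------------------------------------- CIELAB

def test_lab_white_and_black():
    w = pg.D55_WHITE
    L, a, b = pg.xyz_to_lab(*(np.full((1, 1), c) for c in w.as_array()), w)
    np.testing.assert_allclose([L[0, 0], a[0, 0], b[0, 0]], [100, 0, 0],
                               atol=1e-10)
    L, a, b = pg.xyz_to_lab(*(np.zeros((1, 1)) for _ in range(3)), w)
    # linear branch at q=0: 116*(16/116) - 16 = 0
    np.testing.assert_allclose([L[0, 0], a[0, 0], b[0, 0]], [0, 0, 0],
                               atol=1e-10)


def test_lab_branches_agree_at_breakpoint():
    q = 0.008856
    assert abs(q ** (1 / 3) - (7.787 * q + 16 / 116)) < 1e-3


def test_lab_rejects_negative_tristimulus():
    with pytest.raises(ColorDomainError):
        pg.xyz_to_lab(np.full((1, 1), -0.1), np.ones((1, 1)), np.ones((1, 1)))


def test_lab_matches_skimage_d55(rng):
    xyz = rng.uniform(0.02, 0.9, (16, 16, 3))
    L, a, b = pg.xyz_to_lab(xyz[..., 0], xyz[..., 1], xyz[..., 2], pg.D55_WHITE)
    ref = skcolor.xyz2lab(xyz, illuminant="D55", observer="2")
    np.testing.assert_allclose(np.stack([L, a, b], -1), ref, atol=0.05)


@given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
def test_lightness_strictly_increasing_in_y(y1, y2):
    if abs(y1 - y2) < 1e-9:
        return
    lo, hi = sorted([y1, y2])
    f = lambda y: pg.xyz_to_lab(np.full((1, 1), 0.5), np.full((1, 1), y),
                                np.full((1, 1), 0.5))[0][0, 0]
    assert f(hi) > f(lo)


# ---------------------------------------------------------------- full chain

def test_full_chain_white_and_black():
    white = pg.ColorImage(np.full((1, 1, 3), 255, np.uint8))
    stack = pg.rgb_to_lab_d55(white)
    assert abs(stack["L"][0, 0] - 100) < 0.2
    assert abs(stack["a"][0, 0]) < 0.2 and abs(stack["b"][0, 0]) < 0.2
    black = pg.ColorImage(np.zeros((1, 1, 3), np.uint8))
    stack = pg.rgb_to_lab_d55(black)
    assert stack["L"][0, 0] == stack["a"][0, 0] == stack["b"][0, 0] == 0.0


def test_full_chain_red_class_mean_is_red():
    """A pixel at the measured red-class camera RGB lands well above a*=15."""
    px = np.round(np.array([[[0.099, 0.009, 0.010]]]) * 255).astype(np.uint8)
    stack = pg.rgb_to_lab_d55(pg.ColorImage(px, transfer="linear"))
    assert stack["a"][0, 0] > 15


@pytest.mark.parametrize("transfer", ["srgb", "linear"])
def test_vectorized_chain_equals_scalar_oracle(rng, transfer):
    px = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
    stack = pg.rgb_to_lab_d55(pg.ColorImage(px, transfer=transfer))
    for i in range(16):
        for j in range(16):
            L, a, b, X, Y, Z = scalar_lab_d55(
                *px[i, j], linear_input=(transfer == "linear"))
            got = [stack[k][i, j] for k in "LabXYZ"]
            np.testing.assert_allclose(got, [L, a, b, X, Y, Z], atol=1e-6)


def test_compute_planes_subset_and_full():
    im = pg.ColorImage(np.full((2, 2, 3), 128, np.uint8), transfer="linear")
    sub = pg.compute_planes(im, names=("S", "Y", "a"))
    assert set(sub.planes) == {"S", "Y", "a"}
    full = pg.compute_planes(im)
    assert set(full.planes) == set("HSVXYZLab")
    assert np.all((full["S"] >= 0) & (full["S"] <= 1))
    assert np.all((full["H"] >= 0) & (full["H"] < 1))
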