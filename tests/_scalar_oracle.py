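"""Independent scalar (pure-Python, per-pixel) reference for the color chain.

Deliberately avoids numpy and any code from the package: plain floats,
explicit loops, and a hand-written 3x3 inverse, so that agreement with the
vectorized implementation is a meaningful check.
"""

import math

SRGB_TO_XYZ = (
    (0.4124564, 0.3575761, 0.1804375),
    (0.2126729, 0.7151522, 0.0721750),
    (0.0193339, 0.1191920, 0.9503041),
)

HPE = (
    (0.40024, 0.70760, -0.08081),
    (-0.22630, 1.16532, 0.04570),
    (0.00000, 0.00000, 0.91822),
)

D65 = (0.95047, 1.00000, 1.08883)
D55 = (0.95682, 1.00000, 0.92149)


def _matvec(m, v):
    return tuple(sum(m[i][j] * v[j] for j in range(3)) for i in range(3))


def _inv3(m):
    a, b, c = m[0]
    d, e, f = m[1]
    g, h, i = m[2]
    det = a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)
    return (
        ((e * i - f * h) / det, (c * h - b * i) / det, (b * f - c * e) / det),
        ((f * g - d * i) / det, (a * i - c * g) / det, (c * d - a * f) / det),
        ((d * h - e * g) / det, (b * g - a * h) / det, (a * e - b * d) / det),
    )


def _matmul(m, n):
    return tuple(tuple(sum(m[i][k] * n[k][j] for k in range(3))
                       for j in range(3)) for i in range(3))


def von_kries_d65_to_d55():
    """The D65->D55 adaptation matrix via the classic von Kries cones."""
    src = _matvec(HPE, D65)
    dst = _matvec(HPE, D55)
    gain = tuple(tuple((dst[i] / src[i]) if i == j else 0.0 for j in range(3))
                 for i in range(3))
    return _matmul(_inv3(HPE), _matmul(gain, HPE))


def linearize(c):
    return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4


def _lab_f(q):
    return q ** (1.0 / 3.0) if q > 0.008856 else 7.787 * q + 16.0 / 116.0


def scalar_lab_d55(r8, g8, b8, linear_input=False):
    """(L, a, b, X, Y, Z) for one 8-bit pixel, D55-adapted.

    ``linear_input=True`` treats the stored values as linear camera RGB and
    skips the sRGB gamma removal.
    """
    rgb = (r8 / 255.0, g8 / 255.0, b8 / 255.0)
    if not linear_input:
        rgb = tuple(linearize(c) for c in rgb)
    xyz = _matvec(SRGB_TO_XYZ, rgb)
    xyz = _matvec(von_kries_d65_to_d55(), xyz)
    fx = _lab_f(xyz[0] / D55[0])
    fy = _lab_f(xyz[1] / D55[1])
    fz = _lab_f(xyz[2] / D55[2])
    return (116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)) + xyz


def scalar_hsv(r, g, b):
    """Hexcone HSV of one unit-scale pixel, H as fraction of a turn."""
    mx, mn = max(r, g, b), min(r, g, b)
    v = mx
    s = 0.0 if mx == 0 else (mx - mn) / mx
    if mx == mn:
        h = 0.0
    elif mx == r:
        h = ((g - b) / (mx - mn)) % 6.0 / 6.0
    elif mx == g:
        h = ((b - r) / (mx - mn) + 2.0) / 6.0
    else:
        h = ((r - g) / (mx - mn) + 4.0) / 6.0
    return h, s, v
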