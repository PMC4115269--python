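"""Independent brute-force references for the combination equations.

These deliberately avoid the package's separable/cached implementations:
the blur-and-shift oracle evaluates the full 2-D window definition term by
term, and the geometric-mean oracle evaluates the weighted product pixel by
pixel.  Agreement is expected up to floating-point multiply-order effects
(relative tolerance 1e-12), not bit-exactness.
"""

import math

import numpy as np


def shift_zero_fill(a: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """out(x, y) = a(x - dx, y - dy) with zeros outside the grid."""
    h, w = a.shape
    out = np.zeros_like(a)
    for iy in range(h):
        sy = iy - dy
        if not 0 <= sy < h:
            continue
        for ix in range(w):
            sx = ix - dx
            if 0 <= sx < w:
                out[iy, ix] = a[sy, sx]
    return out


def oracle_blur_shift(subunit_map, rho, phi, sigma0, alpha, t1=0.0):
    """Direct evaluation of the blur-and-shift definition.

    out(x, y) = max over |x'|,|y'| <= ceil(3 sigma) of
    thresholded(x - x' - dx, y - y' - dy) * exp(-(x'^2+y'^2)/(2 sigma^2))
    with sigma = sigma0 + alpha*rho, (dx, dy) = round(-rho cos phi,
    -rho sin phi), zero outside the grid, peak-normalized Gaussian weight.
    """
    m = np.asarray(subunit_map, dtype=float)
    thr = m.copy()
    mx = thr.max()
    if t1 > 0 and mx > 0:
        thr[thr < t1 * mx] = 0.0
    sigma = sigma0 + alpha * rho
    k = int(math.ceil(3.0 * sigma))
    dx = int(round(-rho * math.cos(phi)))
    dy = int(round(-rho * math.sin(phi)))
    out = np.zeros_like(m)
    for yp in range(-k, k + 1):
        for xp in range(-k, k + 1):
            g = math.exp(-(xp * xp + yp * yp) / (2.0 * sigma * sigma))
            np.maximum(out, g * shift_zero_fill(thr, xp + dx, yp + dy), out=out)
    return out


def oracle_weighted_gmean(maps, rhos, sp, t3=0.0):
    """Pixel-by-pixel weighted geometric mean with fractional thresholding."""
    weights = [
        1.0 if math.isinf(sp) else math.exp(-(r * r) / (2.0 * sp * sp))
        for r in rhos
    ]
    wsum = sum(weights)
    h, w = maps[0].shape
    out = np.zeros((h, w))
    for iy in range(h):
        for ix in range(w):
            prod = 1.0
            for m, wgt in zip(maps, weights):
                prod *= m[iy, ix] ** wgt
            out[iy, ix] = prod ** (1.0 / wsum)
    mx = out.max()
    if t3 > 0 and mx > 0:
        out[out < t3 * mx] = 0.0
    return out
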