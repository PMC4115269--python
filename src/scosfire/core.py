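"""Generic COSFIRE combination machinery.

A COSFIRE filter combines the responses of simpler subunit filters taken at
polar positions (rho, phi) around its support center.  Two operations are
shared by every level of the hierarchy:

* *blur-and-shift*: a Gaussian-weighted maximum (grayscale dilation) of a
  thresholded subunit response, with blur std ``sigma = sigma0 + alpha*rho``,
  followed by a translation that moves the subunit's preferred position onto
  the filter center (shift vector ``(-rho*cos(phi), -rho*sin(phi))``).
* *weighted geometric mean*: an AND-type combination of the blurred and
  shifted maps with weights ``omega_i = exp(-rho_i^2 / (2*sigma_prime^2))``
  decaying from 1 at the center to 0.5 at the largest tuple radius.

All maps use the math frame: ``map[iy, ix]`` with the y axis pointing up and
angles measured counterclockwise from the +x axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Hashable, Sequence

import numpy as np

__all__ = [
    "CosfireTuple",
    "BlurParams",
    "threshold_fraction",
    "sigma_prime",
    "tuple_weight",
    "gaussian_max_filter",
    "translate",
    "dilate_padded",
    "shift_crop",
    "blur_shift",
    "weighted_geometric_mean",
]


class ParameterError(ValueError):
    """Raised for invalid filter parameters."""


def _normalize_angle(phi: float) -> float:
    """Map an angle to [0, 2*pi)."""
    phi = float(phi) % (2.0 * math.pi)
    # guard against -0.0 and the 2*pi boundary after float modulo
    if phi >= 2.0 * math.pi or phi < 0.0:
        phi = 0.0
    return phi


@dataclass(frozen=True)
class CosfireTuple:
    """One subunit of a COSFIRE filter.

    Parameters
    ----------
    subunit
        Hashable reference to a subunit response channel: a ``(wavelength,
        theta)`` Gabor channel at the vertex level, or a vertex filter at the
        shape level.
    rho
        Radial distance of the subunit's preferred position from the filter
        center, in pixels (>= 0).
    phi
        Polar angle of that position, radians, normalized to [0, 2*pi).
    """

    subunit: Hashable
    rho: float
    phi: float

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ParameterError(f"rho must be >= 0, got {self.rho}")
        object.__setattr__(self, "rho", float(self.rho))
        object.__setattr__(self, "phi", _normalize_angle(self.phi))


@dataclass(frozen=True)
class BlurParams:
    """Linear blur model ``sigma(rho) = sigma0 + alpha * rho``.

    ``sigma0`` (pixels, > 0) sets the positional tolerance at the filter
    center; ``alpha`` (dimensionless, >= 0) makes the tolerance grow with
    eccentricity, mimicking the growth of receptive-field size in the visual
    cortex.
    """

    sigma0: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ParameterError(f"sigma0 must be > 0, got {self.sigma0}")
        if self.alpha < 0:
            raise ParameterError(f"alpha must be >= 0, got {self.alpha}")

    def sigma(self, rho: float) -> float:
        return self.sigma0 + self.alpha * float(rho)


def threshold_fraction(response: np.ndarray, t: float) -> np.ndarray:
    """Soft-threshold a response map at a fraction ``t`` of its global max.

    Values below ``t * max`` are set to 0; values at or above it are kept
    unchanged (no binarization).  An all-zero map is returned unchanged, and
    ``t = 0`` is the identity.
    """
    if not 0.0 <= t <= 1.0:
        raise ParameterError(f"threshold fraction must be in [0, 1], got {t}")
    response = np.asarray(response, dtype=float)
    if t == 0.0:
        return response.copy()
    m = response.max() if response.size else 0.0
    if m <= 0.0:
        return response.copy()
    out = response.copy()
    out[out < t * m] = 0.0
    return out


def sigma_prime(rho_max: float) -> float:
    """Weight std such that omega(0) = 1 and omega(rho_max) = 0.5.

    Computed as ``sqrt(-rho_max^2 / (2 ln 0.5)) = rho_max / sqrt(2 ln 2)``.
    ``rho_max = 0`` returns ``inf`` (i.e. ``1/sigma_prime = 0``), for which
    the weighted geometric mean degenerates to the plain geometric mean with
    equal weights.
    """
    if rho_max < 0:
        raise ParameterError(f"rho_max must be >= 0, got {rho_max}")
    if rho_max == 0:
        return math.inf
    return float(rho_max) / math.sqrt(2.0 * math.log(2.0))


def tuple_weight(rho: float, sp: float) -> float:
    """Weight ``omega = exp(-rho^2 / (2*sigma_prime^2))`` of a tuple."""
    if rho < 0:
        raise ParameterError(f"rho must be >= 0, got {rho}")
    if math.isinf(sp):
        return 1.0
    if sp <= 0:
        raise ParameterError("sigma_prime must be positive (or inf for equal weights)")
    return math.exp(-(float(rho) ** 2) / (2.0 * sp * sp))


def translate(a: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Integer translation with zero fill: ``out(x, y) = a(x - dx, y - dy)``."""
    out = np.zeros_like(a)
    h, w = a.shape
    dx, dy = int(dx), int(dy)
    if abs(dx) >= w or abs(dy) >= h:
        return out
    src_y = slice(max(0, -dy), min(h, h - dy))
    dst_y = slice(max(0, dy), min(h, h + dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = a[src_y, src_x]
    return out


def _axis_max_pass(a: np.ndarray, sigma: float, axis: int) -> np.ndarray:
    k = int(math.ceil(3.0 * sigma))
    out = a.copy()
    for d in range(1, k + 1):
        w = math.exp(-(d * d) / (2.0 * sigma * sigma))
        if w == 0.0:
            break
        shifted = np.zeros_like(a)
        if axis == 0:
            shifted[d:, :] = a[:-d, :]
            np.maximum(out, w * shifted, out=out)
            shifted = np.zeros_like(a)
            shifted[:-d, :] = a[d:, :]
        else:
            shifted[:, d:] = a[:, :-d]
            np.maximum(out, w * shifted, out=out)
            shifted = np.zeros_like(a)
            shifted[:, :-d] = a[:, d:]
        np.maximum(out, w * shifted, out=out)
    return out


def gaussian_max_filter(a: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-weighted grayscale dilation over a +/- ceil(3*sigma) window.

    ``out(x, y) = max_{|x'|,|y'| <= ceil(3 sigma)} a(x - x', y - y') *
    G_sigma(x', y')`` with a peak-normalized Gaussian (G(0, 0) = 1), so a
    subunit response passes through undiminished at zero positional error.
    Out-of-image values are treated as 0.  The weight is separable and
    nonnegative, so the maximum is evaluated as two 1-D passes.
    """
    if sigma <= 0:
        raise ParameterError(f"blur sigma must be > 0, got {sigma}")
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ParameterError("subunit map must be nonnegative")
    return _axis_max_pass(_axis_max_pass(a, sigma, 0), sigma, 1)


def dilate_padded(a: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-weighted dilation of ``a`` zero-padded by the window radius.

    Returns an array grown by ``k = ceil(3*sigma)`` on every side.  Keeping
    the padded frame lets a subsequent shift read dilation values centered
    just outside the original grid, which the literal blur-and-shift formula
    requires (its max window may reach back into the grid even when the
    window center does not).
    """
    k = int(math.ceil(3.0 * sigma))
    return gaussian_max_filter(np.pad(np.asarray(a, dtype=float), k), sigma)


def shift_crop(
    padded: np.ndarray,
    sigma: float,
    dx: int,
    dy: int,
    shape: tuple[int, int],
) -> np.ndarray:
    """Read ``out(x, y) = dilated(x - dx, y - dy)`` from a padded dilation.

    ``padded`` must come from :func:`dilate_padded` with the same ``sigma``
    and an original grid of ``shape``; positions outside the padded frame
    are 0 (all their window terms fall off the grid).
    """
    k = int(math.ceil(3.0 * sigma))
    h, w = shape
    hp, wp = padded.shape
    out = np.zeros(shape, dtype=float)
    oy = k - int(dy)  # row offset into the padded frame
    ox = k - int(dx)
    lo_y, hi_y = max(0, -oy), min(h, hp - oy)
    lo_x, hi_x = max(0, -ox), min(w, wp - ox)
    if lo_y < hi_y and lo_x < hi_x:
        out[lo_y:hi_y, lo_x:hi_x] = padded[
            lo_y + oy : hi_y + oy, lo_x + ox : hi_x + ox
        ]
    return out


def blur_shift(
    subunit_map: np.ndarray,
    tup: CosfireTuple,
    blur: BlurParams,
    t1: float = 0.0,
) -> np.ndarray:
    """Blurred and shifted thresholded subunit response (one COSFIRE tuple).

    The subunit map is thresholded at fraction ``t1`` of its global maximum,
    dilated with a Gaussian weight of std ``sigma0 + alpha*rho``, and then
    translated by ``(dx, dy) = (-rho*cos(phi), -rho*sin(phi))`` (rounded to
    the nearest integer pixel) so that the subunit's preferred position maps
    onto the filter center.  The dilation is evaluated on a zero-padded
    frame so the result equals the direct max-window formula everywhere,
    including image borders.
    """
    sigma = blur.sigma(tup.rho)
    thresholded = threshold_fraction(subunit_map, t1)
    padded = dilate_padded(thresholded, sigma)
    dx = -tup.rho * math.cos(tup.phi)
    dy = -tup.rho * math.sin(tup.phi)
    return shift_crop(padded, sigma, int(round(dx)), int(round(dy)),
                      thresholded.shape)


def weighted_geometric_mean(
    s_maps: Sequence[np.ndarray],
    rho_list: Sequence[float],
    sp: float | None = None,
    t3: float = 0.0,
) -> np.ndarray:
    """AND-type combination of blurred-and-shifted subunit maps.

    ``r(x, y) = (prod_i s_i(x, y)^omega_i)^(1 / sum_i omega_i)``, followed by
    a fractional threshold at ``t3``.  ``sp`` (sigma_prime) defaults to the
    value auto-computed from ``max(rho_list)``; any zero factor makes the
    output zero at that pixel (every subunit is essential).
    """
    if len(s_maps) == 0:
        raise ParameterError("need at least one subunit map")
    if len(s_maps) != len(rho_list):
        raise ParameterError("s_maps and rho_list must have equal length")
    shape = s_maps[0].shape
    for m in s_maps:
        if m.shape != shape:
            raise ParameterError("all subunit maps must share one grid")
    if sp is None:
        sp = sigma_prime(max(rho_list))
    weights = np.array([tuple_weight(r, sp) for r in rho_list])
    wsum = weights.sum()
    acc = np.ones(shape, dtype=float)
    for m, w in zip(s_maps, weights):
        acc *= np.power(np.asarray(m, dtype=float), w)
    out = np.power(acc, 1.0 / wsum)
    return threshold_fraction(out, t3)
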