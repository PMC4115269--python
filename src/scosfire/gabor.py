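"""Layer-1 contour detection: Gabor energy filters and surround suppression.

A channel is a quadrature pair of Gabor kernels (phases 0 and pi/2) at one
wavelength and orientation; its *energy* is the root of the sum of squared
responses of the pair, which is phase-invariant (identical for a contour and
its contrast-reversed copy) and models complex cells in V1.  Channels are
calibrated so that an ideal line of the default stroke width yields energy
close to 1 on the best-aligned channel, putting all channels on the common
[0, 1] scale the downstream geometric-mean combination requires.

Orientation theta is the direction *along* the contour a channel prefers,
radians in [0, pi), measured counterclockwise from +x in the math frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .core import ParameterError, threshold_fraction
from .fixtures import blank, draw_segments, DEFAULT_LINE_WIDTH

__all__ = [
    "GaborParams",
    "GaborBank",
    "GaborStack",
    "build_gabor_bank",
    "gabor_energy",
    "surround_suppress",
    "threshold_fraction",
]


@dataclass(frozen=True)
class GaborParams:
    """Shared Gabor kernel shape parameters.

    ``bandwidth`` (octaves) controls the envelope std relative to the
    wavelength; ``aspect_ratio`` in (0, 1] elongates the envelope along the
    preferred orientation (std ``sigma / aspect_ratio`` along the contour).
    Defaults (1 octave, 0.5) are the standard choice for contour operators.
    """

    bandwidth: float = 1.0
    aspect_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ParameterError("bandwidth must be > 0")
        if not 0 < self.aspect_ratio <= 1:
            raise ParameterError("aspect ratio must be in (0, 1]")

    def sigma(self, wavelength: float) -> float:
        """Envelope std across the contour, from wavelength and bandwidth."""
        b = self.bandwidth
        ratio = (1.0 / math.pi) * math.sqrt(math.log(2.0) / 2.0) * (2**b + 1) / (2**b - 1)
        return ratio * wavelength


def _gabor_kernel_pair(
    wavelength: float, theta: float, params: GaborParams
) -> tuple[np.ndarray, np.ndarray]:
    """Even/odd (cos/sin) kernel pair; even kernel is DC-corrected."""
    sigma = params.sigma(wavelength)
    gamma = params.aspect_ratio
    half = int(math.ceil(3.0 * sigma / gamma))
    ys, xs = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    # u along the preferred contour direction, v across it
    u = xs * math.cos(theta) + ys * math.sin(theta)
    v = -xs * math.sin(theta) + ys * math.cos(theta)
    env = np.exp(-(v * v + (gamma * u) ** 2) / (2.0 * sigma * sigma))
    arg = 2.0 * math.pi * v / wavelength
    even = env * np.cos(arg)
    odd = env * np.sin(arg)
    # remove the DC component of the even kernel by subtracting a scaled
    # envelope, so a constant image gives exactly zero response
    even -= env * (even.sum() / env.sum())
    even /= math.sqrt((even**2).sum())
    odd /= math.sqrt((odd**2).sum())
    return even, odd


@dataclass(frozen=True)
class GaborBank:
    """Bank of quadrature Gabor kernel pairs indexed by (wavelength, theta)."""

    wavelengths: tuple[float, ...]
    orientations: tuple[float, ...]
    params: GaborParams

    @property
    def channels(self) -> list[tuple[float, float]]:
        return [(lam, th) for lam in self.wavelengths for th in self.orientations]

    def kernels(self, lam: float, theta: float) -> tuple[np.ndarray, np.ndarray]:
        return _gabor_kernel_pair(lam, theta, self.params)

    @property
    def n_orientations(self) -> int:
        return len(self.orientations)


def build_gabor_bank(
    wavelengths: Sequence[float],
    n_orientations: int,
    params: GaborParams | None = None,
) -> GaborBank:
    """Bank with ``n_orientations`` equidistant orientations over [0, pi).

    Orientation spacing is ``pi / n_orientations``; the channel list is the
    cartesian product of wavelengths and orientations.
    """
    if n_orientations < 1:
        raise ParameterError("need at least one orientation")
    for lam in wavelengths:
        if lam <= 0:
            raise ParameterError(f"wavelength must be > 0, got {lam}")
    if params is None:
        params = GaborParams()
    orientations = tuple(i * math.pi / n_orientations for i in range(n_orientations))
    return GaborBank(tuple(float(w) for w in wavelengths), orientations, params)


def _convolve_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same'-size correlation with reflect padding at the borders."""
    half = kernel.shape[0] // 2
    padded = np.pad(image, half, mode="reflect")
    # correlation == convolution with a flipped kernel
    out = fftconvolve(padded, kernel[::-1, ::-1], mode="same")
    return out[half:-half, half:-half] if half else out


# Calibrated energies below this are FFT round-off, not signal: Gaussian
# kernel tails decay to ~1e-27 of the peak within the filter support, so
# anything this small on the calibrated [0, 1] scale is numerical noise.
ENERGY_FLOOR = 1e-12

# per-(params, wavelength, width) calibration constants, computed lazily
_CALIBRATION: dict[tuple, float] = {}


def _calibration_constant(lam: float, params: GaborParams,
                          line_width: float = DEFAULT_LINE_WIDTH) -> float:
    """Max raw energy over orientations on an ideal straight line.

    Dividing a wavelength's channels by this constant makes a perfect
    contour of the default stroke width yield energy ~= 1 on the
    best-aligned channel.
    """
    key = (params, round(lam, 6), round(line_width, 6))
    if key in _CALIBRATION:
        return _CALIBRATION[key]
    sigma = params.sigma(lam)
    half = int(math.ceil(3.0 * sigma / params.aspect_ratio))
    n = 8 * half + 33
    img = draw_segments(
        blank((n, n)), [((0.0, (n - 1) / 2.0), (n - 1.0, (n - 1) / 2.0))], line_width
    )
    even, odd = _gabor_kernel_pair(lam, 0.0, params)
    e = _convolve_reflect(img, even)
    o = _convolve_reflect(img, odd)
    c = float(np.sqrt(e * e + o * o).max())
    _CALIBRATION[key] = c
    return c


class GaborStack:
    """Per-channel energy maps of one image, indexed by (wavelength, theta)."""

    def __init__(self, maps: Mapping[tuple[float, float], np.ndarray],
                 bank: GaborBank):
        self._maps = dict(maps)
        self.bank = bank
        first = next(iter(self._maps.values()))
        self.shape = first.shape

    @property
    def channels(self) -> list[tuple[float, float]]:
        return list(self._maps.keys())

    def resolve(self, lam: float, theta: float) -> tuple[float, float]:
        """Nearest available channel key for (lam, theta), theta modulo pi
        (energy channels are polarity- and direction-insensitive)."""
        key = (lam, theta)
        if key in self._maps:
            return key
        cands = [k for k in self._maps if k[0] == lam]
        if not cands:
            raise KeyError(f"no channels at wavelength {lam}")
        theta = theta % math.pi

        def circdist(t: float) -> float:
            d = abs(t - theta) % math.pi
            return min(d, math.pi - d)

        return min(cands, key=lambda k: circdist(k[1]))

    def channel(self, lam: float, theta: float) -> np.ndarray:
        """Channel map for (lam, theta), snapping theta to the nearest
        available orientation."""
        return self._maps[self.resolve(lam, theta)]

    def pooled(self) -> np.ndarray:
        """Pixelwise maximum over all channels."""
        return np.maximum.reduce(list(self._maps.values()))

    def as_array(self) -> np.ndarray:
        return np.stack(list(self._maps.values()))

    def replace(self, maps: Mapping[tuple[float, float], np.ndarray]) -> "GaborStack":
        return GaborStack(maps, self.bank)


def gabor_energy(image: np.ndarray, bank: GaborBank,
                 calibrate: bool = True) -> GaborStack:
    """Gabor energy of an image for every channel of a bank.

    Per channel, energy is the modulus of the quadrature (even/odd) pair's
    responses; boundaries are reflect-padded.  With ``calibrate`` (default),
    each wavelength's channels are divided by the ideal-line calibration
    constant and clipped at 1, so responses live on a common [0, 1] scale.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0 or image.ndim != 2:
        raise ParameterError("image must be a nonempty 2-D array")
    maps: dict[tuple[float, float], np.ndarray] = {}
    for lam in bank.wavelengths:
        scale = 1.0 / _calibration_constant(lam, bank.params) if calibrate else 1.0
        for th in bank.orientations:
            even, odd = bank.kernels(lam, th)
            e = _convolve_reflect(image, even)
            o = _convolve_reflect(image, odd)
            en = np.sqrt(e * e + o * o) * scale
            if calibrate:
                np.clip(en, 0.0, 1.0, en)
                # FFT round-off floor: genuinely contour-free pixels must be
                # exactly 0 so downstream geometric means vanish there.
                en[en < ENERGY_FLOOR] = 0.0
            maps[(lam, th)] = en
    return GaborStack(maps, bank)


def _ring_kernel(sigma: float) -> np.ndarray:
    """L1-normalized positive part of a difference of Gaussians.

    Outer std 4*sigma, inner std sigma: an annular weighting of the local
    surround used for isotropic suppression.
    """
    outer = 4.0 * sigma
    half = int(math.ceil(3.0 * outer))
    ys, xs = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    r2 = xs * xs + ys * ys
    g_out = np.exp(-r2 / (2 * outer * outer)) / (2 * math.pi * outer * outer)
    g_in = np.exp(-r2 / (2 * sigma * sigma)) / (2 * math.pi * sigma * sigma)
    ring = np.clip(g_out - g_in, 0.0, None)
    return ring / ring.sum()


def surround_suppress(stack: GaborStack, suppression_coefficient: float) -> GaborStack:
    """Isotropic surround suppression of an energy stack.

    The surround signal is the orientation-pooled energy averaged over an
    annular (difference-of-Gaussians) neighborhood; each channel is reduced
    by ``coefficient x surround`` and floored at 0.  Isolated contours are
    mostly preserved while dense oriented texture is attenuated.  A zero
    coefficient returns the stack unchanged.
    """
    if suppression_coefficient < 0:
        raise ParameterError("suppression coefficient must be >= 0")
    if suppression_coefficient == 0:
        return stack
    out: dict[tuple[float, float], np.ndarray] = {}
    for lam in stack.bank.wavelengths:
        chans = {th: stack.channel(lam, th) for th in stack.bank.orientations}
        pooled = np.maximum.reduce(list(chans.values()))
        sigma = stack.bank.params.sigma(lam)
        surround = _convolve_reflect(pooled, _ring_kernel(sigma))
        for th, ch in chans.items():
            out[(lam, th)] = np.clip(
                ch - suppression_coefficient * surround, 0.0, None
            )
    return stack.replace(out)
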