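"""Layer-2 vertex detectors (V-COSFIRE filters).

A vertex filter combines Gabor energy responses taken at polar positions
along the two arms of a corner.  Filters are configured automatically from a
rendered synthetic vertex: Gabor energy is sampled along concentric circles
around the corner point, angular local maxima give tuple positions, and the
dominant orientation channels at each position give the tuple channels.

The standard bank holds 60 filters: 12 bisector orientations (steps of pi/6)
x 5 apertures {pi/6, pi/3, pi/2, 2pi/3, 5pi/6}.  A vertex "points" along its
bisector beta: the two contour arms extend from the corner point in
directions ``beta + pi +- gamma/2`` (a northward-pointing corner has its tip
at the top and its arms running down-left and down-right).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .core import (
    BlurParams,
    CosfireTuple,
    ParameterError,
    dilate_padded,
    shift_crop,
    sigma_prime,
    threshold_fraction,
    tuple_weight,
    weighted_geometric_mean,
)
from .fixtures import DEFAULT_LINE_WIDTH, blank, draw_segments
from .gabor import GaborBank, GaborStack, build_gabor_bank, gabor_energy, surround_suppress

__all__ = [
    "APERTURES",
    "ORIENTATION_OFFSET",
    "VertexSpec",
    "VCosfireFilter",
    "ResponseContext",
    "ConfigurationError",
    "render_vertex",
    "configure_v_cosfire",
    "build_vertex_bank",
    "apply_v_cosfire",
    "transform_v_filter",
]

APERTURES: tuple[float, ...] = (
    math.pi / 6, math.pi / 3, math.pi / 2, 2 * math.pi / 3, 5 * math.pi / 6,
)

# Bisector of the first bank column.  With this offset the bank's index
# arithmetic reproduces the canonical worked example: the corners of an
# equilateral triangle with apex north select the aperture-pi/3 filters at
# indices 13 (south-west), 17 (south-east) and 21 (north), i.e. columns
# four apart (orientations 2pi/3 apart).
ORIENTATION_OFFSET = 7 * math.pi / 6

DEFAULT_ARM_LENGTH = 60.0  # pixels; 2.5 * lambda * 6 at the default lambda=4
DEFAULT_RADII: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0)
# The bank skips circles inside ~2*sigma of the corner point: there the
# energy ridge of the two arms is still merged (corner-rounding zone), which
# drags the filter's response peak inside the corner and degrades vertex
# localization.  Starting at 2*lambda keeps the peak on the corner point.
BANK_RADII: tuple[float, ...] = (8.0, 12.0, 16.0, 20.0)
DEFAULT_VERTEX_CANVAS: tuple[int, int] = (161, 161)


class ConfigurationError(RuntimeError):
    """Raised when a prototype yields no usable configuration."""


@dataclass(frozen=True)
class VertexSpec:
    """Synthetic-vertex descriptor: bisector orientation and aperture.

    ``beta`` is the direction the corner points (radians, [0, 2pi));
    ``gamma`` is the angle between the two arms (radians, (0, pi)).
    ``index`` is the 1-based position in the standard 60-entry bank
    (row-major: aperture rows, orientation columns), or None for specs that
    are not bank members (e.g. after a geometric transform).
    """

    beta: float
    gamma: float
    index: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.gamma < math.pi:
            raise ParameterError(
                f"aperture must be in (0, pi), got {self.gamma}"
            )
        object.__setattr__(self, "beta", float(self.beta) % (2 * math.pi))

    @classmethod
    def from_index(cls, k: int, orientation_step: float = math.pi / 6,
                   apertures: Sequence[float] = APERTURES) -> "VertexSpec":
        n_orient = int(round(2 * math.pi / orientation_step))
        if not 1 <= k <= n_orient * len(apertures):
            raise ParameterError(f"bank index out of range: {k}")
        row, col = divmod(k - 1, n_orient)
        return cls(ORIENTATION_OFFSET + col * orientation_step, apertures[row], k)

    @property
    def arm_directions(self) -> tuple[float, float]:
        """Directions of the two contour arms leaving the corner point."""
        base = self.beta + math.pi
        return (
            (base - self.gamma / 2) % (2 * math.pi),
            (base + self.gamma / 2) % (2 * math.pi),
        )


@dataclass(frozen=True)
class VCosfireFilter:
    """Vertex-selective COSFIRE filter over Gabor energy channels.

    ``tuples`` hold ``(wavelength, theta)`` channel references with polar
    positions relative to the corner point; ``t1`` is the fractional
    threshold applied to each channel map before blurring (Eq.-1 style), and
    ``blur`` the positional-tolerance model sigma0 + alpha*rho.
    """

    tuples: tuple[CosfireTuple, ...]
    blur: BlurParams
    t1: float = 0.0
    spec: VertexSpec | None = None

    def __post_init__(self) -> None:
        if len(self.tuples) < 1:
            raise ParameterError("a V-COSFIRE filter needs at least one tuple")

    @property
    def rho_max(self) -> float:
        return max(t.rho for t in self.tuples)

    @property
    def wavelengths(self) -> set[float]:
        return {t.subunit[0] for t in self.tuples}


def render_vertex(
    spec: VertexSpec,
    arm_length: float = DEFAULT_ARM_LENGTH,
    line_width: float = DEFAULT_LINE_WIDTH,
    canvas: tuple[int, int] = DEFAULT_VERTEX_CANVAS,
    contrast: float = 1.0,
) -> np.ndarray:
    """Render a synthetic vertex: two arms meeting at the canvas center."""
    if not arm_length > line_width > 0:
        raise ParameterError("need arm_length > line_width > 0")
    h, w = canvas
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    segs = []
    for d in spec.arm_directions:
        segs.append(
            ((cx, cy), (cx + arm_length * math.cos(d), cy + arm_length * math.sin(d)))
        )
    return draw_segments(blank(canvas), segs, line_width, contrast)


class ResponseContext:
    """Shared per-image computation state.

    Holds the calibrated Gabor energy stack of one image and caches the
    intermediate products that are reused across filters and geometric
    transforms: thresholded channel maps, Gaussian-max dilations, and whole
    vertex-filter response maps (keyed by the hashable filter).
    """

    def __init__(self, image: np.ndarray, bank: GaborBank,
                 suppression: float = 0.0):
        self.image = np.asarray(image, dtype=float)
        self.bank = bank
        stack = gabor_energy(self.image, bank)
        if suppression > 0:
            stack = surround_suppress(stack, suppression)
        self.stack = stack
        self._thr: dict[tuple, np.ndarray] = {}
        self._dil: dict[tuple, np.ndarray] = {}
        self._vresp: dict[VCosfireFilter, np.ndarray] = {}
        self._vdil: dict[tuple, np.ndarray] = {}

    def thresholded(self, lam: float, theta: float, t1: float) -> np.ndarray:
        key = self.stack.resolve(lam, theta) + (round(t1, 9),)
        if key not in self._thr:
            self._thr[key] = threshold_fraction(self.stack.channel(lam, theta), t1)
        return self._thr[key]

    def dilated(self, lam: float, theta: float, t1: float, sigma: float) -> np.ndarray:
        """Padded Gaussian-max dilation of a thresholded channel (the frame
        is grown by the window radius; read it back with ``shift_crop``)."""
        key = self.stack.resolve(lam, theta) + (round(t1, 9), round(sigma, 6))
        if key not in self._dil:
            self._dil[key] = dilate_padded(
                self.thresholded(lam, theta, t1), sigma
            )
        return self._dil[key]

    def v_response(self, vf: VCosfireFilter) -> np.ndarray:
        if vf not in self._vresp:
            self._vresp[vf] = _apply_v(self, vf)
        return self._vresp[vf]

    def v_dilated(self, vf: VCosfireFilter, t1: float, sigma: float) -> np.ndarray:
        """Thresholded + Gaussian-max-dilated vertex response (shape level)."""
        key = (vf, round(t1, 9), round(sigma, 6))
        if key not in self._vdil:
            thr = threshold_fraction(self.v_response(vf), t1)
            self._vdil[key] = dilate_padded(thr, sigma)
        return self._vdil[key]


def _apply_v(ctx: ResponseContext, vf: VCosfireFilter) -> np.ndarray:
    shape = ctx.image.shape
    maps = []
    rhos = []
    for t in vf.tuples:
        lam, theta = t.subunit
        sigma = vf.blur.sigma(t.rho)
        d = ctx.dilated(lam, theta, vf.t1, sigma)
        dx = -t.rho * math.cos(t.phi)
        dy = -t.rho * math.sin(t.phi)
        maps.append(shift_crop(d, sigma, int(round(dx)), int(round(dy)), shape))
        rhos.append(t.rho)
    return weighted_geometric_mean(maps, rhos)


def apply_v_cosfire(
    image_or_ctx: np.ndarray | ResponseContext,
    vf: VCosfireFilter,
    bank: GaborBank | None = None,
) -> np.ndarray:
    """Response map of a vertex filter (Eq.-1 blur-shift per Gabor tuple,
    combined by the weighted geometric mean).

    Pass a :class:`ResponseContext` to share Gabor responses and blur
    products across filters; with a raw image, a context is built from
    ``bank`` (default: a 12-orientation bank at the filter's wavelengths).
    """
    if isinstance(image_or_ctx, ResponseContext):
        return image_or_ctx.v_response(vf)
    if bank is None:
        bank = build_gabor_bank(sorted(vf.wavelengths), 12)
    ctx = ResponseContext(image_or_ctx, bank)
    return ctx.v_response(vf)


def _circular_local_maxima(values: np.ndarray) -> list[int]:
    """Indices of strict local maxima on a circular sequence.

    Plateaus that are maximal against both distinct neighbors keep their
    center sample.
    """
    n = len(values)
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[(j + 1) % n] == values[i]:
            j += 1
        if j - i + 1 >= n:  # constant sequence
            break
        prev = values[(i - 1) % n]
        nxt = values[(j + 1) % n]
        if values[i] > prev and values[i] > nxt:
            maxima.append((i + j) // 2)
        i = j + 1
    return maxima


def _sample_channels(stack: GaborStack, xs: np.ndarray, ys: np.ndarray) -> dict:
    coords = np.vstack([ys, xs])
    return {
        key: map_coordinates(stack.channel(*key), coords, order=1, mode="constant")
        for key in stack.channels
    }


def configure_v_cosfire(
    prototype: np.ndarray,
    center: tuple[float, float],
    bank: GaborBank,
    radii: Sequence[float] = DEFAULT_RADII,
    t1: float = 0.3,
    select_fraction: float = 0.75,
    blur: BlurParams | None = None,
    response_t1: float | None = None,
    spec: VertexSpec | None = None,
    suppression: float = 0.0,
) -> VCosfireFilter:
    """Configure a vertex filter from a prototype corner.

    Gabor energy (pooled over channels) is sampled along concentric circles
    of the given radii around ``center``.  Angular local maxima whose pooled
    energy exceeds ``t1`` x the image-global maximum become tuple positions;
    at each position every channel within ``select_fraction`` of the local
    per-channel maximum contributes one (wavelength, theta, rho, phi) tuple.

    ``t1`` gates configuration; ``response_t1`` (default: same value) is
    stored on the filter and applied when the filter is used.
    """
    if not radii:
        raise ParameterError("radii must be non-empty")
    h, w = prototype.shape
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ParameterError("center must lie inside the image")
    stack = gabor_energy(prototype, bank)
    if suppression > 0:
        stack = surround_suppress(stack, suppression)
    pooled = stack.pooled()
    global_max = float(pooled.max())
    if global_max <= 0:
        raise ConfigurationError("blank prototype: no Gabor energy anywhere")
    gate = max(t1 * global_max, 1e-9 * global_max, 1e-12)

    tuples: list[CosfireTuple] = []
    for rho in radii:
        if rho < 0:
            raise ParameterError("radii must be >= 0")
        if rho == 0:
            xs = np.array([cx])
            ys = np.array([cy])
            phis = np.array([0.0])
            pick = [0] if map_coordinates(
                pooled, np.vstack([ys, xs]), order=1
            )[0] >= gate else []
        else:
            n = max(90, int(round(4 * 2 * math.pi * rho)))
            phis = np.arange(n) * 2 * math.pi / n
            xs = cx + rho * np.cos(phis)
            ys = cy + rho * np.sin(phis)
            vals = map_coordinates(pooled, np.vstack([ys, xs]), order=1,
                                   mode="constant")
            pick = [i for i in _circular_local_maxima(vals) if vals[i] >= gate]
        if not pick:
            continue
        per_chan = _sample_channels(stack, xs[pick], ys[pick])
        for col, i in enumerate(pick):
            local = {key: v[col] for key, v in per_chan.items()}
            best = max(local.values())
            if best <= 0:
                continue
            for key, v in local.items():
                if v >= select_fraction * best:
                    tuples.append(CosfireTuple(key, float(rho), float(phis[i])))
    if not tuples:
        raise ConfigurationError(
            "no above-threshold local maxima on any configuration circle"
        )
    if blur is None:
        blur = BlurParams(0.1, 0.0853)
    app_t1 = t1 if response_t1 is None else response_t1
    return VCosfireFilter(tuple(tuples), blur, app_t1, spec)


def build_vertex_bank(
    orientation_step: float = math.pi / 6,
    apertures: Sequence[float] = APERTURES,
    gabor_bank: GaborBank | None = None,
    blur: BlurParams | None = None,
    radii: Sequence[float] = BANK_RADII,
    t1: float = 0.3,
    response_t1: float = 0.1,
    arm_length: float = DEFAULT_ARM_LENGTH,
    line_width: float = DEFAULT_LINE_WIDTH,
    canvas: tuple[int, int] = DEFAULT_VERTEX_CANVAS,
) -> list[VCosfireFilter]:
    """Configure the standard vertex-filter bank from rendered prototypes.

    Defaults give 12 orientations x 5 apertures = 60 filters, ordered
    row-major (aperture rows, orientation columns, 1-based indices).
    """
    n_orient = 2 * math.pi / orientation_step
    if abs(n_orient - round(n_orient)) > 1e-9:
        raise ParameterError("orientation step must divide 2*pi evenly")
    n_orient = int(round(n_orient))
    if gabor_bank is None:
        gabor_bank = build_gabor_bank([4.0], 12)
    if blur is None:
        blur = BlurParams(0.1, 0.0853)
    filters = []
    k = 1
    for gamma in apertures:
        for col in range(n_orient):
            spec = VertexSpec(ORIENTATION_OFFSET + col * orientation_step, gamma, k)
            img = render_vertex(spec, arm_length, line_width, canvas)
            h, w = canvas
            vf = configure_v_cosfire(
                img, ((w - 1) / 2.0, (h - 1) / 2.0), gabor_bank, radii,
                t1=t1, blur=blur, response_t1=response_t1, spec=spec,
            )
            filters.append(vf)
            k += 1
    return filters


def transform_v_filter(
    vf: VCosfireFilter,
    psi: float = 0.0,
    upsilon: float = 1.0,
    reflect: bool = False,
) -> VCosfireFilter:
    """Rotated / scaled / reflected copy of a vertex filter.

    Reflection (about the y axis) is applied first, then scaling, then
    rotation.  Channel orientations transform modulo pi (energy channels are
    polarity-invariant) while polar angles transform modulo 2*pi; scaling
    multiplies both the channel wavelength and the tuple radius.
    """
    if upsilon <= 0:
        raise ParameterError(f"scale factor must be > 0, got {upsilon}")
    new_tuples = []
    for t in vf.tuples:
        lam, theta = t.subunit
        phi = t.phi
        rho = t.rho
        if reflect:
            theta = (math.pi - theta) % math.pi
            phi = math.pi - phi
        lam = lam * upsilon
        rho = rho * upsilon
        theta = (theta + psi) % math.pi
        phi = phi + psi
        new_tuples.append(CosfireTuple((round(lam, 9), round(theta, 9)), rho, phi))
    new_spec = None
    if vf.spec is not None:
        beta = vf.spec.beta
        if reflect:
            beta = math.pi - beta
        new_spec = VertexSpec(beta + psi, vf.spec.gamma, None)
    return VCosfireFilter(tuple(new_tuples), vf.blur, vf.t1, new_spec)
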