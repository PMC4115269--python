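"""Layer-3 shape detectors (S-COSFIRE filters).

An S-COSFIRE filter encodes a shape as a constellation of vertex filters at
polar positions around a user-chosen point of interest.  Configuration is
automatic from a single prototype image: every bank vertex filter is
applied, the per-pixel maximum over the bank is reduced to its strict
8-neighbor local maxima, and at each kept point the strongly responding
vertex filters (fraction t2 of the local best) become tuples.  The filter's
response is the weighted geometric mean of the blurred and shifted vertex
responses, an AND-type combination: it peaks at the center of any
arrangement of vertices similar to the prototype's and vanishes if any
configured vertex is absent.  Tolerance to rotation, scale, and reflection
comes from transforming the tuple set and taking pixelwise maxima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import (
    BlurParams,
    CosfireTuple,
    ParameterError,
    shift_crop,
    sigma_prime,
    threshold_fraction,
    weighted_geometric_mean,
)
from .gabor import GaborBank, GaborParams, build_gabor_bank
from .vertex import (
    ConfigurationError,
    ResponseContext,
    VCosfireFilter,
    transform_v_filter,
)

__all__ = [
    "FrontendConfig",
    "SCosfireFilter",
    "InvarianceSpec",
    "TransformLabel",
    "configure_s_cosfire",
    "apply_s_cosfire",
    "rotate_s",
    "scale_s",
    "reflect_s",
    "invariant_response",
    "strict_local_maxima",
]


@dataclass(frozen=True)
class FrontendConfig:
    """Gabor front-end settings an S filter needs to evaluate itself."""

    n_orientations: int = 12
    suppression: float = 0.0
    params: GaborParams = field(default_factory=GaborParams)

    def bank_for(self, wavelengths: Sequence[float]) -> GaborBank:
        return build_gabor_bank(sorted(set(wavelengths)), self.n_orientations,
                                self.params)


@dataclass(frozen=True)
class SCosfireFilter:
    """Shape-selective COSFIRE filter.

    ``tuples`` reference vertex filters at polar positions (rho in pixels,
    phi in radians) relative to the support center; ``blur`` gives the
    shape-level positional tolerance sigma0 + alpha*rho, ``t1``/``t3`` the
    fractional thresholds on vertex responses and on the output, and ``t2``
    the configuration selection fraction (kept for provenance).
    ``sigma_prime_override`` replaces the auto value computed from rho_max.
    """

    tuples: tuple[tuple[VCosfireFilter, float, float], ...]
    blur: BlurParams
    t1: float = 0.0
    t2: float = 0.75
    t3: float = 0.0
    sigma_prime_override: float | None = None
    frontend: FrontendConfig = field(default_factory=FrontendConfig)
    center: tuple[float, float] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.tuples) < 1:
            raise ParameterError("an S-COSFIRE filter needs at least one tuple")

    @property
    def rho_max(self) -> float:
        return max(rho for _, rho, _ in self.tuples)

    @property
    def sigma_prime(self) -> float:
        if self.sigma_prime_override is not None:
            return self.sigma_prime_override
        return sigma_prime(self.rho_max)

    @property
    def wavelengths(self) -> set[float]:
        out: set[float] = set()
        for vf, _, _ in self.tuples:
            out |= vf.wavelengths
        return out

    def context(self, image: np.ndarray) -> ResponseContext:
        return ResponseContext(
            image,
            self.frontend.bank_for(self.wavelengths),
            self.frontend.suppression,
        )


def strict_local_maxima(m: np.ndarray) -> list[tuple[int, int]]:
    """Strict 8-neighbor local maxima of a nonnegative map.

    An equal-valued plateau counts as one maximum if it exceeds every pixel
    adjacent to it; the lexicographically smallest (iy, ix) of the plateau
    is kept.  Values below 1e-9 of the global maximum are ignored (numerical
    noise floor of the FFT-based front end).  Returned sorted by descending
    value, ties broken lexicographically.
    """
    gmax = float(m.max()) if m.size else 0.0
    if gmax <= 0:
        return []
    eps = 1e-9 * gmax
    fp = np.ones((3, 3), dtype=bool)
    fp[1, 1] = False
    neigh = ndimage.maximum_filter(m, footprint=fp, mode="constant")
    strict = (m > neigh) & (m > eps)
    ys, xs = np.nonzero(strict)
    out = [(int(y), int(x)) for y, x in zip(ys, xs)]

    plateau = (m >= neigh) & ~strict & (m > eps)
    if plateau.any():
        labels, n = ndimage.label(plateau, structure=np.ones((3, 3), dtype=int))
        h, w = m.shape
        for lab, sl in enumerate(ndimage.find_objects(labels), 1):
            if sl is None:
                continue
            y0 = max(sl[0].start - 1, 0)
            y1 = min(sl[0].stop + 1, h)
            x0 = max(sl[1].start - 1, 0)
            x1 = min(sl[1].stop + 1, w)
            sub = m[y0:y1, x0:x1]
            comp = labels[y0:y1, x0:x1] == lab
            v = sub[comp].max()
            top = comp & (sub == v)
            ring = ndimage.binary_dilation(top, np.ones((3, 3), dtype=bool)) & ~top
            if ring.any() and sub[ring].max() >= v:
                continue
            cys, cxs = np.nonzero(top)
            i = np.lexsort((cxs, cys))[0]
            out.append((int(cys[i]) + y0, int(cxs[i]) + x0))
    out.sort(key=lambda p: (-m[p], p[0], p[1]))
    return out


def configure_s_cosfire(
    prototype: np.ndarray,
    center: tuple[float, float],
    bank: Sequence[VCosfireFilter],
    t1: float = 0.0,
    t2: float = 0.75,
    blur: BlurParams | None = None,
    t3: float = 0.0,
    frontend: FrontendConfig | None = None,
    source: str = "",
) -> SCosfireFilter:
    """Configure a shape filter from a prototype image and a point of interest.

    Every bank filter is applied to the prototype; candidate points are the
    strict 8-neighbor local maxima of the per-pixel bank maximum whose value
    reaches ``t2`` x the global maximum of that map.  Each candidate point
    becomes one tuple per bank filter responding within ``t2`` of the local
    best there, at polar position (rho, phi) relative to ``center``.
    """
    if not bank:
        raise ParameterError("vertex-filter bank must be non-empty")
    h, w = prototype.shape
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ParameterError("center must lie inside the image")
    if frontend is None:
        frontend = FrontendConfig()
    wavelengths: set[float] = set()
    for vf in bank:
        wavelengths |= vf.wavelengths
    ctx = ResponseContext(prototype, frontend.bank_for(wavelengths),
                          frontend.suppression)
    responses = np.stack([ctx.v_response(vf) for vf in bank])
    maxmap = responses.max(axis=0)
    global_max = float(maxmap.max())
    if global_max <= 0:
        raise ConfigurationError("prototype drives no vertex filter")
    points = [
        (iy, ix) for iy, ix in strict_local_maxima(maxmap)
        if maxmap[iy, ix] >= t2 * global_max
    ]
    if not points:
        raise ConfigurationError("no local maxima above the selection threshold")
    tuples: list[tuple[VCosfireFilter, float, float]] = []
    for iy, ix in points:
        rho = math.hypot(ix - cx, iy - cy)
        phi = math.atan2(iy - cy, ix - cx) % (2 * math.pi)
        local_best = float(responses[:, iy, ix].max())
        for vf, r in zip(bank, responses[:, iy, ix]):
            if r >= t2 * local_best:
                tuples.append((vf, rho, phi))
    if blur is None:
        blur = BlurParams(0.1, 0.0853)
    return SCosfireFilter(
        tuple(tuples), blur, t1=t1, t2=t2, t3=t3,
        frontend=frontend, center=(float(cx), float(cy)), source=source,
    )


def apply_s_cosfire(
    image_or_ctx: np.ndarray | ResponseContext,
    filt: SCosfireFilter,
) -> np.ndarray:
    """Response map of a shape filter.

    Each tuple's vertex-filter response is thresholded at ``t1``, dilated
    with the Gaussian-weighted maximum of std sigma0 + alpha*rho, shifted to
    the support center, and the maps are combined by the weighted geometric
    mean (weights from sigma_prime); the output is thresholded at ``t3``.
    """
    if isinstance(image_or_ctx, ResponseContext):
        ctx = image_or_ctx
    else:
        ctx = filt.context(image_or_ctx)
    maps = []
    rhos = []
    shape = ctx.image.shape
    for vf, rho, phi in filt.tuples:
        sigma = filt.blur.sigma(rho)
        d = ctx.v_dilated(vf, filt.t1, sigma)
        dx = -rho * math.cos(phi)
        dy = -rho * math.sin(phi)
        maps.append(shift_crop(d, sigma, int(round(dx)), int(round(dy)), shape))
        rhos.append(rho)
    return weighted_geometric_mean(
        maps, rhos, sp=filt.sigma_prime, t3=filt.t3
    )


def rotate_s(filt: SCosfireFilter, psi: float) -> SCosfireFilter:
    """Filter selective for the prototype rotated by psi: each vertex filter
    is rotated and each polar angle offset by psi; radii (and hence
    sigma_prime) are unchanged."""
    new = tuple(
        (transform_v_filter(vf, psi=psi), rho, (phi + psi) % (2 * math.pi))
        for vf, rho, phi in filt.tuples
    )
    return replace(filt, tuples=new)


def scale_s(filt: SCosfireFilter, upsilon: float) -> SCosfireFilter:
    """Filter selective for the prototype scaled by upsilon: vertex filters,
    radii, and (via rho_max) sigma_prime all scale."""
    if upsilon <= 0:
        raise ParameterError(f"scale factor must be > 0, got {upsilon}")
    new = tuple(
        (transform_v_filter(vf, upsilon=upsilon), rho * upsilon, phi)
        for vf, rho, phi in filt.tuples
    )
    override = filt.sigma_prime_override
    if override is not None:
        override = override * upsilon
    return replace(filt, tuples=new, sigma_prime_override=override)


def reflect_s(filt: SCosfireFilter) -> SCosfireFilter:
    """Filter selective for the prototype reflected about the y axis."""
    new = tuple(
        (transform_v_filter(vf, reflect=True), rho,
         (math.pi - phi) % (2 * math.pi))
        for vf, rho, phi in filt.tuples
    )
    return replace(filt, tuples=new)


@dataclass(frozen=True)
class InvarianceSpec:
    """Geometric-transform grid for tolerant detection.

    ``rotations`` and ``scales`` are explicit value tuples; ``reflect``
    additionally evaluates the mirrored filter at every (psi, upsilon).
    """

    rotations: tuple[float, ...] = (0.0,)
    scales: tuple[float, ...] = (1.0,)
    reflect: bool = False

    def __post_init__(self) -> None:
        if not self.rotations or not self.scales:
            raise ParameterError("rotation and scale sets must be non-empty")
        if any(u <= 0 for u in self.scales):
            raise ParameterError("all scale factors must be > 0")
        object.__setattr__(
            self, "rotations",
            tuple(p % (2 * math.pi) for p in self.rotations),
        )

    @classmethod
    def rotations_equidistant(cls, n_psi: int, **kw) -> "InvarianceSpec":
        return cls(rotations=tuple(2 * math.pi * i / n_psi for i in range(n_psi)),
                   **kw)

    @classmethod
    def scale_grid(cls, i_range: Sequence[int] = (-1, 0, 1), **kw) -> "InvarianceSpec":
        """Half-octave scale grid 2^(i/2) for integer i."""
        return cls(scales=tuple(2.0 ** (i / 2.0) for i in i_range), **kw)


@dataclass(frozen=True)
class TransformLabel:
    psi: float
    upsilon: float
    reflected: bool


def invariant_response(
    image: np.ndarray,
    filt: SCosfireFilter,
    spec: InvarianceSpec,
) -> tuple[np.ndarray, np.ndarray, list[TransformLabel]]:
    """Transform-tolerant response: pixelwise max over the transform grid.

    Evaluates ``rotate_s(scale_s(filter-or-mirror, upsilon), psi)`` for every
    combination in ``spec`` on a shared response context and takes the
    pixelwise maximum.  Returns ``(response, label_index, labels)`` where
    ``labels[label_index[iy, ix]]`` is the transform that achieved the
    maximum at each pixel.
    """
    variants: list[tuple[TransformLabel, SCosfireFilter]] = []
    bases = [(False, filt)]
    if spec.reflect:
        bases.append((True, reflect_s(filt)))
    for reflected, base in bases:
        for u in spec.scales:
            scaled = scale_s(base, u) if u != 1.0 else base
            for p in spec.rotations:
                g = rotate_s(scaled, p) if p != 0.0 else scaled
                variants.append((TransformLabel(p, u, reflected), g))

    wavelengths: set[float] = set()
    for _, g in variants:
        wavelengths |= g.wavelengths
    ctx = ResponseContext(
        image, filt.frontend.bank_for(wavelengths), filt.frontend.suppression
    )
    out = np.zeros(ctx.image.shape, dtype=float)
    label_idx = np.zeros(ctx.image.shape, dtype=int)
    labels = [lab for lab, _ in variants]
    for i, (_, g) in enumerate(variants):
        r = apply_s_cosfire(ctx, g)
        better = r > out
        label_idx[better] = i
        np.maximum(out, r, out=out)
    return out, label_idx, labels
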