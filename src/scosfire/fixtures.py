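"""Deterministic synthetic test stimuli.

Renders the contour stimuli used throughout the package: outlined polygons
(triangles, squares), Kanizsa-style inducer discs, partial and scrambled
shape variants, and composite scenes with ground-truth tables.  All images
are float arrays in [0, 1], white contours on a black background, stored in
the math frame (``img[iy, ix]``, y up).  Rendering is deterministic: a fixed
seed re-renders byte-identical images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "blank",
    "draw_segments",
    "make_triangle",
    "make_kanizsa_triangle",
    "make_square",
    "make_fig1_variant",
    "SceneSpec",
    "ShapeItem",
    "make_scene",
]

DEFAULT_LINE_WIDTH = 3.0


class FixtureError(ValueError):
    pass


def blank(canvas: tuple[int, int]) -> np.ndarray:
    """All-zero canvas of shape (height, width)."""
    h, w = canvas
    return np.zeros((int(h), int(w)), dtype=float)


def _segment_mask(
    shape: tuple[int, int],
    p0: tuple[float, float],
    p1: tuple[float, float],
    width: float,
) -> np.ndarray:
    """Anti-aliased butt-capped segment of the given stroke width.

    Intensity falls linearly from 1 to 0 over one pixel at the stroke edge,
    both across the stroke and at its ends (butt caps, so the covered area
    scales exactly with segment length).
    """
    h, w_img = shape
    x0, y0 = p0
    x1, y1 = p1
    ex, ey = x1 - x0, y1 - y0
    length = math.hypot(ex, ey)
    if length == 0:
        length = 1e-9
    ux, uy = ex / length, ey / length
    half = width / 2.0

    pad = int(math.ceil(half + 2))
    ix_lo = max(0, int(math.floor(min(x0, x1))) - pad)
    ix_hi = min(w_img, int(math.ceil(max(x0, x1))) + pad + 1)
    iy_lo = max(0, int(math.floor(min(y0, y1))) - pad)
    iy_hi = min(h, int(math.ceil(max(y0, y1))) + pad + 1)
    if ix_lo >= ix_hi or iy_lo >= iy_hi:
        return np.zeros(shape, dtype=float)

    ys, xs = np.mgrid[iy_lo:iy_hi, ix_lo:ix_hi]
    rx = xs - x0
    ry = ys - y0
    along = rx * ux + ry * uy
    across = np.abs(-rx * uy + ry * ux)

    across_cov = np.clip(half + 0.5 - across, 0.0, 1.0)
    end_cov = np.clip(along + 0.5, 0.0, 1.0) * np.clip(length - along + 0.5, 0.0, 1.0)
    out = np.zeros(shape, dtype=float)
    out[iy_lo:iy_hi, ix_lo:ix_hi] = across_cov * end_cov
    return out


def draw_segments(
    canvas: np.ndarray,
    segments: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    width: float = DEFAULT_LINE_WIDTH,
    contrast: float = 1.0,
) -> np.ndarray:
    """Composite anti-aliased segments onto a canvas by pixelwise maximum."""
    out = canvas.copy()
    for p0, p1 in segments:
        np.maximum(out, contrast * _segment_mask(out.shape, p0, p1, width), out=out)
    return out


def _polygon_vertices(
    center: tuple[float, float], radius: float, angles: Sequence[float]
) -> list[tuple[float, float]]:
    cx, cy = center
    return [(cx + radius * math.cos(a), cy + radius * math.sin(a)) for a in angles]


def _check_fits(canvas: tuple[int, int], center: tuple[float, float], extent: float) -> None:
    h, w = canvas
    cx, cy = center
    if extent <= 0:
        raise FixtureError(f"shape extent must be > 0, got {extent}")
    if cx - extent < 0 or cx + extent >= w or cy - extent < 0 or cy + extent >= h:
        raise FixtureError(
            f"shape of extent {extent} at {center} does not fit a {w}x{h} canvas"
        )


def make_triangle(
    circumradius: float,
    center: tuple[float, float] | None = None,
    apex_angle_position: float = math.pi / 2,
    canvas: tuple[int, int] = (512, 512),
    line_width: float = DEFAULT_LINE_WIDTH,
    contrast: float = 1.0,
) -> np.ndarray:
    """Equilateral triangle outline.

    Vertices lie at polar angles ``apex + {0, 2pi/3, 4pi/3}`` at distance
    ``circumradius`` from ``center`` (canvas center by default).  The default
    apex position pi/2 puts one vertex due north.
    """
    h, w = canvas
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    _check_fits(canvas, center, circumradius)
    angles = [apex_angle_position + k * 2.0 * math.pi / 3.0 for k in range(3)]
    verts = _polygon_vertices(center, circumradius, angles)
    segs = [(verts[i], verts[(i + 1) % 3]) for i in range(3)]
    return draw_segments(blank(canvas), segs, line_width, contrast)


def make_square(
    half_side: float,
    center: tuple[float, float] | None = None,
    canvas: tuple[int, int] = (256, 256),
    line_width: float = DEFAULT_LINE_WIDTH,
    contrast: float = 1.0,
    orientation: float = 0.0,
) -> np.ndarray:
    """Square outline with corners at ``center + (+-h, +-h)``, rotated by
    ``orientation`` radians about its center (axis-aligned by default)."""
    hgt, w = canvas
    if center is None:
        center = ((w - 1) / 2.0, (hgt - 1) / 2.0)
    _check_fits(canvas, center, half_side * math.sqrt(2.0))
    segs = _square_segments(half_side, center, orientation)
    return draw_segments(blank(canvas), segs, line_width, contrast)


def _rotate_about(p: tuple[float, float], center: tuple[float, float],
                  angle: float) -> tuple[float, float]:
    cx, cy = center
    dx, dy = p[0] - cx, p[1] - cy
    c, s = math.cos(angle), math.sin(angle)
    return (cx + c * dx - s * dy, cy + s * dx + c * dy)


def _square_segments(half_side: float, center: tuple[float, float],
                     orientation: float = 0.0):
    cx, cy = center
    h = half_side
    c = [(cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h), (cx - h, cy + h)]
    if orientation:
        c = [_rotate_about(p, center, orientation) for p in c]
    return [(c[i], c[(i + 1) % 4]) for i in range(4)]


def make_kanizsa_triangle(
    circumradius: float,
    center: tuple[float, float] | None = None,
    inducer_radius: float | None = None,
    apex_angle_position: float = math.pi / 2,
    canvas: tuple[int, int] = (512, 512),
    contrast: float = 1.0,
    supersample: int = 4,
) -> np.ndarray:
    """Kanizsa-style illusory triangle: three wedge-cut inducer discs.

    A filled disc is placed at each vertex position of the corresponding
    outline triangle; from each disc a wedge of aperture pi/3 is removed,
    bisected by the direction toward the triangle's interior.  The two wedge
    edges therefore meet at the disc center with the same arm directions as
    the outline triangle's corner, and no contour connects the discs.

    ``inducer_radius`` defaults to 0.35x the triangle side length.
    """
    h, w = canvas
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    side = circumradius * math.sqrt(3.0)
    if inducer_radius is None:
        inducer_radius = 0.35 * side
    if inducer_radius >= side / 2.0:
        raise FixtureError("inducer radius must be smaller than half the side length")
    _check_fits(canvas, center, circumradius + inducer_radius)

    aperture = math.pi / 3.0  # equilateral corner angle
    ss = int(supersample)
    out = np.zeros((h, w), dtype=float)
    cx, cy = center
    for k in range(3):
        phi_v = apex_angle_position + k * 2.0 * math.pi / 3.0
        dx_c = cx + circumradius * math.cos(phi_v)
        dy_c = cy + circumradius * math.sin(phi_v)
        # supersampled bounding box around the disc
        r = inducer_radius
        ix_lo = max(0, int(math.floor(dx_c - r - 2)))
        ix_hi = min(w, int(math.ceil(dx_c + r + 2)) + 1)
        iy_lo = max(0, int(math.floor(dy_c - r - 2)))
        iy_hi = min(h, int(math.ceil(dy_c + r + 2)) + 1)
        nby, nbx = iy_hi - iy_lo, ix_hi - ix_lo
        sub_y = iy_lo + (np.arange(nby * ss) + 0.5) / ss - 0.5
        sub_x = ix_lo + (np.arange(nbx * ss) + 0.5) / ss - 0.5
        yy, xx = np.meshgrid(sub_y, sub_x, indexing="ij")
        rx, ry = xx - dx_c, yy - dy_c
        inside = (rx * rx + ry * ry) <= r * r
        ang = np.arctan2(ry, rx)
        bisector = phi_v + math.pi  # wedge points at the interior
        d = np.angle(np.exp(1j * (ang - bisector)))
        wedge = np.abs(d) <= aperture / 2.0
        mask = (inside & ~wedge).astype(float)
        block = mask.reshape(nby, ss, nbx, ss).mean(axis=(1, 3))
        np.maximum(out[iy_lo:iy_hi, ix_lo:ix_hi], contrast * block,
                   out=out[iy_lo:iy_hi, ix_lo:ix_hi])
    return out


def _split_segment(p0, p1, t0: float, t1: float):
    x0, y0 = p0
    x1, y1 = p1
    return (
        (x0 + (x1 - x0) * t0, y0 + (y1 - y0) * t0),
        (x0 + (x1 - x0) * t1, y0 + (y1 - y0) * t1),
    )


def make_fig1_variant(
    kind: str,
    half_side: float = 50.0,
    center: tuple[float, float] | None = None,
    canvas: tuple[int, int] = (256, 256),
    line_width: float = DEFAULT_LINE_WIDTH,
    contrast: float = 1.0,
    seed: int = 0,
    orientation: float = 0.0,
) -> np.ndarray:
    """Perceptual-similarity variants of the square prototype.

    ``partial``
        Square outline with contour deleted except for 25% of its length,
        concentrated as stubs at the four corners (all corner vertices kept).
    ``polygon``
        Closed polygon sharing the square's bottom half (50% of the contour)
        but with a different upper half.
    ``scrambled``
        The square's contour cut into eight parts and displaced to seeded
        random positions: locally identical parts, no global arrangement.
    """
    hgt, w = canvas
    if center is None:
        center = ((w - 1) / 2.0, (hgt - 1) / 2.0)
    cx, cy = center
    h = half_side
    segs = _square_segments(h, center, orientation)

    if kind == "partial":
        keep = []
        for p0, p1 in segs:
            keep.append(_split_segment(p0, p1, 0.0, 0.125))
            keep.append(_split_segment(p0, p1, 0.875, 1.0))
        return draw_segments(blank(canvas), keep, line_width, contrast)

    if kind == "polygon":
        # bottom half of the square (bottom side + lower half of both
        # verticals) closed by a roof through an off-square apex
        pts = [
            (cx - h, cy),
            (cx - h, cy - h),
            (cx + h, cy - h),
            (cx + h, cy),
            (cx, cy + 1.3 * h),
        ]
        if orientation:
            pts = [_rotate_about(p, center, orientation) for p in pts]
        segs2 = [(pts[i], pts[(i + 1) % len(pts)]) for i in range(len(pts))]
        return draw_segments(blank(canvas), segs2, line_width, contrast)

    if kind == "scrambled":
        rng = np.random.default_rng(seed)
        parts = []
        for p0, p1 in segs:
            parts.append(_split_segment(p0, p1, 0.0, 0.5))
            parts.append(_split_segment(p0, p1, 0.5, 1.0))
        img = blank(canvas)
        margin = h / 2 + 4
        for (q0, q1) in parts:
            mx, my = (q0[0] + q1[0]) / 2.0, (q0[1] + q1[1]) / 2.0
            nx = rng.uniform(margin, w - 1 - margin)
            ny = rng.uniform(margin, hgt - 1 - margin)
            shift = (nx - mx, ny - my)
            moved = (
                (q0[0] + shift[0], q0[1] + shift[1]),
                (q1[0] + shift[0], q1[1] + shift[1]),
            )
            img = draw_segments(img, [moved], line_width, contrast)
        return img

    raise FixtureError(f"unknown variant kind: {kind!r}")


@dataclass(frozen=True)
class ShapeItem:
    """One shape in a composite scene."""

    kind: str  # triangle | kanizsa_triangle | square | partial | polygon | scrambled
    center: tuple[float, float]
    size: float  # circumradius (triangles) or half-side (square variants)
    orientation: float = 0.0  # psi, radians
    scale: float = 1.0  # upsilon, applied to size
    line_width: float = DEFAULT_LINE_WIDTH
    contrast: float = 1.0


@dataclass(frozen=True)
class SceneSpec:
    canvas: tuple[int, int]
    items: tuple[ShapeItem, ...] = ()
    seed: int = 0


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Composite scene plus a ground-truth table.

    Returns the rendered canvas (pixelwise max over items) and a DataFrame
    with columns (id, kind, x, y, psi, upsilon) giving each item's center and
    geometric transform relative to its canonical pose.
    """
    img = blank(spec.canvas)
    rows = []
    for i, item in enumerate(spec.items):
        size = item.size * item.scale
        if item.kind == "triangle":
            layer = make_triangle(
                size, item.center, math.pi / 2 + item.orientation, spec.canvas,
                item.line_width, item.contrast,
            )
        elif item.kind == "kanizsa_triangle":
            layer = make_kanizsa_triangle(
                size, item.center,
                apex_angle_position=math.pi / 2 + item.orientation,
                canvas=spec.canvas, contrast=item.contrast,
            )
        elif item.kind == "square":
            layer = make_square(size, item.center, spec.canvas,
                                item.line_width, item.contrast,
                                orientation=item.orientation)
        elif item.kind in ("partial", "polygon", "scrambled"):
            layer = make_fig1_variant(item.kind, size, item.center, spec.canvas,
                                      item.line_width, item.contrast, spec.seed,
                                      orientation=item.orientation)
        else:
            raise FixtureError(f"unknown scene item kind: {item.kind!r}")
        np.maximum(img, layer, out=img)
        rows.append(
            dict(id=i, kind=item.kind, x=item.center[0], y=item.center[1],
                 psi=item.orientation, upsilon=item.scale)
        )
    table = pd.DataFrame(rows, columns=["id", "kind", "x", "y", "psi", "upsilon"])
    return img, table
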