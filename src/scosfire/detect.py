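"""Detection post-processing and filter serialization.

Turns response maps into ranked point detections (strict 8-neighbor maxima
with fractional thresholding and non-maximum suppression) and round-trips
shape filters through a versioned JSON format.  All angles are radians and
all distances pixels; the JSON records the coordinate-frame tag
``math-y-up`` (x rightward, y upward, angles counterclockwise from +x).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BlurParams, CosfireTuple, ParameterError
from .gabor import GaborParams
from .shape import FrontendConfig, SCosfireFilter, TransformLabel, strict_local_maxima
from .vertex import VCosfireFilter, VertexSpec

__all__ = [
    "Detection",
    "local_maxima",
    "detections_frame",
    "save_filter",
    "load_filter",
    "FilterFormatError",
]

FORMAT_NAME = "scosfire-filter"
FORMAT_VERSION = 1
FRAME_TAG = "math-y-up"


@dataclass(frozen=True)
class Detection:
    """One detected shape instance.

    ``x``/``y`` are pixel coordinates in the math frame (y up); ``row`` is
    the raster row for ``y`` given the map height.  ``psi``, ``upsilon`` and
    ``reflected`` name the geometric transform that achieved the score.
    """

    x: float
    y: float
    score: float
    psi: float = 0.0
    upsilon: float = 1.0
    reflected: bool = False
    rank: int = 0


def local_maxima(
    response: np.ndarray,
    t3: float = 0.0,
    top_k: int | None = None,
    min_separation: float = 0.0,
    label_idx: np.ndarray | None = None,
    labels: Sequence[TransformLabel] | None = None,
) -> list[Detection]:
    """Ranked detections from a response map.

    Strict 8-neighbor local maxima with value >= ``t3`` x the global
    maximum, non-max suppressed so that no two detections lie within
    ``min_separation`` pixels, truncated to ``top_k`` strongest if given.
    """
    if not 0.0 <= t3 <= 1.0:
        raise ParameterError("t3 must be in [0, 1]")
    peaks = strict_local_maxima(response)
    gmax = float(response.max()) if response.size else 0.0
    if gmax <= 0:
        return []
    kept: list[tuple[int, int]] = []
    for iy, ix in peaks:  # already sorted by descending value
        if response[iy, ix] < t3 * gmax:
            continue
        if any(math.hypot(ix - qx, iy - qy) < min_separation for qy, qx in kept):
            continue
        kept.append((iy, ix))
        if top_k is not None and len(kept) >= top_k:
            break
    out = []
    for rank, (iy, ix) in enumerate(kept):
        lab = TransformLabel(0.0, 1.0, False)
        if label_idx is not None and labels is not None:
            lab = labels[int(label_idx[iy, ix])]
        out.append(
            Detection(float(ix), float(iy), float(response[iy, ix]),
                      lab.psi, lab.upsilon, lab.reflected, rank)
        )
    return out


def detections_frame(detections: Sequence[Detection], height: int) -> pd.DataFrame:
    """Detections as a table with both math-frame (x, y) and raster (row,
    col) coordinates."""
    rows = []
    for d in detections:
        rows.append(
            dict(rank=d.rank, x=d.x, y=d.y, row=height - 1 - d.y, col=d.x,
                 score=d.score, psi=d.psi, upsilon=d.upsilon,
                 reflected=d.reflected)
        )
    return pd.DataFrame(
        rows, columns=["rank", "x", "y", "row", "col", "score", "psi",
                       "upsilon", "reflected"]
    )


class FilterFormatError(ValueError):
    """Raised for malformed or unsupported filter files."""


def _vertex_to_dict(vf: VCosfireFilter) -> dict:
    d = {
        "t1": vf.t1,
        "blur": {"sigma0": vf.blur.sigma0, "alpha": vf.blur.alpha},
        "tuples": [
            {"wavelength": t.subunit[0], "theta": t.subunit[1],
             "rho": t.rho, "phi": t.phi}
            for t in vf.tuples
        ],
        "spec": None,
    }
    if vf.spec is not None:
        d["spec"] = {"beta": vf.spec.beta, "gamma": vf.spec.gamma,
                     "index": vf.spec.index}
    return d


def _vertex_from_dict(d: dict) -> VCosfireFilter:
    spec = None
    if d.get("spec") is not None:
        s = d["spec"]
        spec = VertexSpec(s["beta"], s["gamma"], s.get("index"))
    return VCosfireFilter(
        tuple(
            CosfireTuple((t["wavelength"], t["theta"]), t["rho"], t["phi"])
            for t in d["tuples"]
        ),
        BlurParams(d["blur"]["sigma0"], d["blur"]["alpha"]),
        d["t1"],
        spec,
    )


def save_filter(filt: SCosfireFilter, path: str | Path) -> None:
    """Serialize a shape filter to versioned JSON (lossless round trip)."""
    doc = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "frame": FRAME_TAG,
        "blur": {"sigma0": filt.blur.sigma0, "alpha": filt.blur.alpha},
        "t1": filt.t1,
        "t2": filt.t2,
        "t3": filt.t3,
        "sigma_prime_override": filt.sigma_prime_override,
        "frontend": {
            "n_orientations": filt.frontend.n_orientations,
            "suppression": filt.frontend.suppression,
            "bandwidth": filt.frontend.params.bandwidth,
            "aspect_ratio": filt.frontend.params.aspect_ratio,
        },
        "center": list(filt.center) if filt.center is not None else None,
        "source": filt.source,
        "tuples": [
            {"vertex": _vertex_to_dict(vf), "rho": rho, "phi": phi}
            for vf, rho, phi in filt.tuples
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_filter(path: str | Path) -> SCosfireFilter:
    """Load a shape filter saved by :func:`save_filter`."""
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise FilterFormatError(f"cannot parse filter file {path}: {e}") from e
    if not isinstance(doc, dict) or doc.get("format") != FORMAT_NAME:
        raise FilterFormatError(f"{path} is not a {FORMAT_NAME} file")
    if doc.get("version") != FORMAT_VERSION:
        raise FilterFormatError(
            f"unsupported filter format version {doc.get('version')!r}"
        )
    try:
        fe = doc["frontend"]
        return SCosfireFilter(
            tuple(
                (_vertex_from_dict(t["vertex"]), t["rho"], t["phi"])
                for t in doc["tuples"]
            ),
            BlurParams(doc["blur"]["sigma0"], doc["blur"]["alpha"]),
            t1=doc["t1"],
            t2=doc["t2"],
            t3=doc["t3"],
            sigma_prime_override=doc.get("sigma_prime_override"),
            frontend=FrontendConfig(
                fe["n_orientations"], fe["suppression"],
                GaborParams(fe["bandwidth"], fe["aspect_ratio"]),
            ),
            center=tuple(doc["center"]) if doc.get("center") else None,
            source=doc.get("source", ""),
        )
    except (KeyError, TypeError) as e:
        raise FilterFormatError(f"malformed filter file {path}: {e}") from e
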