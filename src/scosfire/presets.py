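"""Published parameter presets.

Bundles of the parameter values used in the method's worked examples:

``fig4-triangle``
    The equilateral-triangle / Kanizsa worked example: sigma0 = 0.1,
    alpha = 0.0853, t1 = 0, t2 = 0.75, no surround suppression, single
    wavelength lambda = 4 with 12 orientations (so that every vertex-arm
    direction of the 60-filter bank falls on a channel).

``keyword-3.1``
    Handwritten-keyword spotting: t1 = 0.1, t2 = 0.75, t3 = 0.1,
    sigma0 = 0.67, alpha = 0.1.

``shoes-3.2``
    Object spotting in cluttered scenes: Gabor bank lambda = 4 with 16
    orientations, t1 = 0.3, isotropic surround suppression, sigma0 = 0.1,
    alpha = 0.67, t3 = 0.1, top-2 detections per image, reflection
    invariance with scales {3/4, 1, 5/4} and rotations {-pi/8, 0, pi/8}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import BlurParams
from .shape import FrontendConfig, InvarianceSpec

__all__ = ["Preset", "preset", "PRESET_NAMES"]


@dataclass(frozen=True)
class Preset:
    name: str
    blur: BlurParams
    t1: float
    t2: float
    t3: float
    frontend: FrontendConfig
    invariance: InvarianceSpec
    top_k: int | None = None
    config_t1: float = 0.3  # vertex-configuration gate (concentric circles)
    # Threshold the vertex filters apply internally to their Gabor inputs.
    # Distinct from t1, which thresholds the vertex-filter *responses* at the
    # shape level; without it sub-threshold contour tails keep the geometric
    # mean from ever reaching exact zero.
    v_t1: float = 0.1


def preset(name: str) -> Preset:
    """Parameter bundle for a named worked example."""
    if name == "fig4-triangle":
        return Preset(
            name=name,
            blur=BlurParams(0.1, 0.0853),
            t1=0.0,
            t2=0.75,
            t3=0.1,
            frontend=FrontendConfig(n_orientations=12, suppression=0.0),
            invariance=InvarianceSpec(),
            top_k=None,
        )
    if name == "keyword-3.1":
        return Preset(
            name=name,
            blur=BlurParams(0.67, 0.1),
            t1=0.1,
            t2=0.75,
            t3=0.1,
            frontend=FrontendConfig(n_orientations=12, suppression=0.0),
            invariance=InvarianceSpec(),
            top_k=None,
        )
    if name == "shoes-3.2":
        return Preset(
            name=name,
            blur=BlurParams(0.1, 0.67),
            t1=0.3,
            t2=0.75,
            t3=0.1,
            frontend=FrontendConfig(n_orientations=16, suppression=1.0),
            invariance=InvarianceSpec(
                rotations=(-math.pi / 8, 0.0, math.pi / 8),
                scales=(0.75, 1.0, 1.25),
                reflect=True,
            ),
            top_k=2,
            v_t1=0.3,
        )
    raise KeyError(f"unknown preset: {name!r}")


PRESET_NAMES = ("fig4-triangle", "keyword-3.1", "shoes-3.2")
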