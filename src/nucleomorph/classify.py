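"""Cell-type assignment from nuclear size and shape.

Spread Arabidopsis leaf nuclei fall into four microscopically sortable
classes: small spherical guard-cell nuclei (GC), medium elliptic/irregular
parenchyma/pavement nuclei (PC), elongated vascular nuclei (VC) and large
endopolyploid nuclei (EC). The rule is deterministic and ordered —
elongation first, so that a large elongated vascular nucleus is never
mistaken for an endopolyploid one:

1. VC if aspect_ratio >= r_vc
2. GC if area <= A_gc and circularity >= c_gc
3. EC if area >= A_ec
4. PC otherwise

The numeric cutoffs are package defaults (the sorting in the field is done
qualitatively by eye); all four are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import regionprops

from .errors import MeasurementError

CELL_TYPES = ("GC", "PC", "VC", "EC")


@dataclass(frozen=True)
class ShapeDescriptors:
    area: float           # µm²
    circularity: float    # 4π·area / perimeter², in (0, 1] up to raster error
    aspect_ratio: float   # major / minor axis of the best-fit ellipse, >= 1


@dataclass(frozen=True)
class ClassThresholds:
    A_gc: float = 30.0    # µm², max guard-cell area
    A_ec: float = 120.0   # µm², min endopolyploid area
    c_gc: float = 0.85    # min guard-cell circularity
    r_vc: float = 3.0     # min vascular aspect ratio


def shape_descriptors(mask: np.ndarray, pixel_size: float) -> ShapeDescriptors:
    """Area, circularity and aspect ratio of a nucleus mask.

    Perimeter uses the Crofton estimator, which is less biased on digitized
    convex shapes than pixel-edge counting; circularity can slightly exceed
    1 on small rasters (bounded by ~1.05).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MeasurementError("empty mask has no shape")
    props = regionprops(mask.astype(np.uint8))[0]
    area = props.area * pixel_size**2
    perimeter = props.perimeter_crofton * pixel_size
    circularity = 4.0 * math.pi * area / perimeter**2 if perimeter > 0 else 1.0
    minor = max(props.axis_minor_length, 1.0)  # guard degenerate 1-px-wide masks
    aspect = props.axis_major_length / minor
    return ShapeDescriptors(area=area, circularity=circularity, aspect_ratio=max(aspect, 1.0))


def classify(
    desc: ShapeDescriptors, thresholds: ClassThresholds | None = None
) -> str:
    """Map shape descriptors to one of GC / PC / VC / EC (total, deterministic)."""
    th = thresholds or ClassThresholds()
    if not all(
        math.isfinite(v) and v > 0
        for v in (desc.area, desc.circularity, desc.aspect_ratio)
    ):
        raise MeasurementError(f"non-finite or non-positive shape descriptors: {desc}")
    if desc.aspect_ratio >= th.r_vc:
        return "VC"
    if desc.area <= th.A_gc and desc.circularity >= th.c_gc:
        return "GC"
    if desc.area >= th.A_ec:
        return "EC"
    return "PC"
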