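"""Per-nucleus morphometric parameters and ploidy (C-value) calibration.

The parameter set profiles chromatin organisation of one spread nucleus from
its segmented image:

``size``            nucleus area (pixels and µm²)
``content``         integrated background-subtracted fluorescence — a relative
                    DNA amount
``density``         content / area (DNA concentration)
``heterogeneity``   variation in DNA density across the nucleus
``rhf``             relative heterochromatin fraction — summed chromocenter
                    fluorescence over total nuclear fluorescence
``n_cc``            number of chromocenters

Contents partition exactly: nucleus content = chromocenter content +
euchromatin content (nucleolus pixels count as euchromatin; there is no
dedicated nucleolus mask). C-values are calibrated against the guard-cell
anchor: guard-cell nuclei are assumed diploid (2C), and every nucleus gets
``c_value = 2 × content / mean(guard-cell content)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import CalibrationError, MeasurementError
from .segment import SegmentationResult
from .simulate import NucleusImage


@dataclass
class MorphometricRecord:
    nucleus_id: str
    size_px: int
    size_um2: float
    content_nu: float
    density_nu: float            # content / µm²
    size_cc_px: int
    size_cc_um2: float
    content_cc: float
    density_cc: float            # NaN when n_cc == 0
    density_eu: float
    heterogeneity: float
    rhf: float
    n_cc: int
    c_value: float = float("nan")
    cell_type: str = ""
    group: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def heterogeneity(values: np.ndarray, mode: str = "cv") -> float:
    """Variation in DNA density over (background-subtracted) nucleus pixels.

    mode="cv": coefficient of variation (sd / mean).
    mode="deviating_fraction": fraction of pixels deviating more than 10%
    from the mean, the definition used by legacy image-analysis packages.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise MeasurementError("heterogeneity needs at least 2 pixels")
    mean = float(values.mean())
    if mean == 0:
        raise MeasurementError("heterogeneity undefined for zero-mean intensities")
    if mode == "cv":
        return float(values.std()) / mean
    if mode == "deviating_fraction":
        return float(np.mean(np.abs(values - mean) > 0.10 * abs(mean)))
    raise MeasurementError(f"unknown heterogeneity mode {mode!r}")


def measure(
    img: NucleusImage,
    seg: SegmentationResult,
    heterogeneity_mode: str = "cv",
) -> MorphometricRecord:
    """Compute the morphometric parameter vector for one segmented nucleus.

    All intensity sums are background-subtracted; the exact pixel partition
    nucleus = chromocenters + euchromatin guarantees
    ``content_nu == content_cc + content_eu``.
    """
    mask = seg.nucleus_mask
    if not mask.any():
        raise MeasurementError("empty nucleus mask")
    pixels = np.asarray(img.pixels, dtype=np.float64)
    sub = pixels - seg.background_level
    px2 = img.pixel_size**2

    cc_mask = (seg.cc_labels > 0) & mask
    eu_mask = mask & ~cc_mask

    size_px = int(mask.sum())
    size_cc_px = int(cc_mask.sum())
    content_nu = float(sub[mask].sum())
    content_cc = float(sub[cc_mask].sum())
    if content_nu <= 0:
        raise MeasurementError("non-positive integrated nuclear intensity")

    size_um2 = size_px * px2
    size_cc_um2 = size_cc_px * px2
    size_eu_um2 = (size_px - size_cc_px) * px2
    density_cc = content_cc / size_cc_um2 if size_cc_px else float("nan")
    density_eu = (
        (content_nu - content_cc) / size_eu_um2 if size_px > size_cc_px else float("nan")
    )
    return MorphometricRecord(
        nucleus_id=img.source_id,
        size_px=size_px,
        size_um2=size_um2,
        content_nu=content_nu,
        density_nu=content_nu / size_um2,
        size_cc_px=size_cc_px,
        size_cc_um2=size_cc_um2,
        content_cc=content_cc,
        density_cc=density_cc,
        density_eu=density_eu,
        heterogeneity=heterogeneity(sub[mask], mode=heterogeneity_mode),
        rhf=content_cc / content_nu,
        n_cc=int(seg.cc_labels.max()),
    )


def estimate_ploidy(
    records: Sequence[MorphometricRecord],
    anchor_type: str = "GC",
    anchor_c: float = 2.0,
) -> list[MorphometricRecord]:
    """Calibrate C-values against an anchor cell type (guard cells = 2C).

    Returns new records with ``c_value = anchor_c × content_nu /
    mean(content_nu over anchor-type records)``; inputs are not mutated.
    """
    anchor = [r.content_nu for r in records if r.cell_type == anchor_type]
    if not anchor:
        raise CalibrationError(
            f"no records of anchor type {anchor_type!r} for ploidy calibration"
        )
    anchor_mean = float(np.mean(anchor))
    return [
        replace(r, c_value=anchor_c * r.content_nu / anchor_mean) for r in records
    ]
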