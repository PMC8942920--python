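"""Threshold-based segmentation of nuclei and chromocenters.

The nucleus is found by Otsu thresholding of the whole-image histogram
followed by connected-component selection and hole filling; the dim
extranuclear background level is estimated outside a dilation of the
foreground. Chromocenters are the bright 8-connected components whose
background-subtracted intensity exceeds the nucleus mean by ``cc_k``
standard deviations (computed over background-subtracted nucleus pixels),
after discarding components below ``min_cc_area`` pixels. Because both
thresholds are defined relative to image statistics, the segmentation is
invariant under rescaling of the intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .errors import EmptySegmentationError, FormatError
from .simulate import NucleusImage

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


@dataclass
class SegmentationConfig:
    cc_k: float = 2.0            # chromocenter threshold: mean + k·sd
    min_cc_area: int = 4         # pixels
    min_nucleus_area: int = 50   # pixels; rejects noise speckles
    background_dilation: int = 5  # pixels of clearance around foreground


@dataclass
class SegmentationResult:
    nucleus_mask: np.ndarray     # bool, same shape as image
    cc_labels: np.ndarray        # int; 0 = non-CC, k>0 = k-th chromocenter
    background_level: float
    nucleus_threshold: float
    cc_threshold: float          # absolute intensity units

    @property
    def n_cc(self) -> int:
        return int(self.cc_labels.max())


def read_image(
    path: str | Path,
    channel: str | int | None = None,
    pixel_size: float | None = None,
) -> NucleusImage:
    """Read a grayscale (or RGB + channel) TIFF without rescaling intensities.

    ``pixel_size`` (µm/pixel) overrides any value stored in the file's
    metadata; if neither is available a FormatError is raised.
    """
    import tifffile

    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            meta = (tif.shaped_metadata or [{}])[0]
    except (FileNotFoundError, tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc

    if arr.ndim == 3:
        if channel is None:
            raise FormatError(
                f"{path} is multi-channel ({arr.shape[-1]} planes); "
                "name the DAPI channel explicitly (e.g. channel='blue')"
            )
        idx = _CHANNELS.get(channel, channel) if isinstance(channel, str) else channel
        if not isinstance(idx, int) or not (0 <= idx < arr.shape[-1]):
            raise FormatError(f"channel {channel!r} not available in {path}")
        arr = arr[..., idx]
    elif arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2D image, got shape {arr.shape}")

    if pixel_size is None:
        pixel_size = meta.get("pixel_size_um")
    if pixel_size is None:
        raise FormatError(f"{path}: no pixel size in metadata; pass pixel_size=")
    bit_depth = int(meta.get("bit_depth", 8 * arr.dtype.itemsize))
    return NucleusImage(
        pixels=arr, pixel_size=float(pixel_size), bit_depth=bit_depth,
        source_id=path.stem,
    )


def _foreground(img: NucleusImage) -> tuple[np.ndarray, float]:
    pixels = np.asarray(img.pixels, dtype=np.float64)
    if np.ptp(pixels) == 0:
        raise EmptySegmentationError("uniform-intensity image: no object to segment")
    thr = float(threshold_otsu(pixels))
    fg = pixels > thr
    if not fg.any() or fg.all():
        raise EmptySegmentationError("thresholding found no distinct foreground object")
    return fg, thr


def _background_level(pixels: np.ndarray, fg: np.ndarray, dilation: int) -> float:
    dilated = ndimage.binary_dilation(fg, structure=disk(dilation))
    outside = ~dilated
    if not outside.any():
        raise EmptySegmentationError("no background pixels outside the dilated foreground")
    return float(pixels[outside].mean())


def segment_all_nuclei(
    img: NucleusImage, config: SegmentationConfig | None = None
) -> tuple[list[np.ndarray], float, float]:
    """All nucleus masks in a field, largest first, plus background and threshold."""
    config = config or SegmentationConfig()
    pixels = np.asarray(img.pixels, dtype=np.float64)
    fg, thr = _foreground(img)
    labels = cc_label(fg, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    order = [k for k in np.argsort(sizes)[::-1] if sizes[k] >= config.min_nucleus_area]
    if not order:
        raise EmptySegmentationError(
            f"no object of at least {config.min_nucleus_area} pixels found"
        )
    masks = [ndimage.binary_fill_holes(labels == k) for k in order]
    background = _background_level(pixels, fg, config.background_dilation)
    return masks, background, thr


def segment_nucleus(
    img: NucleusImage, config: SegmentationConfig | None = None
) -> tuple[np.ndarray, float, float]:
    """Mask of the largest nucleus, background level and Otsu threshold."""
    masks, background, thr = segment_all_nuclei(img, config)
    return masks[0], background, thr


def segment_chromocenters(
    img: NucleusImage,
    nucleus_mask: np.ndarray,
    background_level: float,
    config: SegmentationConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Label chromocenters inside the nucleus; returns (labels, cc_threshold).

    Labels are sorted by decreasing integrated (background-subtracted)
    intensity, ties broken by centroid row then column; zero chromocenters
    is a valid outcome. ``cc_threshold`` is returned in absolute intensity
    units so it is directly comparable with the nucleus threshold.
    """
    config = config or SegmentationConfig()
    if not nucleus_mask.any():
        raise EmptySegmentationError("empty nucleus mask")
    pixels = np.asarray(img.pixels, dtype=np.float64)
    sub = pixels - background_level
    vals = sub[nucleus_mask]
    mu, sigma = float(vals.mean()), float(vals.std())
    thr_rel = mu + config.cc_k * sigma
    cand = (sub > thr_rel) & nucleus_mask
    raw = cc_label(cand, connectivity=2)

    comps = []
    for k in range(1, raw.max() + 1):
        m = raw == k
        area = int(m.sum())
        if area < config.min_cc_area:
            continue
        rows, cols = np.nonzero(m)
        comps.append((-float(sub[m].sum()), float(rows.mean()), float(cols.mean()), m))
    comps.sort(key=lambda c: c[:3])

    labels = np.zeros(pixels.shape, dtype=np.int32)
    for new, (_, _, _, m) in enumerate(comps, start=1):
        labels[m] = new
    return labels, thr_rel + background_level


def segment(
    img: NucleusImage, config: SegmentationConfig | None = None
) -> SegmentationResult:
    """Full single-nucleus segmentation: nucleus mask + chromocenter labels."""
    config = config or SegmentationConfig()
    mask, background, nu_thr = segment_nucleus(img, config)
    labels, cc_thr = segment_chromocenters(img, mask, background, config)
    return SegmentationResult(
        nucleus_mask=mask,
        cc_labels=labels,
        background_level=background,
        nucleus_threshold=nu_thr,
        cc_threshold=cc_thr,
    )
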