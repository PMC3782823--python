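"""Breast-profile preprocessing: binarize, clean background, crop, downsample, enhance.

The stages separate the breast (plus pectoral) profile from the background,
erase radio-opaque labels/markers and background noise, crop to the breast
region of interest, reduce resolution by block averaging, and median-filter
for enhancement.  Stage order in the pipeline: binarize -> artifact removal
-> crop -> downsample -> median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import label as cc_label
from skimage.morphology import disk, opening


class NoBreastFoundError(ValueError):
    """Raised when thresholding leaves no foreground to call a breast."""


@dataclass(frozen=True)
class CropResult:
    """A cropped view plus enough provenance to map results back to the source."""

    image: np.ndarray
    offset: tuple[int, int]  # (row, col) of the crop origin in the source
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open


def binarize_breast(
    image: np.ndarray,
    threshold: float | None = None,
    method: str = "triangle",
    opening_radius: int = 2,
) -> np.ndarray:
    """Segment the breast profile as the largest bright connected component.

    A global threshold separates tissue from background; morphological
    opening with a disk of ``opening_radius`` removes thin scanning
    artifacts; keeping only the largest 8-connected component discards
    labels and markers, which are disconnected from the breast.

    The automatic threshold (used when ``threshold`` is None) is the
    triangle method by default — suited to mammograms, whose histograms are
    dominated by a dark background peak; Otsu's criterion tends to split
    between tissue classes instead of background vs breast.  ``method`` may
    be "triangle" or "otsu"; a numeric ``threshold`` overrides both.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if threshold is None:
        chooser = {"triangle": threshold_triangle, "otsu": threshold_otsu}
        if method not in chooser:
            raise ValueError(f"unknown threshold method {method!r}")
        try:
            threshold = chooser[method](image)
        except ValueError:  # constant image: no threshold separates anything
            raise NoBreastFoundError("no breast found: image is constant") from None
    fg = image > threshold
    if opening_radius > 0:
        fg = opening(fg, disk(opening_radius))
    if not fg.any():
        raise NoBreastFoundError("no breast found: empty foreground after thresholding")
    comps, n = cc_label(fg, connectivity=2, return_num=True)
    sizes = np.bincount(comps.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1  # ties: lowest label = first in raster order
    return (comps == keep).astype(np.uint8)


def remove_background_artifacts(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace everything outside the breast mask with black pixels."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask {mask.shape}")
    out = image.copy()
    out[mask == 0] = 0
    return out


def crop_to_breast(image: np.ndarray, mask: np.ndarray, margin: int = 0) -> CropResult:
    """Crop to the mask's bounding box dilated by ``margin`` and clipped to bounds."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask {mask.shape}")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask: nothing to crop to")
    r0 = max(int(rows.min()) - margin, 0)
    c0 = max(int(cols.min()) - margin, 0)
    r1 = min(int(rows.max()) + 1 + margin, image.shape[0])
    c1 = min(int(cols.max()) + 1 + margin, image.shape[1])
    return CropResult(image=image[r0:r1, c0:c1].copy(), offset=(r0, c0), bbox=(r0, c0, r1, c1))


def downsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsample by an integer factor (partial edge blocks allowed).

    Each output pixel is the mean of its ``factor``x``factor`` block, averaged
    over the pixels actually present for partial blocks at the bottom/right
    edges, rounded half-up to an integer gray level.
    """
    image = np.asarray(image)
    factor = int(factor)
    if factor < 1:
        raise ValueError("downsample factor must be >= 1")
    if factor == 1:
        return image.astype(np.uint8).copy()
    h, w = image.shape
    row_idx = np.arange(0, h, factor)
    col_idx = np.arange(0, w, factor)
    sums = np.add.reduceat(np.add.reduceat(image.astype(np.float64), row_idx, axis=0),
                           col_idx, axis=1)
    rcount = np.diff(np.append(row_idx, h)).astype(np.float64)
    ccount = np.diff(np.append(col_idx, w)).astype(np.float64)
    means = sums / np.outer(rcount, ccount)
    return np.floor(means + 0.5).astype(np.uint8)  # round half-up


def median_enhance(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter with a kernel x kernel window; borders use edge replication."""
    kernel = int(kernel)
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("median kernel must be an odd positive integer")
    image = np.asarray(image)
    if kernel == 1:
        return image.astype(np.uint8).copy()
    return ndimage.median_filter(image, size=kernel, mode="nearest").astype(np.uint8)
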