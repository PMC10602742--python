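"""Leaf/background segmentation and whole-leaf spectrum extraction.

The region of interest is the whole leaf.  A single gray band is taken from
the calibrated cube (800 nm for the Vis-NIR camera, 1000 nm for SWIR, where
plant tissue sits on its near-infrared high-reflectance plateau and is much
brighter than the scanning platform), Otsu's method splits the histogram, and
the brighter class becomes the leaf mask.  The mask then gates per-band
averaging into one spectrum per leaf.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import SegmentationError
from .hypercube import Hypercube, nearest_band

__all__ = ["otsu_threshold", "segment_leaf", "mean_spectrum", "mask_to_rle", "rle_to_mask"]


def otsu_threshold(gray: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    The image is binned into ``n_bins`` equal-width bins over its finite
    range; every interior bin edge is a candidate threshold and the edge with
    the largest between-class variance sigma^2_b = w0*w1*(mu0-mu1)^2 is
    returned (ties -> lowest edge).  Pixels with value < threshold form the
    dark class.  NaNs are ignored.
    """
    values = np.asarray(gray, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0 or values.min() == values.max():
        raise SegmentationError("cannot threshold a constant (or empty) image")
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    counts = counts.astype(float)
    total = counts.sum()
    # Cumulative class weights and means for a split after bin i (threshold
    # at edges[i+1]): class 0 = bins 0..i, class 1 = the rest.
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    centers = 0.5 * (edges[:-1] + edges[1:])
    csum = np.cumsum(counts * centers)[:-1]
    tsum = (counts * centers).sum()
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise SegmentationError("degenerate histogram: a single occupied bin")
    mu0 = np.where(valid, csum / np.where(w0 > 0, w0, 1.0), 0.0)
    mu1 = np.where(valid, (tsum - csum) / np.where(w1 > 0, w1, 1.0), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return float(edges[int(np.argmax(sigma_b)) + 1])


def segment_leaf(
    cube: Hypercube,
    band_nm: float,
    n_bins: int = 256,
    cleanup: bool = True,
) -> np.ndarray:
    """Boolean leaf mask from a single gray band of a calibrated cube.

    The Otsu split partitions pixels at ``band_nm``; the class with the larger
    mean gray value is the leaf (tissue is NIR-bright against the platform).
    With ``cleanup`` the largest 4-connected foreground component is retained
    and interior holes are filled, so stray bright pixels cannot contaminate
    the mean spectrum.  Invalid (NaN) pixels count as background throughout.
    """
    gray = cube.data[:, :, nearest_band(cube.wavelengths, band_nm)]
    finite = np.isfinite(gray)
    if not finite.any():
        raise SegmentationError("gray band has no valid pixels")
    work = np.where(finite, gray, np.nanmin(gray[finite]))
    thr = otsu_threshold(work[finite], n_bins=n_bins)
    lower = work < thr
    upper = ~lower
    mean_lower = work[lower].mean() if lower.any() else -np.inf
    mean_upper = work[upper].mean() if upper.any() else -np.inf
    mask = upper if mean_upper >= mean_lower else lower
    mask = mask & finite
    if cleanup and mask.any():
        labels, n = ndimage.label(mask)  # default structure = 4-connectivity
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
        mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise SegmentationError("segmentation produced an empty foreground")
    return mask


def mean_spectrum(cube: Hypercube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean over foreground pixels, ignoring NaNs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise SegmentationError(
            f"mask shape {mask.shape} does not match cube {cube.shape[:2]}"
        )
    if not mask.any():
        raise SegmentationError("empty mask")
    pixels = cube.data[mask]  # n_fg x bands
    with np.errstate(invalid="ignore"):
        return np.nanmean(pixels, axis=0)


def mask_to_rle(mask: np.ndarray) -> list[int]:
    """Row-major run-length encoding [run0, run1, ...] starting with a
    background run (possibly 0)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    runs: list[int] = []
    current, length = False, 0
    for v in flat:
        if v == current:
            length += 1
        else:
            runs.append(length)
            current, length = v, 1
    runs.append(length)
    return runs


def rle_to_mask(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for run in runs:
        flat[pos : pos + run] = value
        pos += run
        value = not value
    return flat.reshape(shape)
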