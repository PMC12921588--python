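"""Tissue segmentation by Otsu thresholding and section volume estimation.

Volumes are kept in px²·µm throughout the calibration path: areas in pixels
(the bookkeeping unit of the fluorescence sums) times thickness in µm.
Conversion of areas to µm² is offered via the mask's pixel size but not used
internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .io import SectionImage

__all__ = [
    "TissueMask",
    "otsu_threshold",
    "image_histogram",
    "segment_tissue",
    "thin_section_volume",
    "thick_section_volume",
]


@dataclass
class TissueMask:
    """Boolean tissue mask with the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area_px(self) -> int:
        """Segmented tissue area in pixels."""
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2


def otsu_threshold(counts: np.ndarray, bin_centers: np.ndarray) -> float:
    """Threshold maximizing between-class variance over a histogram.

    ``counts`` are pixel counts per intensity bin at ``bin_centers``
    (increasing). The returned threshold is the center of the last bin of the
    background class; pixels strictly above it are foreground. Ties are broken
    toward the lowest qualifying threshold.

    The sweep is evaluated in exact rational arithmetic (counts and bin
    centers are rationals), so the argmax is deterministic: float rounding
    cannot flip near-tied splits, and ties are true ties.
    """
    counts = np.asarray(counts, dtype=float)
    bin_centers = np.asarray(bin_centers, dtype=float)
    if counts.shape != bin_centers.shape or counts.ndim != 1:
        raise ValueError("counts and bin_centers must be matching 1-D arrays")
    if np.count_nonzero(counts) < 2:
        raise ValueError("degenerate histogram: fewer than 2 nonempty bins")

    from fractions import Fraction

    c = [Fraction(v) for v in counts.tolist()]  # exact: floats are rationals
    z = [Fraction(v) for v in bin_centers.tolist()]
    w_total = sum(c)
    s_total = sum(ci * zi for ci, zi in zip(c, z))
    # between-class variance at split after bin i:
    #   w0·w1·(mu0 − mu1)² = (s0·w1 − s1·w0)² / (w0·w1)
    best_score, best_idx = None, None
    w0 = Fraction(0)
    s0 = Fraction(0)
    for i in range(len(c) - 1):
        w0 += c[i]
        s0 += c[i] * z[i]
        w1 = w_total - w0
        if w0 == 0 or w1 == 0:
            continue
        score = (s0 * w1 - (s_total - s0) * w0) ** 2 / (w0 * w1)
        if best_score is None or score > best_score:
            best_score, best_idx = score, i
    return float(bin_centers[best_idx])


def image_histogram(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Histogram used for thresholding: bit-depth-native unit bins for integer
    images, 256 bins over min–max for float images."""
    pixels = np.asarray(pixels)
    if np.issubdtype(pixels.dtype, np.integer):
        lo, hi = int(pixels.min()), int(pixels.max())
        centers = np.arange(lo, hi + 1, dtype=float)
        counts = np.bincount((pixels - lo).ravel(), minlength=hi - lo + 1).astype(float)
        return counts, centers
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi == lo:
        raise ValueError("degenerate histogram: single-valued image")
    counts, edges = np.histogram(pixels.ravel(), bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def segment_tissue(fi: SectionImage, min_object_px: int = 0) -> TissueMask:
    """Otsu-threshold the analyte image into tissue vs background.

    Connected foreground components smaller than ``min_object_px`` are removed
    (default 0 = no cleanup); holes inside tissue are retained.
    """
    pixels = fi.pixels
    if pixels.max() == pixels.min():
        raise ValueError("degenerate histogram: single-valued image")
    counts, centers = image_histogram(pixels)
    threshold = otsu_threshold(counts, centers)
    mask = pixels > threshold
    if min_object_px > 0:
        labelled = morphology.label(mask, connectivity=2)
        sizes = np.bincount(labelled.ravel())
        keep = sizes >= min_object_px
        keep[0] = False
        mask = keep[labelled]
    return TissueMask(mask=mask, threshold=threshold, pixel_size_um=fi.pixel_size_um)


def thin_section_volume(mask: TissueMask, thickness_um: float) -> float:
    """Thin-section volume = segmented area (px) × thickness (µm), in px²·µm."""
    if not thickness_um > 0:
        raise ValueError("thickness_um must be > 0")
    if mask.area_px == 0:
        raise ValueError("empty tissue mask")
    return mask.area_px * thickness_um


def thick_section_volume(
    area_before_px: float, area_after_px: float, h_d_um: float
) -> float:
    """Thick-section volume from the mean area of its two flanking thin
    sections: ((A_before + A_after) / 2) × h, in px²·µm."""
    if area_before_px <= 0 or area_after_px <= 0:
        raise ValueError("flanking areas must be > 0")
    if not h_d_um > 0:
        raise ValueError("thickness must be > 0")
    return 0.5 * (area_before_px + area_after_px) * h_d_um
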