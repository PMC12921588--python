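"""Registration of the paired frames, autofluorescence subtraction and
residual background correction.

The secondary-probe frame (SAI) is the fixed frame: the pre-probe frame (PAI)
is warped onto it so that the derived analyte image FI = max(SAI − PAI, 0)
lives in the coordinate frame used by all downstream mapping. Negative
differences clamp to 0 — intensities are physical and a negative excess over
autofluorescence is noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

from .io import LandmarkSet, SectionImage, Stage

__all__ = [
    "PlanarTransform",
    "fit_landmark_transform",
    "warp_image",
    "warp_coverage",
    "subtract_autofluorescence",
    "estimate_background",
    "correct_background",
]

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-9


@dataclass
class PlanarTransform:
    """A 2-D similarity or affine transform mapping moving (x, y) → fixed (x, y).

    ``matrix`` is the top 2×3 block of the homogeneous matrix; for a
    similarity it has the form s·R | t with s > 0 and R a proper rotation.
    ``rms_residual_px`` is the root-mean-square landmark residual of the fit
    that produced it (0 for hand-constructed transforms).
    """

    kind: str
    matrix: np.ndarray
    rms_residual_px: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("similarity", "affine"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("matrix must be 2x3")
        if self.kind == "similarity":
            a = self.matrix[:, :2]
            # s·R satisfies AᵀA = s²·I and det > 0
            gram = a.T @ a
            s2 = gram[0, 0]
            if s2 <= 0 or np.abs(gram - s2 * np.eye(2)).max() > _ORTHO_TOL * max(1.0, s2):
                raise ValueError("similarity matrix is not of the form s.R | t")
            if np.linalg.det(a) <= 0:
                raise ValueError("similarity must not contain a reflection")

    @property
    def homogeneous(self) -> np.ndarray:
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (x, y) points through the transform."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "PlanarTransform":
        hinv = np.linalg.inv(self.homogeneous)
        return PlanarTransform(kind=self.kind, matrix=hinv[:2, :], rms_residual_px=0.0)

    def _as_skimage(self) -> sktransform.ProjectiveTransform:
        cls = (
            sktransform.SimilarityTransform
            if self.kind == "similarity"
            else sktransform.AffineTransform
        )
        return cls(matrix=self.homogeneous)

    @classmethod
    def identity(cls, kind: str = "similarity") -> "PlanarTransform":
        return cls(kind=kind, matrix=np.hstack([np.eye(2), np.zeros((2, 1))]))


def fit_landmark_transform(
    landmarks: LandmarkSet, kind: str = "similarity"
) -> PlanarTransform:
    """Least-squares planar transform from paired landmarks.

    Minimizes Σ‖T(moving) − fixed‖² over the chosen family. A similarity needs
    ≥ 2 point pairs; an affine needs ≥ 3 non-collinear pairs.
    """
    moving, fixed = landmarks.moving, landmarks.fixed
    if np.allclose(moving, moving[0]) or np.allclose(fixed, fixed[0]):
        raise ValueError("degenerate landmarks: all points identical")
    if kind == "similarity":
        cls = sktransform.SimilarityTransform
        if hasattr(cls, "from_estimate"):
            tf = cls.from_estimate(moving, fixed)
            if not tf:
                raise ValueError("transform estimation failed (degenerate landmarks)")
        else:  # scikit-image < 0.26
            tf = cls()
            if not tf.estimate(moving, fixed):
                raise ValueError("transform estimation failed (degenerate landmarks)")
        matrix = np.asarray(tf.params)[:2, :]
    elif kind == "affine":
        if len(moving) < 3:
            raise ValueError("affine fit needs >= 3 landmark pairs")
        # collinearity check: rank of centered moving points
        centered = moving - moving.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
            raise ValueError("collinear landmarks cannot determine an affine transform")
        # the geometric least-squares affine is a plain linear regression of
        # fixed on (moving, 1); solved directly to keep that objective exact
        design = np.column_stack([moving, np.ones(len(moving))])
        coeffs, _, rank, _ = np.linalg.lstsq(design, fixed, rcond=None)
        if rank < 3:
            raise ValueError("degenerate landmarks for an affine fit")
        matrix = coeffs.T
    else:
        raise ValueError(f"unknown transform kind {kind!r}")
    residuals = (moving @ matrix[:, :2].T + matrix[:, 2]) - fixed
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return PlanarTransform(kind=kind, matrix=matrix, rms_residual_px=rms)


def warp_image(
    image: SectionImage,
    tf: PlanarTransform,
    fill: float = 0.0,
    output_shape: tuple[int, int] | None = None,
) -> SectionImage:
    """Resample ``image`` into the fixed frame through ``tf`` (moving → fixed).

    Bilinear interpolation; pixels with no source data take ``fill``. The
    output shape defaults to the input shape (i.e. the fixed frame is assumed
    congruent, as for serial sections imaged on the same stage).
    """
    warped = sktransform.warp(
        image.pixels.astype(float),
        inverse_map=tf._as_skimage().inverse,
        output_shape=output_shape or image.shape,
        order=1,
        cval=fill,
        mode="constant",
        preserve_range=True,
    )
    if fill >= 0:
        warped = np.clip(warped, 0.0, None)
    return image.with_pixels(warped)


def warp_coverage(
    shape: tuple[int, int],
    tf: PlanarTransform,
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Boolean mask of fixed-frame pixels fully covered by the warped moving frame."""
    ones = sktransform.warp(
        np.ones(shape, dtype=float),
        inverse_map=tf._as_skimage().inverse,
        output_shape=output_shape or shape,
        order=1,
        cval=0.0,
        mode="constant",
        preserve_range=True,
    )
    return ones > 1.0 - 1e-6


def subtract_autofluorescence(
    sai: SectionImage, pai_aligned: SectionImage
) -> SectionImage:
    """Analyte-specific image FI = max(SAI − PAI, 0), elementwise in float.

    Both frames must share the SAI coordinate frame and shape; the count of
    clamped (negative-difference) pixels is logged as a quality signal.
    """
    if sai.shape != pai_aligned.shape:
        raise ValueError(f"shape mismatch: SAI {sai.shape} vs PAI {pai_aligned.shape}")
    if sai.stage != Stage.SAI or pai_aligned.stage != Stage.PAI:
        raise ValueError("expected stages SAI and PAI")
    diff = sai.pixels.astype(float) - pai_aligned.pixels.astype(float)
    n_clamped = int(np.count_nonzero(diff < 0))
    if n_clamped:
        logger.info("subtract_autofluorescence: clamped %d negative pixels", n_clamped)
    return sai.with_pixels(np.clip(diff, 0.0, None), stage=Stage.FI)


def estimate_background(fi: SectionImage, tissue_mask: np.ndarray) -> float:
    """Mean residual intensity over non-tissue pixels of the FI image.

    Requires at least 1% of pixels outside the tissue mask to give the mean a
    meaningful support.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape != fi.shape:
        raise ValueError("mask shape differs from image shape")
    outside = ~tissue_mask
    if outside.sum() < 0.01 * tissue_mask.size:
        raise ValueError("no background pixels: tissue mask covers >= 99% of the image")
    return float(fi.pixels[outside].mean())


def correct_background(fi: SectionImage, background: float) -> SectionImage:
    """Subtract the scalar background from every pixel, clamping at 0."""
    if background < 0:
        raise ValueError("background must be >= 0")
    return fi.with_pixels(np.clip(fi.pixels.astype(float) - background, 0.0, None))
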