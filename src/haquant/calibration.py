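"""Calibration of fluorescence intensity against bulk analyte concentration
and conversion of pixel intensities into absolute concentration maps.

Units
-----
Per-pixel fluorescence lives in arbitrary units (AU). Summed fluorescence is
normalized by a volume in px²·µm, giving an *FI concentration* in AU per
px²·µm; the per-pixel counterpart divides a pixel's AU by its voxel volume
(1 px² × section thickness). Keeping both sides of the calibration on the
same per-volume scale is what lets a curve fitted on whole sections be
applied pixel by pixel.

Two conversion modes are provided:

* ``ratio`` — the single-block proportionality
  ``c_local = Tk × (c_bulk / fi_conc_total) × fi_conc_local``,
  which conserves total analyte mass over the section exactly;
* ``curve`` — the fitted calibration polynomial applied to each pixel's FI
  concentration, then scaled by the thickness factor Tk (the headline
  multi-sample pipeline).

The thickness factor ``Tk = reference_thickness / section_thickness`` is 1
when mapping sections of the calibration thickness itself; it rescales the
per-pixel FI of a thicker or thinner cut to the calibration's reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import ConcentrationMap, SampleBlock, SectionImage
from .segmentation import TissueMask, segment_tissue, thick_section_volume, thin_section_volume

__all__ = [
    "CalibrationPoint",
    "CalibrationModel",
    "ThicknessFactor",
    "RatioParams",
    "total_fi",
    "fi_concentration",
    "build_calibration_point",
    "fit_calibration",
    "select_model",
    "pixel_to_concentration_ratio",
    "concentration_map",
    "ratio_params_for_block",
]

logger = logging.getLogger(__name__)

# floor on the residual sum of squares in the AIC: an exact interpolation has
# RSS 0 and an unbounded Gaussian likelihood; flooring makes exact linear and
# exact quadratic fits tie (the tie-break then prefers the simpler model)
_RSS_FLOOR_PER_POINT = 1e-30


@dataclass
class CalibrationPoint:
    """One block's (FI concentration, bulk concentration) pair.

    ``fi_concentration`` is in AU per px²·µm (volume-normalized total
    fluorescence, averaged over the two flanking thin sections);
    ``ha_concentration`` is the thick section's bulk value in mg/mL.
    """

    fi_concentration: float
    ha_concentration: float
    block_id: str = ""

    def __post_init__(self) -> None:
        if self.fi_concentration < 0 or self.ha_concentration < 0:
            raise ValueError("calibration point values must be >= 0")


@dataclass
class CalibrationModel:
    """Polynomial calibration c_bulk = Σ_k coef_k · fi^k with fit diagnostics.

    Coefficients are in ascending order. ``residuals`` are observed − predicted
    bulk concentrations; they describe the fit and are never added to
    predictions. ``fi_range`` records the fitted abscissa span, used to warn
    about extrapolation.
    """

    degree: int
    coefficients: np.ndarray
    r_squared: float
    residuals: np.ndarray
    n_points: int
    aic: float
    fi_range: tuple[float, float] = (0.0, math.inf)
    fitted: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        self.fitted = np.asarray(self.fitted, dtype=float)
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("coefficient count does not match degree")
        if self.n_points < self.degree + 2:
            raise ValueError("need at least degree + 2 points")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")

    def predict(self, fi: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(fi, self.coefficients)


@dataclass
class ThicknessFactor:
    """Dimensionless thickness normalization Tk = reference / section thickness."""

    thin_thickness_um: float
    reference_thickness_um: float

    def __post_init__(self) -> None:
        if self.thin_thickness_um <= 0 or self.reference_thickness_um <= 0:
            raise ValueError("thicknesses must be > 0")

    @property
    def tk(self) -> float:
        return self.reference_thickness_um / self.thin_thickness_um

    @classmethod
    def unity(cls, thickness_um: float = 5.0) -> "ThicknessFactor":
        return cls(thin_thickness_um=thickness_um, reference_thickness_um=thickness_um)


@dataclass
class RatioParams:
    """Inputs of the ratio (single-block) conversion.

    ``fi_total_conc`` is the section's summed FI divided by the normalization
    volume (px²·µm) — use the thick-section volume when the bulk value comes
    from the flanked thick cut, so that total analyte mass is conserved.
    """

    ha_total: float
    fi_total_conc: float

    def __post_init__(self) -> None:
        if self.ha_total < 0:
            raise ValueError("ha_total must be >= 0")
        if self.fi_total_conc <= 0:
            raise ValueError("fi_total_conc must be > 0")


def total_fi(fi: SectionImage, mask: TissueMask) -> float:
    """Sum of FI pixel intensities over the segmented tissue area (AU)."""
    if mask.mask.shape != fi.shape:
        raise ValueError("mask shape differs from image shape")
    if mask.area_px == 0:
        raise ValueError("empty tissue mask")
    return float(fi.pixels[mask.mask].sum())


def fi_concentration(total: float, volume: float) -> float:
    """Volume-normalized fluorescence, AU per px²·µm."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return total / volume


def build_calibration_point(
    block: SampleBlock,
    fi_before: SectionImage | None,
    fi_after: SectionImage | None,
    masks: tuple[TissueMask, TissueMask] | None = None,
) -> CalibrationPoint:
    """Calibration point for one block: mean flanking FI concentration vs bulk.

    Each flanking thin section contributes its total FI normalized by its own
    thin-section volume; the two are averaged. A missing flank falls back to
    the single available section with a logged warning.
    """
    if fi_before is None and fi_after is None:
        raise ValueError("at least one flanking FI image is required")
    concs = []
    for i, fi in enumerate((fi_before, fi_after)):
        if fi is None:
            logger.warning(
                "block %s: missing flanking section, using single-section FI",
                block.block_id,
            )
            continue
        mask = masks[i] if masks is not None else segment_tissue(fi)
        vol = thin_section_volume(mask, fi.thickness_um)
        concs.append(fi_concentration(total_fi(fi, mask), vol))
    return CalibrationPoint(
        fi_concentration=float(np.mean(concs)),
        ha_concentration=block.d_bulk_concentration,
        block_id=block.block_id,
    )


def fit_calibration(points: list[CalibrationPoint], degree: int) -> CalibrationModel:
    """Ordinary least-squares polynomial fit of bulk concentration on FI
    concentration.

    Requires at least ``degree + 2`` points (one residual degree of freedom).
    The AIC uses the Gaussian log-likelihood with ``degree + 2`` parameters
    (coefficients plus the noise variance).
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = len(points)
    if n < degree + 2:
        raise ValueError(f"need >= {degree + 2} points for degree {degree}, got {n}")
    x = np.array([p.fi_concentration for p in points], dtype=float)
    y = np.array([p.ha_concentration for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("rank-deficient design: all FI concentrations equal")
    design = np.polynomial.polynomial.polyvander(x, degree)
    coeffs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < degree + 1:
        raise ValueError("rank-deficient design")
    predicted = design @ coeffs
    residuals = y - predicted
    rss = float(residuals @ residuals)
    tss = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 if tss == 0 else 1.0 - rss / tss
    rss_f = max(rss, n * _RSS_FLOOR_PER_POINT)
    k = degree + 2
    loglik = -0.5 * n * (math.log(2 * math.pi) + math.log(rss_f / n) + 1.0)
    aic = 2 * k - 2 * loglik
    return CalibrationModel(
        degree=degree,
        coefficients=coeffs,
        r_squared=r_squared,
        residuals=residuals,
        n_points=n,
        aic=aic,
        fi_range=(float(x.min()), float(x.max())),
        fitted=predicted,
    )


# AIC-difference support scale (Burnham & Anderson): models within ~2 units
# are equivalent, a gap of 4+ means the worse model has considerably less
# support. The extra curvature term must clear that gap; otherwise model
# selection would flip between degrees on noise alone.
AIC_MARGIN = 4.0


def select_model(
    linear: CalibrationModel, quadratic: CalibrationModel
) -> tuple[CalibrationModel, dict]:
    """Choose between the linear and quadratic calibration by AIC.

    The quadratic is selected only when it beats the linear model by more
    than :data:`AIC_MARGIN` units of AIC; ties and small gaps prefer the
    simpler model. The report carries both models' R², AIC and
    residual-vs-fitted values — the surface a residual analysis inspects.
    """
    if linear.degree != 1 or quadratic.degree != 2:
        raise ValueError("expected a degree-1 and a degree-2 model")
    if linear.n_points != quadratic.n_points:
        raise ValueError("models were not fit on the same points")
    chosen = quadratic if quadratic.aic < linear.aic - AIC_MARGIN else linear
    report = {
        "chosen_degree": chosen.degree,
        "linear": _diagnostics(linear),
        "quadratic": _diagnostics(quadratic),
    }
    return chosen, report


def _diagnostics(model: CalibrationModel) -> dict:
    return {
        "r_squared": model.r_squared,
        "aic": model.aic,
        "fitted": model.fitted.tolist(),
        "residuals": model.residuals.tolist(),
    }


def pixel_to_concentration_ratio(
    fi_local: float | np.ndarray,
    fi_total_conc: float,
    ha_total: float,
    tk: ThicknessFactor,
) -> float | np.ndarray:
    """Ratio conversion c_local = Tk × (c_bulk / fi_conc_total) × fi_local.

    ``fi_local`` and ``fi_total_conc`` must share the same per-volume
    normalization. The calibration residual describes scatter around the curve
    and is never added at prediction time.
    """
    if fi_total_conc <= 0:
        raise ValueError("fi_total_conc must be > 0")
    return tk.tk * (ha_total / fi_total_conc) * fi_local


def concentration_map(
    fi: SectionImage,
    mask: TissueMask,
    calibration: CalibrationModel | RatioParams,
    tk: ThicknessFactor | None = None,
    mode: str = "curve",
) -> ConcentrationMap:
    """Convert an FI image into an absolute concentration map (mg/mL).

    Each pixel's FI is first put on the per-volume scale (AU per px²·µm) by
    dividing by its voxel volume, 1 px² × section thickness. In ``curve`` mode
    the fitted polynomial is applied and scaled by Tk, with negative
    predictions clamped to 0 (logged); in ``ratio`` mode the mass-conserving
    proportionality is applied. Pixels outside the tissue mask are 0.
    """
    if mask.mask.shape != fi.shape:
        raise ValueError("mask shape differs from image shape")
    tk = tk or ThicknessFactor.unity(fi.thickness_um)
    fi_conc = fi.pixels.astype(float) / fi.thickness_um  # AU per px².µm
    if mode == "curve":
        if not isinstance(calibration, CalibrationModel):
            raise TypeError("curve mode needs a CalibrationModel")
        lo, hi = calibration.fi_range
        observed = fi_conc[mask.mask]
        span = max(hi - lo, 1e-12)
        if observed.size and (
            observed.min() < lo - 1e-9 * span or observed.max() > hi + 1e-9 * span
        ):
            logger.warning(
                "concentration_map: FI range [%.4g, %.4g] extends beyond the "
                "calibration's fitted range [%.4g, %.4g]; extrapolating",
                observed.min(), observed.max(), lo, hi,
            )
        values = np.asarray(calibration.predict(fi_conc), dtype=float) * tk.tk
        n_neg = int(np.count_nonzero(values[mask.mask] < 0))
        if n_neg:
            logger.info("concentration_map: clamped %d negative predictions", n_neg)
        values = np.clip(values, 0.0, None)
    elif mode == "ratio":
        if not isinstance(calibration, RatioParams):
            raise TypeError("ratio mode needs RatioParams")
        values = pixel_to_concentration_ratio(
            fi_conc, calibration.fi_total_conc, calibration.ha_total, tk
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    values = np.where(mask.mask, values, 0.0)
    return ConcentrationMap(
        values=values,
        mask=mask.mask,
        pixel_size_um=fi.pixel_size_um,
        thickness_um=fi.thickness_um,
        mode=mode,
    )


def ratio_params_for_block(
    block: SampleBlock,
    fi_before: SectionImage,
    fi_after: SectionImage,
    mask_before: TissueMask,
    mask_after: TissueMask,
    which: str = "before",
) -> RatioParams:
    """Ratio parameters for mapping one of a block's thin sections.

    The summed FI of the chosen section is normalized by the thick-section
    volume (mean flanking area × thick thickness), pairing it with the thick
    cut's bulk concentration so that Σ map × voxel volume = c_bulk × V_thick.
    """
    v_thick = thick_section_volume(
        mask_before.area_px, mask_after.area_px, block.d_thickness_um
    )
    fi, mask = (fi_before, mask_before) if which == "before" else (fi_after, mask_after)
    return RatioParams(
        ha_total=block.d_bulk_concentration,
        fi_total_conc=fi_concentration(total_fi(fi, mask), v_thick),
    )
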