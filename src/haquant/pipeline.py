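"""End-to-end orchestration: from a sample table of paired frames and bulk
assay values to calibration, concentration maps, spatial summaries and a
reproducibility report.

Stage outputs are files, not in-memory handoffs, so any stage can be rerun or
swapped independently. Every run writes a machine-readable manifest recording
package/library versions, a hash of the resolved configuration, and per-stage
provenance (registration residuals, background levels, thresholds, clamped
pixel counts).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import io as hio
from . import preprocess as pre
from . import repro
from . import segmentation as seg
from . import spatial
from ._version import __version__

__all__ = [
    "RunConfig",
    "ValidationError",
    "BlockResult",
    "run_pipeline",
    "process_block",
    "write_model",
    "read_model",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Configuration or input-contract failure detected before computation."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Landmarks for a block are looked up as ``<block_id>.landmarks.csv`` in
    ``image_dir`` (or per-block via an optional ``landmarks`` column in the
    sample table); blocks without landmarks are assumed pre-aligned.
    """

    sample_table: str
    image_dir: str
    output_dir: str
    transform: str = "similarity"
    mode: str = "curve"
    degree: str = "auto"  # "auto", "1" or "2"
    region_scheme: str = "concentric_depth"
    region_k: int = 4
    min_object_px: int = 0
    reference_thickness_um: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        try:
            return cls(**data)
        except TypeError as exc:
            raise ValidationError(f"invalid config {path}: {exc}") from exc

    def validate(self) -> None:
        if not Path(self.sample_table).is_file():
            raise ValidationError(f"sample table not found: {self.sample_table}")
        if not Path(self.image_dir).is_dir():
            raise ValidationError(f"image directory not found: {self.image_dir}")
        if self.transform not in ("similarity", "affine"):
            raise ValidationError(f"unknown transform kind {self.transform!r}")
        if self.mode not in ("curve", "ratio"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if str(self.degree) not in ("auto", "1", "2"):
            raise ValidationError(f"degree must be auto, 1 or 2, got {self.degree!r}")
        if self.region_k < 2:
            raise ValidationError("region_k must be >= 2")
        table = hio.read_sample_table(self.sample_table)
        for _, row in table.iterrows():
            for col in ("c_before_pai", "c_before_sai", "c_after_pai", "c_after_sai"):
                p = Path(self.image_dir) / row[col]
                if not p.is_file():
                    raise ValidationError(f"block {row['block_id']}: missing image {p}")


@dataclass
class BlockResult:
    """Per-block intermediates: aligned FI images, masks and bookkeeping."""

    block: hio.SampleBlock
    fi_before: hio.SectionImage
    fi_after: hio.SectionImage
    mask_before: seg.TissueMask
    mask_after: seg.TissueMask
    point: cal.CalibrationPoint
    transform_before: pre.PlanarTransform
    transform_after: pre.PlanarTransform
    background_before: float
    background_after: float

    @property
    def thick_volume(self) -> float:
        return seg.thick_section_volume(
            self.mask_before.area_px, self.mask_after.area_px, self.block.d_thickness_um
        )


def _preprocess_pair(
    pai: hio.SectionImage,
    sai: hio.SectionImage,
    landmarks: hio.LandmarkSet | None,
    kind: str,
    min_object_px: int,
) -> tuple[hio.SectionImage, seg.TissueMask, pre.PlanarTransform, float]:
    """Register, subtract, background-correct and segment one section pair."""
    if landmarks is not None:
        tf = pre.fit_landmark_transform(landmarks, kind=kind)
    else:
        tf = pre.PlanarTransform.identity(kind)
    pai_aligned = pre.warp_image(pai, tf)
    coverage = pre.warp_coverage(pai.shape, tf, output_shape=sai.shape)
    fi_raw = pre.subtract_autofluorescence(sai, pai_aligned)
    # pixels the moving frame could not supply carry no evidence; zero them so
    # border strips do not contaminate the background estimate
    fi_raw = fi_raw.with_pixels(np.where(coverage, fi_raw.pixels, 0.0))
    provisional = seg.segment_tissue(fi_raw)
    background = pre.estimate_background(fi_raw, provisional.mask)
    fi = pre.correct_background(fi_raw, background)
    mask = seg.segment_tissue(fi, min_object_px=min_object_px)
    return fi, mask, tf, background


def process_block(
    block: hio.SampleBlock,
    landmarks_before: hio.LandmarkSet | None,
    landmarks_after: hio.LandmarkSet | None,
    transform: str = "similarity",
    min_object_px: int = 0,
) -> BlockResult:
    """Run registration → subtraction → background correction → segmentation
    for both flanking sections of a block and build its calibration point."""
    fi_b, mask_b, tf_b, bg_b = _preprocess_pair(
        *block.c_before, landmarks_before, transform, min_object_px
    )
    fi_a, mask_a, tf_a, bg_a = _preprocess_pair(
        *block.c_after, landmarks_after, transform, min_object_px
    )
    point = cal.build_calibration_point(block, fi_b, fi_a, masks=(mask_b, mask_a))
    return BlockResult(
        block=block,
        fi_before=fi_b,
        fi_after=fi_a,
        mask_before=mask_b,
        mask_after=mask_a,
        point=point,
        transform_before=tf_b,
        transform_after=tf_a,
        background_before=bg_b,
        background_after=bg_a,
    )


def fit_and_select(
    points: list[cal.CalibrationPoint], degree: str = "auto"
) -> tuple[cal.CalibrationModel, dict]:
    """Fit the calibration at the configured degree policy."""
    if str(degree) == "auto":
        if len(points) >= 4:
            linear = cal.fit_calibration(points, 1)
            quadratic = cal.fit_calibration(points, 2)
            return cal.select_model(linear, quadratic)
        model = cal.fit_calibration(points, 1)
        return model, {"chosen_degree": 1, "note": "too few points for quadratic"}
    model = cal.fit_calibration(points, int(degree))
    return model, {"chosen_degree": model.degree}


def write_model(
    model: cal.CalibrationModel, tk: cal.ThicknessFactor, path: str | Path
) -> None:
    data = {
        "degree": model.degree,
        "coefficients": [float(c) for c in model.coefficients],
        "r_squared": float(model.r_squared),
        "n_points": model.n_points,
        "aic": float(model.aic),
        "fi_range": [float(model.fi_range[0]), float(model.fi_range[1])],
        "tk": {
            "thin_thickness_um": tk.thin_thickness_um,
            "reference_thickness_um": tk.reference_thickness_um,
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_model(path: str | Path) -> tuple[cal.CalibrationModel, cal.ThicknessFactor]:
    data = yaml.safe_load(Path(path).read_text())
    n = data["n_points"]
    model = cal.CalibrationModel(
        degree=data["degree"],
        coefficients=np.array(data["coefficients"]),
        r_squared=data["r_squared"],
        residuals=np.zeros(n),
        n_points=n,
        aic=data["aic"],
        fi_range=tuple(data["fi_range"]),
    )
    tk = cal.ThicknessFactor(**data["tk"])
    return model, tk


def _landmarks_for(row: pd.Series, image_dir: Path) -> hio.LandmarkSet | None:
    if "landmarks" in row.index and isinstance(row["landmarks"], str):
        return hio.read_landmarks(image_dir / row["landmarks"])
    candidate = image_dir / f"{row['block_id']}.landmarks.csv"
    if candidate.is_file():
        return hio.read_landmarks(candidate)
    return None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow described by ``config``.

    Per block: registered FI images, tissue masks and the calibration point;
    globally: the fitted calibration (with model-selection diagnostics),
    per-section concentration maps, region statistics and radial profiles,
    and a reproducibility report treating each block's two flanking sections
    as intraslide technical duplicates. Any stage failure aborts with the
    failing block and stage named; outputs written so far are retained.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    image_dir = Path(config.image_dir)
    table = hio.read_sample_table(config.sample_table)

    manifest: dict = {
        "haquant_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "blocks": {},
    }

    results: list[BlockResult] = []
    stage = "load"
    for _, row in table.iterrows():
        block_id = str(row["block_id"])
        try:
            stage = "load"
            block = hio.load_block(row, image_dir)
            landmarks = _landmarks_for(row, image_dir)
            stage = "preprocess"
            res = process_block(
                block,
                landmarks,
                landmarks,
                transform=config.transform,
                min_object_px=config.min_object_px,
            )
        except Exception as exc:
            raise RuntimeError(f"block {block_id}, stage {stage}: {exc}") from exc
        results.append(res)
        hio.write_section_image(res.fi_before, out / f"{block_id}_before_fi.tif")
        hio.write_section_image(res.fi_after, out / f"{block_id}_after_fi.tif")
        manifest["blocks"][block_id] = {
            "rms_residual_px": res.transform_before.rms_residual_px,
            "background_before": res.background_before,
            "background_after": res.background_after,
            "threshold_before": res.mask_before.threshold,
            "threshold_after": res.mask_after.threshold,
            "area_before_px": res.mask_before.area_px,
            "area_after_px": res.mask_after.area_px,
            "fi_concentration": res.point.fi_concentration,
            "bulk_mg_per_ml": res.point.ha_concentration,
        }

    stage = "calibrate"
    points = [r.point for r in results]
    points_df = pd.DataFrame(
        {
            "block_id": [p.block_id for p in points],
            "fi_concentration": [p.fi_concentration for p in points],
            "ha_mg_per_ml": [p.ha_concentration for p in points],
        }
    )
    points_df.to_csv(out / "calibration_points.csv", index=False)

    model, diagnostics = fit_and_select(points, config.degree)
    thin_um = float(table["thin_thickness_um"].iloc[0])
    ref_um = config.reference_thickness_um or thin_um
    tk = cal.ThicknessFactor(thin_thickness_um=thin_um, reference_thickness_um=ref_um)
    write_model(model, tk, out / "model.yaml")
    manifest["calibration"] = {
        "degree": model.degree,
        "r_squared": model.r_squared,
        "aic": model.aic,
        "diagnostics": {
            k: v for k, v in diagnostics.items() if not isinstance(v, dict)
        },
    }

    stage = "map"
    region_rows = []
    for res in results:
        block_id = res.block.block_id
        for which, fi, mask in (
            ("before", res.fi_before, res.mask_before),
            ("after", res.fi_after, res.mask_after),
        ):
            if config.mode == "curve":
                cmap = cal.concentration_map(fi, mask, model, tk, mode="curve")
            else:
                params = cal.ratio_params_for_block(
                    res.block, res.fi_before, res.fi_after,
                    res.mask_before, res.mask_after, which=which,
                )
                cmap = cal.concentration_map(fi, mask, params, tk, mode="ratio")
            hio.write_concentration_map(cmap, out / f"{block_id}_{which}_map.tif")
            if which == "before":
                regions = spatial.concentric_regions(
                    mask, config.region_k, scheme=config.region_scheme
                )
                inside = cmap.values[cmap.mask]
                bins = np.linspace(0.0, max(float(inside.max()), 1e-9), 33)
                hist = spatial.region_histogram(cmap, regions, bins)
                hist.insert(0, "block_id", block_id)
                region_rows.append(hist)
                profile = spatial.radial_profile(cmap, regions)
                profile.to_frame().to_csv(
                    out / f"{block_id}_radial_profile.csv", index=False
                )
    if region_rows:
        pd.concat(region_rows, ignore_index=True).to_csv(
            out / "region_histograms.csv", index=False
        )

    stage = "report"
    rep_values = np.array(
        [
            [
                _section_fi_conc(r.fi_before, r.mask_before),
                _section_fi_conc(r.fi_after, r.mask_after),
            ]
            for r in results
        ]
    )
    report = repro.reproducibility_report(
        repro.ReplicateTable(values=rep_values, grouping="intraslide")
    )
    report.to_frame().to_csv(out / "reproducibility.csv", index=False)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "results": results,
        "model": model,
        "diagnostics": diagnostics,
        "report": report,
        "manifest": manifest,
        "output_dir": out,
    }


def _section_fi_conc(fi: hio.SectionImage, mask: seg.TissueMask) -> float:
    volume = seg.thin_section_volume(mask, fi.thickness_um)
    return cal.fi_concentration(cal.total_fi(fi, mask), volume)
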