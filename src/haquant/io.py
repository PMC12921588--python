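"""Reading and writing of section images, landmark files, sample tables and
concentration maps.

Conventions used throughout the package (and stated in every file this module
writes):

* coordinates are 0-based with ``(x, y) = (column, row)``;
* images are single-channel grayscale TIFFs, 8- or 16-bit integer (or 32-bit
  float) in, 32-bit float out;
* intensities are never rescaled on read — an 8-bit image stays on [0, 255];
* landmark files are comma-separated with a mandatory (case-insensitive)
  header ``moving_x, moving_y, fixed_x, fixed_y``;
* concentration maps serialize masked-out pixels as 0 in the float TIFF, with
  the tissue mask written as a companion 8-bit 0/255 TIFF referenced from a
  YAML sidecar.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "Stage",
    "SectionImage",
    "SampleBlock",
    "LandmarkSet",
    "ConcentrationMap",
    "read_section_image",
    "write_section_image",
    "read_landmarks",
    "write_landmarks",
    "read_concentration_map",
    "write_concentration_map",
    "read_sample_table",
    "SAMPLE_TABLE_COLUMNS",
]


class Stage(str, enum.Enum):
    """Acquisition stage of a fluorescence frame.

    PAI — before the secondary fluorescent probe (tissue autofluorescence
    plus any primary-probe contribution); SAI — after the secondary probe
    (autofluorescence plus analyte-specific signal); FI — the derived
    analyte-specific image SAI − PAI.
    """

    PAI = "PAI"
    SAI = "SAI"
    FI = "FI"


@dataclass
class SectionImage:
    """One grayscale fluorescence frame with its acquisition metadata.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities in arbitrary units (AU).
    stage
        Acquisition stage (:class:`Stage`).
    thickness_um
        Physical section thickness in µm (> 0).
    pixel_size_um
        Lateral pixel size in µm/px (> 0).
    section_id
        Free-form identifier, e.g. ``"C_3.1"``.
    """

    pixels: np.ndarray
    stage: Stage
    thickness_um: float
    pixel_size_um: float
    section_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"expected single channel, got {self.pixels.ndim}-dimensional data"
            )
        if np.issubdtype(self.pixels.dtype, np.floating) and not np.all(
            np.isfinite(self.pixels)
        ):
            raise ValueError("pixel intensities must be finite")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("pixel intensities must be non-negative")
        self.stage = Stage(self.stage)
        if not self.thickness_um > 0:
            raise ValueError(f"thickness_um must be > 0, got {self.thickness_um}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, stage: Stage | None = None) -> "SectionImage":
        """Copy of this frame with new pixel data (and optionally a new stage)."""
        return replace(self, pixels=pixels, stage=self.stage if stage is None else stage)


@dataclass
class SampleBlock:
    """The sectioning unit: thin imaging sections flanking a thick digestion cut.

    ``c_before`` holds the (PAI, SAI) pair of the thin section cut immediately
    before the thick section and ``c_after`` the pair cut immediately after it;
    the thick section in between carries the bulk analyte concentration
    measured biochemically.
    """

    c_before: tuple[SectionImage, SectionImage]
    c_after: tuple[SectionImage, SectionImage]
    d_thickness_um: float
    d_bulk_concentration: float
    block_id: str = ""

    def __post_init__(self) -> None:
        if not self.d_thickness_um > 0:
            raise ValueError("d_thickness_um must be > 0")
        if self.d_bulk_concentration < 0:
            raise ValueError("d_bulk_concentration must be >= 0")
        sizes = {
            img.pixel_size_um
            for pair in (self.c_before, self.c_after)
            if pair is not None
            for img in pair
        }
        if len(sizes) > 1:
            raise ValueError(f"flanking sections disagree on pixel size: {sorted(sizes)}")


@dataclass
class LandmarkSet:
    """Paired 2-D landmark coordinates (moving → fixed), 0-based (x, y) pixels."""

    moving: np.ndarray
    fixed: np.ndarray

    def __post_init__(self) -> None:
        self.moving = np.asarray(self.moving, dtype=float)
        self.fixed = np.asarray(self.fixed, dtype=float)
        for name, pts in (("moving", self.moving), ("fixed", self.fixed)):
            if pts.ndim != 2 or pts.shape[1] != 2:
                raise ValueError(f"{name} points must be an (n, 2) array")
            if not np.all(np.isfinite(pts)):
                raise ValueError(f"{name} points contain NaN/inf coordinates")
        if len(self.moving) != len(self.fixed):
            raise ValueError("moving and fixed point lists differ in length")
        if len(self.moving) < 2:
            raise ValueError("at least 2 landmark pairs are required")
        if len(np.unique(self.fixed, axis=0)) != len(self.fixed):
            raise ValueError("duplicate fixed points")

    def __len__(self) -> int:
        return len(self.moving)


@dataclass
class ConcentrationMap:
    """Per-pixel absolute analyte concentration (mg/mL) on a tissue mask.

    Values are defined (≥ 0) where ``mask`` is true and 0 outside it.
    ``mode`` records how the map was produced: ``"ratio"`` (single-block
    intensity ratio) or ``"curve"`` (fitted calibration polynomial).
    """

    values: np.ndarray
    mask: np.ndarray
    pixel_size_um: float
    thickness_um: float
    mode: str = "curve"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.size and self.values[self.mask].size and self.values[self.mask].min() < 0:
            raise ValueError("concentrations must be >= 0 inside the mask")
        if np.any(self.values[~self.mask] != 0):
            raise ValueError("pixels outside the mask must be 0")
        if self.mode not in ("ratio", "curve"):
            raise ValueError(f"unknown map mode {self.mode!r}")
        if not self.pixel_size_um > 0 or not self.thickness_um > 0:
            raise ValueError("pixel_size_um and thickness_um must be > 0")


_ALLOWED_DTYPES = (np.uint8, np.uint16, np.float32)


def read_section_image(
    path: str | Path,
    *,
    stage: Stage | str,
    thickness_um: float | None,
    pixel_size_um: float | None,
    section_id: str = "",
) -> SectionImage:
    """Read a single-channel grayscale TIFF and attach acquisition metadata.

    Integer inputs are preserved exactly; intensities are never rescaled.
    Multi-channel images are rejected with a message naming the channel count.
    """
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 3:
        raise ValueError(f"expected single channel, got {pixels.shape[-1]}")
    if pixels.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {pixels.shape}")
    if pixels.dtype not in [np.dtype(t) for t in _ALLOWED_DTYPES]:
        raise ValueError(
            f"unsupported dtype {pixels.dtype}; expected uint8, uint16 or float32"
        )
    if thickness_um is None or pixel_size_um is None:
        raise ValueError(f"{path.name}: thickness_um and pixel_size_um are required")
    return SectionImage(
        pixels=pixels,
        stage=Stage(stage),
        thickness_um=float(thickness_um),
        pixel_size_um=float(pixel_size_um),
        section_id=section_id or path.stem,
    )


def write_section_image(image: SectionImage, path: str | Path) -> None:
    """Write a section image as TIFF, preserving its dtype (float data → float32)."""
    pixels = image.pixels
    if np.issubdtype(pixels.dtype, np.floating):
        pixels = pixels.astype(np.float32)
    tifffile.imwrite(Path(path), pixels)


_LANDMARK_COLUMNS = ("moving_x", "moving_y", "fixed_x", "fixed_y")


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Parse a landmark CSV (columns moving_x, moving_y, fixed_x, fixed_y).

    Headers are matched case-insensitively; coordinates are 0-based pixels.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark file {path} lacks columns: {', '.join(missing)}")
    if df[list(_LANDMARK_COLUMNS)].isna().any().any():
        raise ValueError(f"landmark file {path} contains NaN coordinates")
    if len(df) < 2:
        raise ValueError(f"landmark file {path} has {len(df)} rows; need >= 2")
    return LandmarkSet(
        moving=df[["moving_x", "moving_y"]].to_numpy(float),
        fixed=df[["fixed_x", "fixed_y"]].to_numpy(float),
    )


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "moving_x": landmarks.moving[:, 0],
            "moving_y": landmarks.moving[:, 1],
            "fixed_x": landmarks.fixed[:, 0],
            "fixed_y": landmarks.fixed[:, 1],
        }
    ).to_csv(path, index=False)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _mask_path(path: Path) -> Path:
    return path.with_suffix(".mask.tif")


def write_concentration_map(
    cmap: ConcentrationMap, path: str | Path, *, png: str | Path | None = None
) -> None:
    """Write a concentration map as a 32-bit float TIFF plus sidecar metadata.

    Pixels outside the tissue mask are written as 0; the mask itself goes to a
    companion 8-bit 0/255 TIFF named in the YAML sidecar. ``png`` optionally
    renders an 8-bit color-mapped preview with a scale legend.
    """
    path = Path(path)
    values = np.where(cmap.mask, cmap.values, 0.0).astype(np.float32)
    tifffile.imwrite(path, values)
    mask_path = _mask_path(path)
    tifffile.imwrite(mask_path, (cmap.mask.astype(np.uint8) * 255))
    meta = {
        "units": "mg/mL",
        "pixel_size_um": float(cmap.pixel_size_um),
        "thickness_um": float(cmap.thickness_um),
        "mode": cmap.mode,
        "mask_file": mask_path.name,
        "coordinates": "0-based, (x, y) = (column, row)",
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    if png is not None:
        _render_png(cmap, Path(png))


def _render_png(cmap: ConcentrationMap, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    shown = np.where(cmap.mask, cmap.values, np.nan)
    im = ax.imshow(shown, cmap="viridis")
    fig.colorbar(im, ax=ax, label="concentration (mg/mL)")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def read_concentration_map(path: str | Path) -> ConcentrationMap:
    """Read a float TIFF + sidecar written by :func:`write_concentration_map`."""
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    meta = yaml.safe_load(_sidecar_path(path).read_text())
    mask_file = path.parent / meta["mask_file"]
    mask = tifffile.imread(mask_file) > 0
    return ConcentrationMap(
        values=values,
        mask=mask,
        pixel_size_um=meta["pixel_size_um"],
        thickness_um=meta["thickness_um"],
        mode=meta["mode"],
    )


SAMPLE_TABLE_COLUMNS = (
    "block_id",
    "c_before_pai",
    "c_before_sai",
    "c_after_pai",
    "c_after_sai",
    "d_thickness_um",
    "d_bulk_mg_per_ml",
    "thin_thickness_um",
    "pixel_size_um",
)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read the per-block sample table (CSV) and validate its schema."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table {path} lacks columns: {', '.join(missing)}")
    for col in ("d_thickness_um", "thin_thickness_um", "pixel_size_um"):
        if (df[col] <= 0).any():
            raise ValueError(f"sample table column {col} must be positive")
    if (df["d_bulk_mg_per_ml"] < 0).any():
        raise ValueError("bulk concentrations must be >= 0")
    return df


def load_block(
    row: pd.Series, image_dir: str | Path
) -> SampleBlock:
    """Assemble a :class:`SampleBlock` from one sample-table row.

    Image paths in the table are resolved relative to ``image_dir``.
    """
    image_dir = Path(image_dir)

    def _img(col: str, stage: Stage) -> SectionImage:
        return read_section_image(
            image_dir / row[col],
            stage=stage,
            thickness_um=row["thin_thickness_um"],
            pixel_size_um=row["pixel_size_um"],
        )

    return SampleBlock(
        c_before=(_img("c_before_pai", Stage.PAI), _img("c_before_sai", Stage.SAI)),
        c_after=(_img("c_after_pai", Stage.PAI), _img("c_after_sai", Stage.SAI)),
        d_thickness_um=float(row["d_thickness_um"]),
        d_bulk_concentration=float(row["d_bulk_mg_per_ml"]),
        block_id=str(row["block_id"]),
    )
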