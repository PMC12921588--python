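"""Region-based summaries of concentration maps: concentric depth/radial
bands, per-region density histograms, and directional concentration profiles.

Regions partition the tissue mask; region 1 is always the outermost band.
Pixel membership uses pixel centers, and a pixel exactly on a band edge is
assigned to the outer band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ConcentrationMap
from .segmentation import TissueMask

__all__ = [
    "RegionLabels",
    "Profile",
    "concentric_regions",
    "manual_regions",
    "region_histogram",
    "line_profile",
    "radial_profile",
]


@dataclass
class RegionLabels:
    """Integer region labels over a tissue mask.

    ``labels`` is 0 outside the tissue and 1..K inside; regions are disjoint
    and cover the mask. ``band_edges`` (concentric schemes only) holds the
    K+1 edges of the distance coordinate, in px.
    """

    labels: np.ndarray
    names: list[str]
    scheme: str
    pixel_size_um: float = 1.0
    band_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.scheme not in ("concentric_depth", "concentric_centroid", "manual"):
            raise ValueError(f"unknown region scheme {self.scheme!r}")
        k_used = int(self.labels.max(initial=0))
        if len(self.names) < k_used:
            raise ValueError(f"{k_used} labelled regions but {len(self.names)} names")

    @property
    def k(self) -> int:
        return len(self.names)


@dataclass
class Profile:
    """Concentration profile along a spatial coordinate.

    ``positions`` are µm along the sampling direction (strictly increasing),
    with per-step mean ± SD in mg/mL and the pixel count behind each step.
    """

    positions: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n_pixels: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        if not (len(self.positions) == len(self.means) == len(self.sds) == len(self.n_pixels)):
            raise ValueError("profile arrays differ in length")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.n_pixels) and self.n_pixels.min() < 1:
            raise ValueError("every reported step needs at least 1 pixel")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_um": self.positions,
                "mean_mg_per_ml": self.means,
                "sd_mg_per_ml": self.sds,
                "n_pixels": self.n_pixels,
            }
        )


def _band_labels(distance: np.ndarray, mask: np.ndarray, k: int, outer_is_low: bool):
    """Split masked pixels into k equal-width bands of the distance coordinate.

    Band 1 is the outermost band: low distance for depth-to-boundary, high
    distance for centroid radius. Pixels exactly on an internal edge go to
    the outer band.
    """
    d = distance[mask]
    lo, hi = float(d.min()), float(d.max())
    if len(np.unique(d)) < k:
        raise ValueError(f"k={k} exceeds the number of distinct distance values")
    edges = np.linspace(lo, hi, k + 1)
    labels = np.zeros(distance.shape, dtype=int)
    if outer_is_low:
        # band j = (edge_{j-1}, edge_j], closed below only for band 1
        idx = np.searchsorted(edges[1:-1], d, side="left") + 1
    else:
        # outermost = largest distance: band j = [edge_{K+1-j}, edge_{K+2-j})
        idx = k - (np.searchsorted(edges[1:-1], d, side="right"))
        idx = np.clip(idx, 1, k)
    labels[mask] = idx
    return labels, edges


def concentric_regions(
    mask: TissueMask, k: int, scheme: str = "concentric_depth"
) -> RegionLabels:
    """Partition the tissue into k concentric bands.

    ``concentric_depth`` bands the Euclidean distance to the tissue boundary
    (band 1 = surface, band k = core), the coordinate along which an
    outside-in gradient is expressed; ``concentric_centroid`` bands the
    distance from the mask centroid (band 1 = periphery).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    m = mask.mask
    if not m.any():
        raise ValueError("empty tissue mask")
    if scheme == "concentric_depth":
        distance = ndimage.distance_transform_edt(m)
        labels, edges = _band_labels(distance, m, k, outer_is_low=True)
    elif scheme == "concentric_centroid":
        rows, cols = np.indices(m.shape)
        r0, c0 = ndimage.center_of_mass(m)
        distance = np.hypot(rows - r0, cols - c0)
        labels, edges = _band_labels(distance, m, k, outer_is_low=False)
    else:
        raise ValueError(f"unknown concentric scheme {scheme!r}")
    return RegionLabels(
        labels=labels,
        names=[f"R{i}" for i in range(1, k + 1)],
        scheme=scheme,
        pixel_size_um=mask.pixel_size_um,
        band_edges=edges,
    )


def manual_regions(
    labels: np.ndarray, names: list[str], pixel_size_um: float = 1.0
) -> RegionLabels:
    """Wrap user-supplied integer labels (e.g. hand-drawn skin layers) as regions."""
    return RegionLabels(
        labels=np.asarray(labels, dtype=int),
        names=list(names),
        scheme="manual",
        pixel_size_um=pixel_size_um,
    )


def region_histogram(
    cmap: ConcentrationMap, regions: RegionLabels, bins: np.ndarray
) -> pd.DataFrame:
    """Per-region concentration densities plus summary statistics.

    Returns one row per (region, bin) with the normalized density (densities
    integrate to 1 over the binned range) and, repeated per region, the mean,
    median and IQR of its pixel values. Empty regions are flagged with n=0.
    """
    if cmap.values.shape != regions.labels.shape:
        raise ValueError("map and region shapes differ")
    bins = np.asarray(bins, dtype=float)
    rows = []
    for idx, name in enumerate(regions.names, start=1):
        vals = cmap.values[regions.labels == idx]
        if vals.size == 0:
            rows.append(
                {
                    "region": name, "bin_left": np.nan, "bin_right": np.nan,
                    "density": np.nan, "count": 0, "n_pixels": 0,
                    "mean": np.nan, "median": np.nan, "iqr": np.nan,
                    "empty": True,
                }
            )
            continue
        counts, edges = np.histogram(vals, bins=bins)
        densities, _ = np.histogram(vals, bins=bins, density=True)
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        for c, dens, left, right in zip(counts, densities, edges[:-1], edges[1:]):
            rows.append(
                {
                    "region": name, "bin_left": left, "bin_right": right,
                    "density": dens, "count": int(c), "n_pixels": int(vals.size),
                    "mean": vals.mean(), "median": q50, "iqr": q75 - q25,
                    "empty": False,
                }
            )
    return pd.DataFrame(rows)


def line_profile(
    cmap: ConcentrationMap,
    origin: tuple[float, float],
    direction: tuple[float, float],
    band_width_px: int = 1,
    step_px: float = 1.0,
) -> Profile:
    """Concentration vs distance along a ray through the tissue.

    From ``origin`` (x, y in px, inside the mask) step along ``direction``;
    each step averages masked map values inside the rectangle of width
    ``band_width_px`` perpendicular to the direction and length ``step_px``
    along it. The profile stops at the first step whose band has left the
    mask. Positions are converted to µm via the map's pixel size.
    """
    ox, oy = origin
    dx, dy = direction
    norm = float(np.hypot(dx, dy))
    if norm == 0:
        raise ValueError("direction must be nonzero")
    ux, uy = dx / norm, dy / norm
    r, c = int(round(oy)), int(round(ox))
    if not (0 <= r < cmap.mask.shape[0] and 0 <= c < cmap.mask.shape[1]) or not cmap.mask[r, c]:
        raise ValueError("origin lies outside the tissue mask")
    if step_px <= 0 or band_width_px < 1:
        raise ValueError("step_px must be > 0 and band_width_px >= 1")

    rows, cols = np.nonzero(cmap.mask)
    rel_x, rel_y = cols - ox, rows - oy
    along = rel_x * ux + rel_y * uy
    across = -rel_x * uy + rel_y * ux
    in_band = np.abs(across) <= band_width_px / 2.0
    vals = cmap.values[rows, cols]

    positions, means, sds, counts = [], [], [], []
    i = 0
    while True:
        sel = in_band & (along >= i * step_px - step_px / 2.0) & (
            along < i * step_px + step_px / 2.0
        )
        n = int(sel.sum())
        if n == 0:
            break
        v = vals[sel]
        positions.append(i * step_px * cmap.pixel_size_um)
        means.append(float(v.mean()))
        sds.append(float(v.std(ddof=0)))
        counts.append(n)
        i += 1
    return Profile(
        positions=np.array(positions),
        means=np.array(means),
        sds=np.array(sds),
        n_pixels=np.array(counts),
    )


def radial_profile(cmap: ConcentrationMap, regions: RegionLabels) -> Profile:
    """Per-band mean ± SD ordered from the tissue surface inward.

    Positions are the band midpoints of the distance coordinate, in µm.
    Requires a concentric region scheme.
    """
    if regions.scheme == "manual":
        raise ValueError("radial_profile needs a concentric region scheme")
    if cmap.values.shape != regions.labels.shape:
        raise ValueError("map and region shapes differ")
    edges = regions.band_edges
    k = regions.k
    mids = 0.5 * (edges[:-1] + edges[1:])
    if regions.scheme == "concentric_depth":
        # band j covers depth interval (edges[j-1], edges[j]]
        band_pos = mids
    else:
        # band j covers radius interval [edges[k-j], edges[k-j+1]];
        # express position as distance inward from the outer radius
        band_pos = np.array([edges[-1] - mids[k - j] for j in range(1, k + 1)])
    positions, means, sds, counts = [], [], [], []
    for j in range(1, k + 1):  # bands are ordered surface -> inward
        vals = cmap.values[regions.labels == j]
        if vals.size == 0:
            continue
        positions.append(band_pos[j - 1] * regions.pixel_size_um)
        means.append(float(vals.mean()))
        sds.append(float(vals.std(ddof=0)))
        counts.append(int(vals.size))
    return Profile(
        positions=np.array(positions),
        means=np.array(means),
        sds=np.array(sds),
        n_pixels=np.array(counts),
    )
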