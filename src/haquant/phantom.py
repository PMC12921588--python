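"""Synthetic sample blocks with known ground truth for validating the whole
pipeline without real tissue.

A phantom emulates what the acquisition produces: a smooth autofluorescence
field shared by the pre-probe (PAI) and post-probe (SAI) frames, an
analyte-proportional signal added to the SAI, additive Gaussian (optionally
Poisson) noise, a small rigid/similarity misalignment between the two frames
with matching landmark files, and a bulk concentration per simulated thick
section consistent with the ground-truth field plus measurement noise.

All spatial fields (tissue support, concentration law, autofluorescence) are
analytic functions of continuous (x, y) coordinates. The misaligned SAI is
produced by evaluating the scene at the inverse-transformed grid rather than
by resampling a raster, so a noiseless phantom is exact to machine precision
and the ground-truth map can be stored in the very frame the pipeline's FI
image ends up in (the SAI frame).

What the phantom does *not* emulate: optics (PSF, vignetting), mosaic tile
seams, probe-affinity variation, and tissue deformation between serial
sections — the two flanking thin sections share one geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import ConcentrationMap, LandmarkSet, SampleBlock, SectionImage, Stage
from .preprocess import PlanarTransform

__all__ = [
    "ConcentrationLaw",
    "Misalignment",
    "PhantomSpec",
    "PhantomDataset",
    "generate_phantom",
    "generate_calibration_series",
]


@dataclass
class ConcentrationLaw:
    """Parametrized ground-truth concentration as a function of depth.

    ``kind``:
      * ``constant`` — c(depth) = c_surface everywhere;
      * ``linear`` — from c_surface at the boundary to c_deep at maximal depth;
      * ``exponential`` — c_deep + (c_surface − c_deep)·exp(−depth/length_px).

    Concentrations in mg/mL, depth in px.
    """

    kind: str = "constant"
    c_surface: float = 1.0
    c_deep: float = 1.0
    length_px: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear", "exponential"):
            raise ValueError(f"unknown concentration law {self.kind!r}")
        if self.c_surface < 0 or self.c_deep < 0:
            raise ValueError("concentrations must be >= 0")
        if self.length_px <= 0:
            raise ValueError("length_px must be > 0")

    def evaluate(self, depth: np.ndarray, max_depth: float) -> np.ndarray:
        if self.kind == "constant":
            return np.full_like(depth, self.c_surface, dtype=float)
        if self.kind == "linear":
            frac = np.clip(depth / max_depth, 0.0, 1.0)
            return self.c_surface + (self.c_deep - self.c_surface) * frac
        return self.c_deep + (self.c_surface - self.c_deep) * np.exp(
            -np.clip(depth, 0.0, None) / self.length_px
        )


@dataclass
class Misalignment:
    """Similarity misalignment between the PAI and SAI acquisitions.

    Maps PAI (moving) coordinates to SAI (fixed) coordinates: rotation about
    the frame center by ``rotation_deg``, isotropic ``scale``, then
    translation by (tx, ty) px.
    """

    tx: float = 3.0
    ty: float = 2.0
    rotation_deg: float = 0.4
    scale: float = 1.0

    def transform(self, shape: tuple[int, int]) -> PlanarTransform:
        cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        th = math.radians(self.rotation_deg)
        s = self.scale
        rot = s * np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        center = np.array([cx, cy])
        t = center - rot @ center + np.array([self.tx, self.ty])
        return PlanarTransform(kind="similarity", matrix=np.column_stack([rot, t]))

    @classmethod
    def identity(cls) -> "Misalignment":
        return cls(tx=0.0, ty=0.0, rotation_deg=0.0, scale=1.0)


@dataclass
class PhantomSpec:
    """Full parametrization of one synthetic sample block.

    Defaults describe a realistic small acquisition: a 192×192 px field of
    view at 1 µm/px, a disk of tissue holding ~1 mg/mL of analyte, smooth
    autofluorescence around 200 AU, probe gain 1200 AU per mg/mL (signal ≈
    5× the autofluorescence), read noise of a few AU, a few-pixel stage shift
    between the paired frames, and a 5% CV on the bulk biochemical assay.
    """

    shape: tuple[int, int] = (192, 192)
    tissue_geometry: str = "disk"
    concentration_law: ConcentrationLaw = field(default_factory=ConcentrationLaw)
    af_mean: float = 200.0
    af_scale_px: float = 60.0
    af_n_blobs: int = 4
    af_amplitude: float = 60.0
    gain: float = 1200.0
    curvature: float = 0.0
    noise_sigma: float = 3.0
    poisson: bool = False
    misalignment: Misalignment = field(default_factory=Misalignment)
    elisa_cv: float = 0.05
    thin_thickness_um: float = 5.0
    thick_thickness_um: float = 400.0
    pixel_size_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue_geometry not in ("disk", "layered_slab", "annulus"):
            raise ValueError(f"unknown geometry {self.tissue_geometry!r}")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        for name in ("af_mean", "af_amplitude", "noise_sigma", "elisa_cv", "curvature"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.shape) < 32:
            raise ValueError("phantom must be at least 32 px on a side")


@dataclass
class PhantomDataset:
    """One generated block plus everything needed to score the pipeline.

    ``truth_map`` (and its mask) live in the SAI frame — the frame the
    pipeline's FI image is produced in. ``bulk_true`` is the mean of the
    truth over its support before assay noise; the block carries the noisy
    value. ``fi_of_concentration`` is the generating FI(c) law (per pixel,
    AU) used by curve-mode round trips.
    """

    truth_map: ConcentrationMap
    block: SampleBlock
    landmarks: LandmarkSet
    misalignment_transform: PlanarTransform
    bulk_true: float
    spec: PhantomSpec

    def fi_of_concentration(self, c: np.ndarray | float) -> np.ndarray | float:
        s = self.spec
        return s.gain * c * (1.0 + s.curvature * c)


# --- analytic scene -------------------------------------------------------


def _geometry(spec: PhantomSpec):
    """Return (support(x, y), depth(x, y), max_depth) as analytic callables."""
    rows, cols = spec.shape
    if spec.tissue_geometry == "disk":
        cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
        radius = 0.38 * min(rows, cols)

        def depth(x, y):
            return radius - np.hypot(x - cx, y - cy)

        return (lambda x, y: depth(x, y) >= 0), depth, radius
    if spec.tissue_geometry == "annulus":
        cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
        r_out = 0.42 * min(rows, cols)
        r_in = 0.18 * min(rows, cols)

        def depth(x, y):
            r = np.hypot(x - cx, y - cy)
            return np.minimum(r_out - r, r - r_in)

        return (lambda x, y: depth(x, y) >= 0), depth, (r_out - r_in) / 2.0
    # layered slab: a rectangle with depth measured from its top edge, the
    # skin-like geometry (surface layer at the top, deep layer at the bottom)
    m_r, m_c = int(0.12 * rows), int(0.12 * cols)
    top, bottom = m_r, rows - 1 - m_r
    left, right = m_c, cols - 1 - m_c

    def support(x, y):
        return (y >= top) & (y <= bottom) & (x >= left) & (x <= right)

    def depth(x, y):
        return y - top

    return support, depth, float(bottom - top)


def _autofluorescence_params(spec: PhantomSpec, rng: np.random.Generator):
    rows, cols = spec.shape
    centers = rng.uniform(low=[0, 0], high=[cols - 1, rows - 1], size=(spec.af_n_blobs, 2))
    amps = rng.uniform(0.3, 1.0, size=spec.af_n_blobs) * spec.af_amplitude
    sigmas = rng.uniform(0.7, 1.3, size=spec.af_n_blobs) * spec.af_scale_px
    return centers, amps, sigmas


def _autofluorescence(x, y, params, af_mean: float):
    centers, amps, sigmas = params
    out = np.full(np.broadcast(x, y).shape, af_mean, dtype=float)
    for (cx, cy), a, s in zip(centers, amps, sigmas):
        out += a * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * s**2))
    return out


def _apply_noise(clean: np.ndarray, spec: PhantomSpec, rng: np.random.Generator):
    noisy = clean
    if spec.poisson:
        noisy = rng.poisson(np.clip(noisy, 0.0, None)).astype(float)
    if spec.noise_sigma > 0:
        noisy = noisy + rng.normal(0.0, spec.noise_sigma, size=clean.shape)
    return np.clip(noisy, 0.0, None)


def generate_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Generate one synthetic block, deterministically for a given seed.

    The PAI is the autofluorescence field (plus noise) in its own frame; the
    SAI is autofluorescence + gain·truth evaluated at the inverse-misaligned
    coordinates (plus independent noise); the emitted landmarks map PAI
    coordinates to SAI coordinates exactly. The two flanking thin sections
    share the scene but draw independent noise. All randomness comes from a
    single stream seeded with ``spec.seed``, drawn in a fixed order
    (autofluorescence shape, then per-section noise, then assay noise).
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    support, depth, max_depth = _geometry(spec)
    af_params = _autofluorescence_params(spec, rng)
    tf = spec.misalignment.transform(spec.shape)
    tf_inv = tf.inverse()

    yy, xx = np.indices((rows, cols), dtype=float)
    # SAI-frame grid pulled back into the scene (PAI) frame
    back = tf_inv.apply(np.column_stack([xx.ravel(), yy.ravel()]))
    xb = back[:, 0].reshape(rows, cols)
    yb = back[:, 1].reshape(rows, cols)

    sup_sai = support(xb, yb)
    truth = np.where(
        sup_sai,
        spec.concentration_law.evaluate(np.where(sup_sai, depth(xb, yb), 0.0), max_depth),
        0.0,
    )
    if not sup_sai.any():
        raise ValueError("degenerate geometry: no tissue in the field of view")

    af_pai = _autofluorescence(xx, yy, af_params, spec.af_mean)
    af_sai = _autofluorescence(xb, yb, af_params, spec.af_mean)
    signal = spec.gain * truth * (1.0 + spec.curvature * truth)

    def section_pair(suffix: str) -> tuple[SectionImage, SectionImage]:
        pai = _apply_noise(af_pai.copy(), spec, rng)
        sai = _apply_noise(af_sai + signal, spec, rng)
        common = dict(thickness_um=spec.thin_thickness_um, pixel_size_um=spec.pixel_size_um)
        return (
            SectionImage(pixels=pai, stage=Stage.PAI, section_id=f"{suffix}_PAI", **common),
            SectionImage(pixels=sai, stage=Stage.SAI, section_id=f"{suffix}_SAI", **common),
        )

    c_before = section_pair("C_n.2")
    c_after = section_pair("C_n+1.1")

    bulk_true = float(truth[sup_sai].mean())
    bulk = bulk_true * (1.0 + spec.elisa_cv * rng.standard_normal()) if spec.elisa_cv > 0 else bulk_true
    bulk = max(bulk, 0.0)

    # landmarks: four interior points of the PAI frame, mapped exactly
    mr, mc = 0.15 * (rows - 1), 0.15 * (cols - 1)
    moving = np.array(
        [[mc, mr], [cols - 1 - mc, mr], [cols - 1 - mc, rows - 1 - mr], [mc, rows - 1 - mr]]
    )
    landmarks = LandmarkSet(moving=moving, fixed=tf.apply(moving))

    block = SampleBlock(
        c_before=c_before,
        c_after=c_after,
        d_thickness_um=spec.thick_thickness_um,
        d_bulk_concentration=bulk,
        block_id=f"phantom_seed{spec.seed}",
    )
    truth_map = ConcentrationMap(
        values=truth,
        mask=sup_sai,
        pixel_size_um=spec.pixel_size_um,
        thickness_um=spec.thin_thickness_um,
        mode="curve",
    )
    return PhantomDataset(
        truth_map=truth_map,
        block=block,
        landmarks=landmarks,
        misalignment_transform=tf,
        bulk_true=bulk_true,
        spec=spec,
    )


def generate_calibration_series(
    base_spec: PhantomSpec, levels: list[float], seed: int | None = None
) -> list[PhantomDataset]:
    """One phantom block per concentration level, sharing acquisition
    parameters.

    Each level gets a constant-concentration version of the base spec with an
    independent per-level seed derived from ``seed`` (default: the base
    spec's seed). Set ``base_spec.curvature`` > 0 to make FI a quadratic
    function of concentration and exercise calibration model selection.
    """
    if len(levels) < 2:
        raise ValueError("need at least 2 concentration levels")
    if any(lv < 0 for lv in levels):
        raise ValueError("levels must be >= 0")
    root = np.random.SeedSequence(base_spec.seed if seed is None else seed)
    children = root.spawn(len(levels))
    datasets = []
    for level, child in zip(levels, children):
        spec = replace(
            base_spec,
            concentration_law=ConcentrationLaw(kind="constant", c_surface=level, c_deep=level),
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        datasets.append(generate_phantom(spec))
    return datasets
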