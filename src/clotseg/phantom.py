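"""Digital CT phantoms with a hyperdense MCA-M1-like clot and known truth.

Each phantom is a paired NCCT/CTA volume at thin-slice head-CT geometry
(default 0.625 mm isotropic, 128 x 128 x 64): uniform brain parenchyma, two
mirrored straight arterial tubes, one of which carries a hyperdense clot
segment (NCCT) appearing as a contrast filling defect (CTA), plus two
ventricle-like hypodense ellipsoids that give rigid registration anatomical
anchors. Geometry is evaluated analytically in physical coordinates, so the
CTA can be "acquired" under a rigid offset without interpolation error and
the ground-truth clot mask is exact.

All randomness flows from one integer seed through a counter-based
``SeedSequence`` splitting rule, so each noise stream is independently
reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .volume_core import Centerline, Mask, ROISpec, RigidTransform, Volume

__all__ = [
    "PhantomParams",
    "Phantom",
    "generate_phantom",
    "degrade_slices",
    "generate_cohort",
    "sample_phantom_params",
    "COHORT_COLUMNS",
]

VENTRICLE_HU = 8.0  # CSF-like density, well below parenchyma

COHORT_COLUMNS = [
    "subject",
    "age",
    "hematocrit",
    "slice_thickness_mm",
    "parenchyma_hu",
    "artery_hu",
    "thrombus_hu",
    "optimal_threshold_hu",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Counter-split generator: one integer seed, independent named streams."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class PhantomParams:
    """Generating parameters for one synthetic subject.

    HU means are per-subject constants (cohort-level spread belongs to
    :func:`sample_phantom_params`); ``noise_sd`` is the within-scan Gaussian
    voxel noise. Defaults sit where the clinical data lived: parenchyma
    ~34 HU gives a parenchyma-model predicted threshold of ~51 HU, the
    cohort median, and artery ~44 HU gives ~51 HU via the artery model.
    """

    shape: tuple[int, int, int] = (128, 128, 64)
    spacing: tuple[float, float, float] = (0.625, 0.625, 0.625)
    parenchyma_hu: float = 34.0
    artery_hu: float = 44.0
    clot_hu: float = 55.0
    contrast_hu: float = 150.0
    vessel_radius_mm: float = 1.5
    clot_length_mm: float = 12.0
    noise_sd: float = 3.0
    slice_factor: int = 1
    seed: int = 0
    hematocrit: float = 0.42
    transform: RigidTransform | None = None
    include_ventricles: bool = True

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)  # type: ignore[assignment]
        if len(self.shape) != 3 or min(self.shape) < 8:
            raise ValueError("phantom grid must be 3D with at least 8 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.clot_hu <= self.parenchyma_hu:
            raise ValueError(
                "no hyperdense sign: clot HU must exceed parenchyma HU "
                f"(got clot {self.clot_hu}, parenchyma {self.parenchyma_hu})"
            )
        if self.vessel_radius_mm <= 0 or self.clot_length_mm <= 0:
            raise ValueError("vessel radius and clot length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if int(self.slice_factor) < 1:
            raise ValueError("slice-degradation factor must be >= 1")
        ex, ey, ez = (n * s for n, s in zip(self.shape, self.spacing))
        if self.clot_length_mm > 0.8 * ex:
            raise ValueError("clot does not fit grid along x")
        if 2 * self.vessel_radius_mm > 0.2 * min(ey, ez):
            raise ValueError("vessel radius too large for grid")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]


def _geometry(params: PhantomParams) -> dict:
    ex, ey, ez = params.extent_mm
    zc = 0.5 * ez
    geom = {
        "occluded_y": 0.375 * ey,
        "patent_y": 0.625 * ey,
        "z_center": zc,
        "clot_x_center": 0.5 * ex,
        "ellipsoids": [],
    }
    if params.include_ventricles:
        # placed clear of both tubes and the default parenchyma ROI; sizes and
        # positions asymmetric so rigid registration is constrained in all axes
        geom["ellipsoids"] = [
            ((0.65 * ex, 0.50 * ey, 0.60 * ez), (12.0, 6.0, 5.0)),
            ((0.30 * ex, 0.725 * ey, 0.40 * ez), (8.0, 5.0, 4.0)),
            ((0.75 * ex, 0.25 * ey, 0.35 * ez), (6.0, 4.0, 3.5)),
        ]
    return geom


def _ideal_field(
    params: PhantomParams,
    geom: dict,
    px: np.ndarray,
    py: np.ndarray,
    pz: np.ndarray,
    modality: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless HU field at physical points; also returns the clot indicator."""
    val = np.full(px.shape, params.parenchyma_hu, dtype=np.float64)
    for (cx, cy, cz), (rx, ry, rz) in geom["ellipsoids"]:
        inside = ((px - cx) / rx) ** 2 + ((py - cy) / ry) ** 2 + ((pz - cz) / rz) ** 2 <= 1.0
        val[inside] = VENTRICLE_HU
    r2 = params.vessel_radius_mm**2
    occ = (py - geom["occluded_y"]) ** 2 + (pz - geom["z_center"]) ** 2 <= r2
    pat = (py - geom["patent_y"]) ** 2 + (pz - geom["z_center"]) ** 2 <= r2
    clot = occ & (np.abs(px - geom["clot_x_center"]) <= 0.5 * params.clot_length_mm)
    if modality == "ncct":
        val[occ] = params.artery_hu
        val[pat] = params.artery_hu
        val[clot] = params.clot_hu
    elif modality == "cta":
        val[occ] = params.artery_hu + params.contrast_hu
        val[pat] = params.artery_hu + params.contrast_hu
        # filling defect: no contrast over the clot segment
        val[clot] = params.parenchyma_hu
    else:  # pragma: no cover - internal
        raise ValueError(modality)
    return val, clot


@dataclass
class Phantom:
    """Paired NCCT/CTA volumes with exact clot truth and generating params."""

    ncct: Volume
    cta: Volume
    truth_mask: Mask
    centerline: Centerline
    params: PhantomParams
    applied_transform: RigidTransform

    def default_parenchyma_roi(self, size: int = 10) -> ROISpec:
        """A parenchyma ROI placed analytically clear of vessels/ventricles."""
        nx, ny, nz = self.ncct.shape
        return ROISpec(center=(nx // 2, max(size, 12), nz // 2), size=size, tissue_class="parenchyma")

    def default_seeds(self, n: int = 3) -> list[tuple[int, int, int]]:
        """Seed voxels at equidistant arc-length fractions of the centerline."""
        cl = self.centerline
        seeds = []
        for i in range(n):
            p = cl.point_at_arclength((i + 0.5) / n * cl.arc_length)
            idx = np.rint(self.ncct.physical_to_index(p)).astype(int)
            seeds.append(tuple(int(v) for v in idx))
        return seeds

    def default_box(self, margin: int = 8) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        """Truth-mask bounding box padded by ``margin`` voxels (half-open)."""
        idx = np.argwhere(self.truth_mask.data)
        lo = np.maximum(idx.min(axis=0) - margin, 0)
        hi = np.minimum(idx.max(axis=0) + 1 + margin, self.truth_mask.shape)
        return tuple(int(v) for v in lo), tuple(int(v) for v in hi)


def generate_phantom(params: PhantomParams) -> Phantom:
    """Build a paired NCCT/CTA phantom with exact ground truth.

    The NCCT is sampled on the reference grid; the CTA is sampled at
    coordinates pushed through ``params.transform`` (CTA relative to NCCT),
    so ``resample(cta, transform, ncct)`` re-aligns it and rigid registration
    has a known answer to recover. With ``noise_sd = 0`` every truth-mask
    voxel equals ``clot_hu`` exactly.
    """
    geom = _geometry(params)
    nx, ny, nz = params.shape
    sx, sy, sz = params.spacing
    ix = np.arange(nx) * sx
    iy = np.arange(ny) * sy
    iz = np.arange(nz) * sz
    px, py, pz = np.meshgrid(ix, iy, iz, indexing="ij")

    ncct_vals, clot = _ideal_field(params, geom, px, py, pz, "ncct")
    if not clot.any():
        raise ValueError("clot does not fit grid: truth mask is empty")

    transform = params.transform or RigidTransform()
    pts = np.stack([px, py, pz], axis=-1).reshape(-1, 3)
    tpts = transform.apply_points(pts)
    cta_vals, _ = _ideal_field(
        params,
        geom,
        tpts[:, 0].reshape(px.shape),
        tpts[:, 1].reshape(px.shape),
        tpts[:, 2].reshape(px.shape),
        "cta",
    )

    if params.noise_sd > 0:
        ncct_vals = ncct_vals + _rng(params.seed, 1).normal(0.0, params.noise_sd, ncct_vals.shape)
        cta_vals = cta_vals + _rng(params.seed, 2).normal(0.0, params.noise_sd, cta_vals.shape)

    ncct = Volume(ncct_vals, spacing=params.spacing)
    cta = Volume(cta_vals, spacing=params.spacing)
    truth = Mask(clot, spacing=params.spacing, label="clot_truth")

    x0 = geom["clot_x_center"] - 0.5 * params.clot_length_mm
    x1 = geom["clot_x_center"] + 0.5 * params.clot_length_mm
    xs = np.linspace(x0, x1, 5)
    cl_pts = np.column_stack([xs, np.full(5, geom["occluded_y"]), np.full(5, geom["z_center"])])
    centerline = Centerline(cl_pts)

    if int(params.slice_factor) > 1:
        f = int(params.slice_factor)
        ncct = degrade_slices(ncct, f)
        cta = degrade_slices(cta, f)
        slab = clot.reshape(nx, ny, nz // f, f).mean(axis=3) >= 0.5
        truth = Mask(slab, spacing=ncct.spacing, origin=ncct.origin, label="clot_truth")
        if not truth.data.any():
            raise ValueError("clot does not survive slice degradation")

    return Phantom(ncct, cta, truth, centerline, params, transform)


def degrade_slices(vol: Volume, factor: int) -> Volume:
    """Thick-slice simulation: average groups of ``factor`` axial slices.

    Models the partial-volume blending along z that thick-slice NCCT
    introduces; in-plane sampling is unchanged, slice spacing is multiplied.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return Volume(vol.data.copy(), vol.spacing, vol.origin)
    nx, ny, nz = vol.shape
    if nz % factor != 0:
        raise ValueError(f"factor {factor} does not divide z-dimension {nz}")
    data = vol.data.reshape(nx, ny, nz // factor, factor).mean(axis=3)
    sx, sy, sz = vol.spacing
    ox, oy, oz = vol.origin
    return Volume(data, (sx, sy, sz * factor), (ox, oy, oz + 0.5 * sz * (factor - 1)))


def generate_cohort(
    n: int,
    model: str = "parenchyma",
    noise_sd: float = 3.0,
    seed: int = 0,
    hematocrit_corr: float = 0.43,
) -> pd.DataFrame:
    """Simulate a cohort covariate table under a known threshold regression.

    The ROC-optimal-threshold column is generated from the published linear
    predictor for ``model`` ("parenchyma": 0.62 x + 30.0; "artery":
    0.45 x + 31) plus ``Normal(0, noise_sd^2)`` HU noise. Predictors follow
    parenchyma ~ Normal(34, 3^2) and artery ~ Normal(44, 4^2); hematocrit is
    coupled to the artery-HU deviate at population correlation
    ``hematocrit_corr``. Fully determined by ``seed``.
    """
    from .thresholding import PUBLISHED_MODELS

    if n < 3:
        raise ValueError("cohort needs at least 3 subjects")
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    if model not in PUBLISHED_MODELS:
        raise ValueError(f"model must be one of {sorted(PUBLISHED_MODELS)}, got {model!r}")
    if not -1.0 <= hematocrit_corr <= 1.0:
        raise ValueError("hematocrit correlation must be in [-1, 1]")

    z_par = _rng(seed, 10).standard_normal(n)
    z_art = _rng(seed, 11).standard_normal(n)
    eps_h = _rng(seed, 12).standard_normal(n)
    z_thr = _rng(seed, 13).standard_normal(n)
    noise = _rng(seed, 14).standard_normal(n)
    age = np.clip(np.rint(_rng(seed, 15).normal(70.0, 12.0, n)), 35, 95).astype(int)
    thick = _rng(seed, 16).choice([0.625, 1.25, 2.5], size=n, p=[0.5, 0.3, 0.2])

    parenchyma = 34.0 + 3.0 * z_par
    artery = 44.0 + 4.0 * z_art
    rho = hematocrit_corr
    hematocrit = 0.42 + 0.05 * (rho * z_art + np.sqrt(1.0 - rho**2) * eps_h)
    thrombus = 55.0 + 4.0 * z_thr

    m = PUBLISHED_MODELS[model]
    predictor = parenchyma if model == "parenchyma" else artery
    threshold = m.intercept + m.slope * predictor + noise_sd * noise

    return pd.DataFrame(
        {
            "subject": np.arange(n),
            "age": age,
            "hematocrit": hematocrit,
            "slice_thickness_mm": thick,
            "parenchyma_hu": parenchyma,
            "artery_hu": artery,
            "thrombus_hu": thrombus,
            "optimal_threshold_hu": threshold,
        }
    )


def sample_phantom_params(
    n: int,
    seed: int = 0,
    parenchyma_mean: float = 34.0,
    parenchyma_sd: float = 2.0,
    artery_offset: float = 10.0,
    clot_offset: float = 21.0,
    noise_sd: float = 3.0,
    hematocrit_corr: float = 0.43,
    max_translation_mm: float = 0.0,
    max_rotation_deg: float = 0.0,
    **overrides,
) -> list[PhantomParams]:
    """Draw per-subject phantom parameters for a cohort of ``n`` phantoms.

    Parenchyma HU varies across subjects; artery and clot HU ride on top of
    it at the default contrasts (+10 and +21 HU), mimicking a global
    (hematocrit-like) tissue-density shift, so the hyperdense sign is
    preserved whatever the parenchyma level. Optional random rigid offsets
    (uniform within the stated bounds) misalign each CTA.
    """
    if n < 1:
        raise ValueError("need at least one subject")
    rng = _rng(seed, 20)
    z_par = rng.standard_normal(n)
    z_art = _rng(seed, 21).standard_normal(n)
    eps_h = _rng(seed, 22).standard_normal(n)
    z_clot = _rng(seed, 23).standard_normal(n)
    trng = _rng(seed, 24)
    sub_seeds = [
        int(np.random.SeedSequence(seed, spawn_key=(30, i)).generate_state(1)[0] >> 1)
        for i in range(n)
    ]

    rho = hematocrit_corr
    out = []
    for i in range(n):
        mu_p = parenchyma_mean + parenchyma_sd * z_par[i]
        mu_a = mu_p + artery_offset + 1.5 * z_art[i]
        mu_c = mu_p + clot_offset + 2.0 * z_clot[i]
        hct = 0.42 + 0.05 * (rho * z_art[i] + np.sqrt(1.0 - rho**2) * eps_h[i])
        transform = None
        if max_translation_mm > 0 or max_rotation_deg > 0:
            t = trng.uniform(-max_translation_mm, max_translation_mm, 3)
            r = np.deg2rad(trng.uniform(-max_rotation_deg, max_rotation_deg, 3))
            shape = overrides.get("shape", PhantomParams.shape)
            spacing = overrides.get("spacing", PhantomParams.spacing)
            center = tuple(0.5 * d * s for d, s in zip(shape, spacing))
            transform = RigidTransform(tuple(r), tuple(t), center)
        out.append(
            PhantomParams(
                parenchyma_hu=float(mu_p),
                artery_hu=float(mu_a),
                clot_hu=float(mu_c),
                noise_sd=noise_sd,
                seed=sub_seeds[i],
                hematocrit=float(hct),
                transform=transform,
                **overrides,
            )
        )
    return out
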