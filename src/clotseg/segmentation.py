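"""3D thrombus segmentation: smooth, then grow from seeds inside a box.

Pipeline (per scan): restrict to a manually drawn bounding box around the
hyperdense artery sign, reduce noise with edge-preserving Perona-Malik
diffusion, then volume-grow from seed voxels placed on the sign, keeping
voxels whose smoothed HU lies in [lower, upper]. The lower threshold is
either the conventional fixed 45 HU or the patient-specific value predicted
from a contralateral-parenchyma (or artery) ROI, rounded to integer HU.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .thresholding import ThresholdModel, predict_threshold
from .volume_core import Mask, ROISpec, Volume, extract_roi_values

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "anisotropic_smooth",
    "volume_grow",
    "segment_thrombus",
    "FIXED_THRESHOLD_HU",
]

logger = logging.getLogger(__name__)

FIXED_THRESHOLD_HU = 45.0
THRESHOLD_MODES = ("fixed45", "patient_specific")


@dataclass
class SegmentationConfig:
    """All knobs of the segmentation pipeline, recorded as provenance."""

    threshold_mode: str = "fixed45"
    seeds: list[tuple[int, int, int]] = field(default_factory=list)
    box: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None
    upper_hu: float | None = 100.0
    connectivity: int = 26
    smooth_iterations: int = 5
    smooth_time_step: float = 0.0625
    smooth_conductance: float = 3.0

    def __post_init__(self) -> None:
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(f"threshold_mode must be one of {THRESHOLD_MODES}")
        if len(self.seeds) < 1:
            raise ValueError("at least one seed voxel is required")
        self.seeds = [tuple(int(v) for v in s) for s in self.seeds]
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class SegmentationResult:
    """Binary clot mask plus provenance and derived morphometry."""

    mask: Mask
    config: SegmentationConfig
    threshold_hu: float
    volume_mm3: float
    length_mm: float
    n_components: int
    seed_fates: list[str]


def anisotropic_smooth(
    vol: Volume,
    iterations: int = 5,
    time_step: float = 0.0625,
    conductance: float = 3.0,
) -> Volume:
    """Perona-Malik gradient-modulated diffusion (explicit scheme).

    Neighbour differences are taken in index space with conductance in HU:
    flux across each voxel interface is ``exp(-(dHU/conductance)^2) * dHU``.
    With ``time_step <= 1/(2*ndim)`` every update is a convex combination of
    neighbours, so the maximum principle holds and ``iterations = 0`` is the
    identity. Strong edges (|dHU| >> conductance) pass almost no flux and
    are preserved.
    """
    iterations = int(iterations)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    stable = 1.0 / (2.0 * vol.data.ndim)
    if time_step <= 0 or time_step > stable:
        raise ValueError(
            f"unstable time step {time_step}; explicit 3D diffusion requires 0 < dt <= {stable}"
        )
    if conductance <= 0:
        raise ValueError("conductance must be positive")

    u = vol.data.copy()
    k2 = float(conductance) ** 2
    for _ in range(iterations):
        div = np.zeros_like(u)
        for ax in range(3):
            d = np.diff(u, axis=ax)
            flux = np.exp(-(d * d) / k2) * d
            pad = [(0, 0)] * 3
            pad[ax] = (1, 1)  # zero-flux boundary
            flux = np.pad(flux, pad)
            div += np.diff(flux, axis=ax)
        u += time_step * div
    return Volume(u, vol.spacing, vol.origin)


def _in_box(seed, box) -> bool:
    (lo, hi) = box
    return all(lo[d] <= seed[d] < hi[d] for d in range(3))


def volume_grow(
    vol: Volume,
    seeds: Sequence[tuple[int, int, int]],
    lower: float,
    upper: float | None = None,
    connectivity: int = 26,
    box: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None,
) -> Mask:
    """Seeded 3D region growing within an HU band, restricted to a box.

    The mask is the set of voxels connected (6- or 26-neighbourhood) to any
    seed through voxels with HU in ``[lower, upper]``, intersected with the
    bounding box. Seeds whose own HU falls outside the band contribute
    nothing (logged); if no seed survives, an empty mask is returned with a
    warning.
    """
    if upper is not None and lower >= upper:
        raise ValueError(f"lower threshold {lower} must be below upper {upper}")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    if len(seeds) == 0:
        raise ValueError("at least one seed voxel is required")
    nx, ny, nz = vol.shape
    if box is None:
        box = ((0, 0, 0), (nx, ny, nz))
    (lo, hi) = box
    if any(l < 0 for l in lo) or any(h > s for h, s in zip(hi, vol.shape)) or any(
        h <= l for l, h in zip(lo, hi)
    ):
        raise ValueError(f"bounding box {box} invalid for volume of shape {vol.shape}")
    for s in seeds:
        if not all(0 <= s[d] < vol.shape[d] for d in range(3)):
            raise ValueError(f"seed {s} outside volume of shape {vol.shape}")
        if not _in_box(s, box):
            raise ValueError(f"seed {s} outside bounding box {box}")

    band = vol.data >= lower
    if upper is not None:
        band &= vol.data <= upper
    restricted = np.zeros_like(band)
    restricted[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = band[
        lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]
    ]

    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, _ = ndimage.label(restricted, structure=structure)
    keep: set[int] = set()
    for s in seeds:
        lab = int(labels[s])
        if lab > 0:
            keep.add(lab)
        else:
            logger.warning("seed %s has HU %.1f outside [%s, %s]; ignored",
                           s, vol.data[s], lower, upper)
    if not keep:
        warnings.warn(
            f"no seed inside HU band [{lower}, {upper}]; returning empty mask", RuntimeWarning
        )
        grown = np.zeros_like(restricted)
    else:
        grown = np.isin(labels, sorted(keep))
    return Mask(grown, vol.spacing, vol.origin, label=f"clot_{lower:g}HU")


def segment_thrombus(
    ncct: Volume,
    config: SegmentationConfig,
    model: ThresholdModel | None = None,
    parenchyma_roi: ROISpec | None = None,
) -> SegmentationResult:
    """Run the full segmentation pipeline on one NCCT.

    In ``patient_specific`` mode the lower threshold is the model prediction
    at the mean HU of the raw (unsmoothed) parenchyma ROI, rounded to the
    nearest integer HU; in ``fixed45`` mode it is 45 HU and any supplied
    model is ignored. The box is cropped first, smoothing and growing happen
    inside it, and the mask is re-embedded on the full grid.
    """
    nx, ny, nz = ncct.shape
    box = config.box or ((0, 0, 0), (nx, ny, nz))
    (lo, hi) = box

    if config.threshold_mode == "patient_specific":
        if model is None or parenchyma_roi is None:
            raise ValueError("patient_specific mode requires a model and a parenchyma ROI")
        if model.predictor == "parenchyma" and parenchyma_roi.tissue_class != "parenchyma":
            raise ValueError("predictor ROI tissue class does not match the model predictor")
        predictor_hu = float(np.mean(extract_roi_values(ncct, parenchyma_roi)))
        lower = float(np.rint(predict_threshold(model, predictor_hu)))
    else:
        lower = FIXED_THRESHOLD_HU

    for s in config.seeds:
        if not _in_box(s, box):
            raise ValueError(f"seed {s} outside bounding box {box}")

    sub = Volume(
        ncct.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].copy(),
        ncct.spacing,
        tuple(o + l * s for o, l, s in zip(ncct.origin, lo, ncct.spacing)),
    )
    smoothed = anisotropic_smooth(
        sub, config.smooth_iterations, config.smooth_time_step, config.smooth_conductance
    )
    sub_seeds = [tuple(s[d] - lo[d] for d in range(3)) for s in config.seeds]
    sub_mask = volume_grow(
        smoothed, sub_seeds, lower, config.upper_hu, config.connectivity, box=None
    )

    full = np.zeros(ncct.shape, dtype=bool)
    full[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub_mask.data
    mask = Mask(full, ncct.spacing, ncct.origin, label=f"clot_{config.threshold_mode}")

    seed_fates = []
    for s, ss in zip(config.seeds, sub_seeds):
        hu = smoothed.data[ss]
        ok = hu >= lower and (config.upper_hu is None or hu <= config.upper_hu)
        seed_fates.append(f"seed {s}: smoothed HU {hu:.1f} " + ("in band", "rejected")[not ok])

    structure = ndimage.generate_binary_structure(3, 1 if config.connectivity == 6 else 3)
    _, n_comp = ndimage.label(mask.data, structure=structure)

    if mask.voxel_count:
        from .evaluation import clot_length  # deferred: evaluation imports this module

        length = clot_length(mask)
    else:
        length = 0.0
    return SegmentationResult(
        mask=mask,
        config=config,
        threshold_hu=lower,
        volume_mm3=mask.volume_mm3,
        length_mm=length,
        n_components=int(n_comp),
        seed_fates=seed_fates,
    )
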