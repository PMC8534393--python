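"""Domain types for HU volumes, masks, ROIs, rigid transforms and centerlines.

Conventions
-----------
* Arrays are indexed ``(x, y, z)`` with ``z`` the slice axis; voxel indices
  are 0-based.
* Physical position of voxel ``(i, j, k)`` is ``origin + index * spacing``
  (millimetres, axis-aligned grid, identity direction matrix).
* HU values are stored as floating point internally even when files carry
  integers, so smoothed volumes need no separate type.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk
from scipy.spatial.transform import Rotation

__all__ = [
    "Volume",
    "Mask",
    "ROISpec",
    "RigidTransform",
    "Centerline",
    "read_volume",
    "write_volume",
    "extract_roi_values",
    "mask_to_mesh",
    "write_mesh",
]

_EXTENSIONS = {
    "nifti": (".nii", ".nii.gz"),
    "metaimage": (".mha", ".mhd"),
}

TISSUE_CLASSES = ("thrombus", "contralateral_vessel", "parenchyma")


def _as_triple(value, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in value)
    if len(t) != 3:
        raise ValueError(f"{name} must have exactly 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class Volume:
    """A 3D scalar grid of HU values with anisotropic voxel spacing.

    Parameters
    ----------
    data
        3D array of HU values, axis order ``(x, y, z)``.
    spacing
        Voxel spacing ``(sx, sy, sz)`` in mm, strictly positive.
    origin
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D data")
        if min(self.data.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def index_to_physical(self, index: Sequence[float]) -> np.ndarray:
        """Physical mm coordinates of a (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def physical_to_index(self, point: Sequence[float]) -> np.ndarray:
        return (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def to_sitk(self, dtype=np.float32) -> sitk.Image:
        """Convert to a SimpleITK image (which stores arrays as (z, y, x))."""
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.astype(dtype).transpose(2, 1, 0)))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(arr, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


@dataclass
class Mask:
    """Binary voxel mask sharing a Volume's grid geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D data")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        """Physical volume: voxel count x sx*sy*sz."""
        sx, sy, sz = self.spacing
        return self.voxel_count * sx * sy * sz

    def same_grid(self, other: "Mask | Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class ROISpec:
    """A single-slice axial ROI: a w x h in-plane patch centred on a voxel.

    ``size`` may be an odd integer (square patch) or an explicit ``(w, h)``
    pair. The slice extent is fixed at one slice: all ROIs live in the axial
    view. The study protocol uses 3x3 patches for thrombus and contralateral
    vessel and a single 10x10 patch for normal parenchyma.
    """

    center: tuple[int, int, int]
    size: int | tuple[int, int] = 3
    tissue_class: str = "thrombus"

    def __post_init__(self) -> None:
        self.center = tuple(int(c) for c in self.center)  # type: ignore[assignment]
        if len(self.center) != 3:
            raise ValueError("center must be a voxel index (i, j, k)")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(
                f"tissue_class must be one of {TISSUE_CLASSES}, got {self.tissue_class!r}"
            )

    @property
    def in_plane_shape(self) -> tuple[int, int]:
        if isinstance(self.size, tuple):
            w, h = self.size
        else:
            w = h = int(self.size)
        if w < 1 or h < 1:
            raise ValueError("ROI size must be positive")
        return int(w), int(h)

    def bounds(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Half-open index bounds ((i0, i1), (j0, j1)) of the in-plane patch.

        For even sizes the patch extends one voxel further on the low side
        (e.g. 10x10 spans center-5 .. center+4), keeping bounds deterministic.
        """
        w, h = self.in_plane_shape
        i, j, _ = self.center
        i0 = i - w // 2
        j0 = j - h // 2
        return (i0, i0 + w), (j0, j0 + h)

    def to_dict(self) -> dict:
        size = list(self.size) if isinstance(self.size, tuple) else self.size
        return {"center": list(self.center), "size": size, "class": self.tissue_class}

    @classmethod
    def from_dict(cls, d: dict) -> "ROISpec":
        size = d.get("size", 3)
        if isinstance(size, list):
            size = tuple(size)
        return cls(center=tuple(d["center"]), size=size, tissue_class=d.get("class", "thrombus"))


def _rotation_matrix(angles: Sequence[float]) -> np.ndarray:
    # extrinsic x-y-z Euler angles: R = Rz(az) @ Ry(ay) @ Rx(ax)
    return Rotation.from_euler("xyz", np.asarray(angles, dtype=float)).as_matrix()


@dataclass
class RigidTransform:
    """Rigid 3D map ``y = R (x - c) + c + t`` in physical mm coordinates.

    ``rotation`` holds extrinsic x-y-z Euler angles in radians, ``translation``
    is in mm and ``center`` is the centre of rotation in mm.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.rotation = _as_triple(self.rotation, "rotation")
        self.translation = _as_triple(self.translation, "translation")
        self.center = _as_triple(self.center, "center")

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix of the map."""
        R = _rotation_matrix(self.rotation)
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        return M

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) or (3,) physical points through the transform."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        M = self.matrix
        out = p @ M[:3, :3].T + M[:3, 3]
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "RigidTransform":
        R = _rotation_matrix(self.rotation)
        t = np.asarray(self.translation)
        # x = R^T (y - c) + c - R^T t
        angles = Rotation.from_matrix(R.T).as_euler("xyz")
        return RigidTransform(tuple(angles), tuple(-R.T @ t), self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        M = self.matrix @ other.matrix
        return RigidTransform.from_matrix(M[:3, :3], M[:3, 3])

    @classmethod
    def from_matrix(
        cls,
        R: np.ndarray,
        offset: Sequence[float],
        center: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Build from ``y = R x + offset``, re-expressed about ``center``."""
        R = np.asarray(R, dtype=float)
        c = np.asarray(center, dtype=float)
        angles = Rotation.from_matrix(R).as_euler("xyz")
        # offset = c + t - R c  =>  t = offset - c + R c
        t = np.asarray(offset, dtype=float) - c + R @ c
        return cls(tuple(angles), tuple(t), tuple(c))

    def to_sitk(self) -> sitk.AffineTransform:
        tf = sitk.AffineTransform(3)
        tf.SetMatrix(_rotation_matrix(self.rotation).ravel())
        tf.SetCenter(self.center)
        tf.SetTranslation(self.translation)
        return tf

    def to_dict(self) -> dict:
        return {
            "rotation_rad": list(self.rotation),
            "translation_mm": list(self.translation),
            "center_mm": list(self.center),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(tuple(d["rotation_rad"]), tuple(d["translation_mm"]), tuple(d["center_mm"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Centerline:
    """Ordered polyline of physical points (mm) tracing the clot axis."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must be an (N, 3) array")
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive centerline points must be distinct")

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def arc_length(self) -> float:
        return float(self.segment_lengths.sum())

    def point_at_arclength(self, s: float) -> np.ndarray:
        """Point at arc-length position ``s`` (clamped to [0, L])."""
        s = float(np.clip(s, 0.0, self.arc_length))
        cum = np.concatenate([[0.0], np.cumsum(self.segment_lengths)])
        idx = int(np.searchsorted(cum, s, side="right") - 1)
        idx = min(idx, len(self.points) - 2)
        seg = cum[idx + 1] - cum[idx]
        frac = 0.0 if seg == 0 else (s - cum[idx]) / seg
        return self.points[idx] + frac * (self.points[idx + 1] - self.points[idx])


# ---------------------------------------------------------------------------
# File I/O


def _infer_format(path: str | Path) -> str:
    name = str(path).lower()
    for fmt, exts in _EXTENSIONS.items():
        if any(name.endswith(e) for e in exts):
            return fmt
    raise ValueError(
        f"cannot infer format of {path!r}; supported formats: "
        + ", ".join(f"{k} ({'/'.join(v)})" for k, v in _EXTENSIONS.items())
    )


def read_volume(path: str | Path, format: str | None = None) -> Volume:
    """Read a 3D HU volume from NIfTI or MetaImage.

    Spacing and origin are taken from the header; HU values are unmodified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _EXTENSIONS:
        raise ValueError(f"unsupported format {fmt!r}; supported: {sorted(_EXTENSIONS)}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # unreadable header / corrupt file
        raise ValueError(f"could not read image {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"expected 3D volume, got {img.GetDimension()}D image in {path}")
    return Volume.from_sitk(img)


def write_volume(vol: Volume | Mask, path: str | Path, format: str | None = None) -> Path:
    """Write a Volume (float32) or Mask (uint8) as NIfTI or MetaImage."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _EXTENSIONS:
        raise ValueError(f"unsupported format {fmt!r}; supported: {sorted(_EXTENSIONS)}")
    if not any(str(path).lower().endswith(e) for e in _EXTENSIONS[fmt]):
        raise ValueError(f"path {path} does not match format {fmt!r} extensions {_EXTENSIONS[fmt]}")
    if isinstance(vol, Mask):
        arr = vol.data.astype(np.uint8)
    else:
        arr = vol.data.astype(np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


# ---------------------------------------------------------------------------
# ROI sampling


def extract_roi_values(vol: Volume, roi: ROISpec) -> np.ndarray:
    """HU values of an axial ROI patch in deterministic row-major order.

    Returns exactly w*h values, iterating x (rows) then y (columns) within
    the single axial slice. ROIs touching or exceeding the volume bounds
    raise; no clamping is applied.
    """
    (i0, i1), (j0, j1) = roi.bounds()
    k = roi.center[2]
    nx, ny, nz = vol.shape
    if i0 < 0 or j0 < 0 or k < 0 or i1 > nx or j1 > ny or k >= nz:
        raise ValueError(
            f"ROI {roi.to_dict()} out of bounds for volume of shape {vol.shape}"
        )
    patch = vol.data[i0:i1, j0:j1, k]
    return patch.reshape(-1).copy()


# ---------------------------------------------------------------------------
# Surface meshing


def mask_to_mesh(mask: Mask):
    """Extract a closed triangle surface (physical mm) from a binary mask.

    The mask is upsampled 2x per axis before marching cubes at iso-level 0.5
    so each voxel contributes a near-cubical cell: marching cubes applied
    directly to single grid samples would enclose only ~1/6 of the voxel
    volume. Returns a ``trimesh.Trimesh`` (writable as STL/PLY).
    """
    import trimesh
    from skimage import measure

    if mask.voxel_count == 0:
        raise ValueError("no voxels to mesh: mask is empty")
    up = np.repeat(np.repeat(np.repeat(mask.data, 2, axis=0), 2, axis=1), 2, axis=2)
    up = np.pad(up, 1).astype(np.float32)
    half = np.asarray(mask.spacing) / 2.0
    verts, faces, _, _ = measure.marching_cubes(up, level=0.5, spacing=tuple(half))
    # padded upsampled voxel j corresponds to physical (origin - 3/4 s) + j * s/2
    verts = verts + (np.asarray(mask.origin) - 0.75 * np.asarray(mask.spacing))
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def write_mesh(mesh, path: str | Path) -> Path:
    """Write a triangle mesh as STL or PLY (by extension)."""
    path = Path(path)
    if path.suffix.lower() not in (".stl", ".ply"):
        raise ValueError(f"unsupported mesh format {path.suffix!r}; use .stl or .ply")
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path))
    return path
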