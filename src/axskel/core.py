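"""Volume data model, resampling, morphology primitives and geometry.

All segmentation and PET logic runs on a fixed isotropic working grid
(4 x 4 x 4 mm by default, matched to the PET resolution); inputs are
resampled on load.  Arrays follow the canonical ``(left, anterior,
superior)`` index order described in :mod:`axskel.taxonomy`, and the mm
coordinate of voxel ``(i, j, k)`` is ``origin + index * spacing``
(voxel-center convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, InvalidArgumentError
from .taxonomy import default_taxonomy

WORKING_SPACING_MM = 4.0

Triple = tuple[float, float, float]


def _as_triple(x) -> tuple[float, float, float]:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 1:
        a = np.repeat(a, 3)
    if a.size != 3:
        raise InvalidArgumentError(f"expected a scalar or length-3 value, got {x!r}")
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass
class ImageVolume:
    """A 3-D scalar image with physical spacing, origin and a fixed modality."""

    voxels: np.ndarray
    spacing: Triple = (WORKING_SPACING_MM,) * 3
    origin: Triple = (0.0, 0.0, 0.0)
    modality: str = "CT-HU"  # or "PET-SUV"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise InvalidArgumentError("voxels must be a non-empty 3-D grid")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise InvalidArgumentError("spacing components must be strictly positive")
        if self.modality not in ("CT-HU", "PET-SUV"):
            raise InvalidArgumentError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_mm(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def mm_to_index(self, mm) -> np.ndarray:
        return (np.asarray(mm, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class LabelVolume:
    """A 3-D integer label grid plus the taxonomy naming its labels.

    Label 0 is reserved for background; every nonzero value present in
    ``voxels`` must appear in ``taxonomy``.
    """

    voxels: np.ndarray
    spacing: Triple = (WORKING_SPACING_MM,) * 3
    origin: Triple = (0.0, 0.0, 0.0)
    taxonomy: dict[int, str] = field(default_factory=default_taxonomy)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise InvalidArgumentError("voxels must be a non-empty 3-D grid")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise InvalidArgumentError("label voxels must be integers")
        if self.voxels.min() < 0:
            raise InvalidArgumentError("label values must be non-negative")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise InvalidArgumentError("spacing components must be strictly positive")
        present = set(np.unique(self.voxels).tolist()) - {0}
        unknown = present - set(self.taxonomy)
        if unknown:
            raise InvalidArgumentError(f"labels {sorted(unknown)} missing from taxonomy")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def name_to_id(self) -> dict[str, int]:
        return {v: k for k, v in self.taxonomy.items()}

    def mask(self, structure: str | int) -> np.ndarray:
        """Binary mask of one structure, by name or label id."""
        if isinstance(structure, str):
            structure = self.name_to_id[structure]
        return self.voxels == structure

    def present(self, structure: str | int) -> bool:
        try:
            return bool(self.mask(structure).any())
        except KeyError:
            return False

    def index_to_mm(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)


# ---------------------------------------------------------------------------
# structuring elements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructuringElement:
    """Sphere or vertical-line structuring element with a size in mm.

    Sphere offsets are exactly the lattice points whose center-to-center
    distance is <= the radius.  The vertical line spans ``+-round(size /
    spacing)`` voxels along the craniocaudal axis (one-sided extent), so a
    12 mm element reaches 3 voxels on the 4 mm grid, 8 mm reaches 2 and
    4 mm reaches 1.
    """

    kind: str  # "sphere" | "vertical-line"
    size_mm: float

    def __post_init__(self):
        if self.kind not in ("sphere", "vertical-line"):
            raise InvalidArgumentError(f"unknown structuring element kind {self.kind!r}")
        if self.size_mm <= 0:
            raise InvalidArgumentError("structuring element size must be positive")

    def offsets(self, spacing) -> np.ndarray:
        """(n, 3) integer voxel offsets implied by size and grid spacing."""
        sp = np.asarray(_as_triple(spacing))
        if self.kind == "sphere":
            reach = np.floor(self.size_mm / sp).astype(int)
            rng = [np.arange(-r, r + 1) for r in reach]
            ii, jj, kk = np.meshgrid(*rng, indexing="ij")
            d2 = (ii * sp[0]) ** 2 + (jj * sp[1]) ** 2 + (kk * sp[2]) ** 2
            keep = d2 <= self.size_mm**2 + 1e-9
            return np.stack([ii[keep], jj[keep], kk[keep]], axis=1)
        r = int(round(self.size_mm / sp[2]))
        ks = np.arange(-r, r + 1)
        return np.stack([np.zeros_like(ks), np.zeros_like(ks), ks], axis=1)

    def footprint(self, spacing) -> np.ndarray:
        """Dense binary footprint array centered on the origin offset."""
        off = self.offsets(spacing)
        lo = off.min(axis=0)
        hi = off.max(axis=0)
        fp = np.zeros(hi - lo + 1, dtype=bool)
        fp[tuple((off - lo).T)] = True
        return fp


def binary_dilate(mask: np.ndarray, se: StructuringElement, spacing=WORKING_SPACING_MM) -> np.ndarray:
    """Dilate a binary mask: union of the element translated to every
    foreground voxel, clipped to the grid."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=se.footprint(spacing))


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def erode_one_voxel(mask: np.ndarray) -> np.ndarray:
    """One-voxel erosion: a voxel survives iff all 6 face-neighbours are
    foreground (grid border counts as background)."""
    mask = np.asarray(mask, dtype=bool)
    return ndimage.binary_erosion(mask, structure=_FACE_STRUCTURE, border_value=0)


def center_of_mass(mask: np.ndarray) -> np.ndarray:
    """Unweighted mean of foreground voxel indices (continuous coordinate)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("center of mass of an empty mask is undefined")
    return np.mean(np.argwhere(mask), axis=0)


def center_of_mass_mm(mask: np.ndarray, spacing=WORKING_SPACING_MM, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    return np.asarray(_as_triple(origin)) + center_of_mass(mask) * np.asarray(_as_triple(spacing))


def round_half_away(x) -> np.ndarray:
    """Round to nearest integer, halves away from zero (table convention)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def resample_to_grid(vol, target_spacing=WORKING_SPACING_MM):
    """Resample a volume to a new isotropic/anisotropic spacing.

    Intensity volumes are interpolated linearly, label volumes with nearest
    neighbour.  The world extent is preserved: the corner of voxel (0,0,0)
    stays fixed and the output covers the same physical box to within one
    voxel.
    """
    target = np.asarray(_as_triple(target_spacing))
    if np.any(target <= 0):
        raise InvalidArgumentError("target spacing must be strictly positive")
    src = np.asarray(vol.spacing)
    if np.allclose(src, target):
        return replace(vol, voxels=vol.voxels.copy())

    is_label = isinstance(vol, LabelVolume)
    new_shape = np.maximum(1, np.ceil(np.asarray(vol.shape) * src / target - 1e-9).astype(int))
    # voxel-center mapping preserving the volume corner
    grids = np.meshgrid(*[np.arange(n) for n in new_shape], indexing="ij")
    coords = [
        (g + 0.5) * (target[a] / src[a]) - 0.5 for a, g in enumerate(grids)
    ]
    order = 0 if is_label else 1
    out = ndimage.map_coordinates(
        vol.voxels.astype(float) if not is_label else vol.voxels,
        coords,
        order=order,
        mode="nearest",
    )
    new_origin = tuple(np.asarray(vol.origin) + 0.5 * (target - src))
    if is_label:
        return LabelVolume(out.astype(vol.voxels.dtype), tuple(target), new_origin, dict(vol.taxonomy))
    return ImageVolume(out.astype(np.float32), tuple(target), new_origin, vol.modality)


# ---------------------------------------------------------------------------
# similarity transforms
# ---------------------------------------------------------------------------


def rotation_matrix(rotation_deg) -> np.ndarray:
    """Intrinsic x-y-z Euler rotation matrix from degrees."""
    rx, ry, rz = np.deg2rad(_as_triple(rotation_deg))
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


@dataclass
class SimilarityTransform:
    """Rigid rotation + isotropic scale + translation about a center (mm).

    Maps a point ``p`` to ``center + translation + scale * R @ (p - center)``.
    """

    rotation: np.ndarray  # 3x3 orthonormal
    scale: float = 1.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.rotation)) or not np.all(np.isfinite(self.translation)):
            raise InvalidArgumentError("transform parameters must be finite")
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise InvalidArgumentError("scale must be positive and finite")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3))

    @classmethod
    def from_params(cls, rotation_deg=(0, 0, 0), scale=1.0, translation_mm=(0, 0, 0), center_mm=(0, 0, 0)):
        return cls(rotation_matrix(rotation_deg), float(scale),
                   np.asarray(_as_triple(translation_mm)), np.asarray(_as_triple(center_mm)))

    def apply_points(self, pts) -> np.ndarray:
        arr = np.asarray(pts, dtype=float)
        single = arr.ndim == 1
        pts2 = np.atleast_2d(arr)
        out = self.center + self.translation + self.scale * (pts2 - self.center) @ self.rotation.T
        return out[0] if single else out

    def inverse(self) -> "SimilarityTransform":
        Rt = self.rotation.T
        s = 1.0 / self.scale
        t = -s * Rt @ self.translation
        return SimilarityTransform(Rt, s, t, self.center.copy())

    @property
    def linear(self) -> np.ndarray:
        """Combined linear part ``scale * R``."""
        return self.scale * self.rotation


def apply_transform_to_volume(vol, transform: SimilarityTransform, background=0.0):
    """Move a volume's content by ``transform``: ``out(q) = in(T^-1(q))``.

    Linear interpolation for intensity volumes, nearest neighbour for label
    volumes; the grid itself is unchanged.
    """
    inv = transform.inverse()
    sp = np.asarray(vol.spacing)
    org = np.asarray(vol.origin)
    M = inv.linear
    k = inv.center + inv.translation - M @ inv.center
    # output index o -> input index: S^-1 (M (org + S o) + k - org)
    matrix = (M * sp[None, :]) / sp[:, None]
    offset = (M @ org + k - org) / sp
    is_label = isinstance(vol, LabelVolume)
    out = ndimage.affine_transform(
        vol.voxels if is_label else vol.voxels.astype(float),
        matrix,
        offset=offset,
        order=0 if is_label else 1,
        mode="constant",
        cval=0 if is_label else background,
    )
    if is_label:
        return replace(vol, voxels=out.astype(vol.voxels.dtype))
    return replace(vol, voxels=out.astype(np.float32))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------
# In-memory arrays use (left+, anterior+, superior+) index order; on disk we
# store RAS+ NIfTI, so axis 0 is flipped on the way in and out.


def _to_ras(voxels: np.ndarray, spacing, origin):
    data = voxels[::-1]
    affine = np.diag(list(spacing) + [1.0])
    # RAS x coordinate of the first (flipped) voxel
    x0 = -(origin[0] + (voxels.shape[0] - 1) * spacing[0])
    affine[:3, 3] = (x0, origin[1], origin[2])
    return data, affine


def _from_ras(img: nib.Nifti1Image):
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise InvalidArgumentError("expected a 3-D NIfTI volume")
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    ras_origin = aff[:3, 3]
    voxels = data[::-1]
    origin = (-(ras_origin[0] + (data.shape[0] - 1) * aff[0, 0]), float(ras_origin[1]), float(ras_origin[2]))
    return voxels, spacing, origin


def write_image(vol: ImageVolume, path) -> None:
    data, affine = _to_ras(np.asarray(vol.voxels, dtype=np.float32), vol.spacing, vol.origin)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_image(path, modality="CT-HU") -> ImageVolume:
    voxels, spacing, origin = _from_ras(nib.load(str(path)))
    return ImageVolume(np.ascontiguousarray(voxels, dtype=np.float32), spacing, origin, modality)


def write_labels(vol: LabelVolume, path, taxonomy_path=None) -> None:
    data, affine = _to_ras(np.asarray(vol.voxels, dtype=np.int16), vol.spacing, vol.origin)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    if taxonomy_path is None:
        taxonomy_path = _sidecar_path(path)
    Path(taxonomy_path).write_text(
        json.dumps({str(k): v for k, v in sorted(vol.taxonomy.items())}, indent=1)
    )


def read_labels(path, taxonomy_path=None) -> LabelVolume:
    voxels, spacing, origin = _from_ras(nib.load(str(path)))
    if taxonomy_path is None:
        cand = _sidecar_path(path)
        taxonomy_path = cand if Path(cand).exists() else None
    if taxonomy_path is not None:
        raw = json.loads(Path(taxonomy_path).read_text())
        taxonomy = {int(k): str(v) for k, v in raw.items()}
    else:
        taxonomy = default_taxonomy()
    return LabelVolume(np.ascontiguousarray(voxels.astype(np.int32)), spacing, origin, taxonomy)


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".taxonomy.json")
    return p.with_suffix(".taxonomy.json")
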