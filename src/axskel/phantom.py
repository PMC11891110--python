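"""Synthetic spine phantom: LDCT label maps, intensity images and PET volumes.

The phantom emulates the input interface of the pipeline — a low-dose CT
volume plus a TotalSegmentator-style multi-label mask, and a co-registered
PET volume in SUV units — on the 4 mm working grid.  Vertebrae are rounded
cuboids carrying a posterior arch (pedicles, lateral masses and a lamina /
spinous block) so that the vertebral-body split, the dilation-overlap joint
localisation and the facet-joint geometry are all exercised.  Adjacent bone
structures are separated by at least a one-voxel soft-tissue gap, which is
where the disks and joints live.  Geometric realism is a non-goal.

All randomness flows through the spec seeds: two runs with equal seeds are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import taxonomy as tax
from .core import (
    ImageVolume,
    LabelVolume,
    SimilarityTransform,
    apply_transform_to_volume,
    center_of_mass,
    round_half_away,
)
from .errors import GenerationError, InvalidArgumentError

SPACING = 4.0  # mm, working grid

# Region -> vertebral-body (width, depth, height) in mm at scale 1.
_VB_SIZE_MM = {
    "cervical": (24.0, 24.0, 12.0),
    "thoracic": (32.0, 32.0, 16.0),
    "lumbar": (40.0, 40.0, 24.0),
}

# CT intensities in HU
_HU = {
    "bone_vertebra": 400.0,
    "bone_rib": 350.0,
    "bone_pelvis": 380.0,
    "bone_femur": 420.0,
    "cord": 30.0,
    "liver": 60.0,
    "aorta": 45.0,
    "background": -50.0,
}


@dataclass
class PhantomSpec:
    """Geometry and pose parameters of one synthetic scan."""

    vb_size_mm: dict = field(default_factory=lambda: dict(_VB_SIZE_MM))
    disk_gap_mm: float = 4.0  # one working voxel
    cord_radius_mm: float = 4.0
    sacrum_height_mm: float = 32.0
    scale: float = 1.0  # anatomical size factor
    rotation_deg: tuple = (0.0, 0.0, 0.0)  # pose jitter
    translation_mm: tuple = (0.0, 0.0, 0.0)
    ct_noise_sd_hu: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not (0.8 <= self.scale <= 1.2):
            raise InvalidArgumentError("scale factor must lie in [0.8, 1.2]")
        if self.disk_gap_mm < SPACING - 1e-9:
            raise InvalidArgumentError("disk gap must be at least one working voxel")


@dataclass
class LesionSpec:
    """One focal lesion: placed at a structure's COM or an explicit voxel."""

    peak_suv: float  # amplitude added on top of the local background
    sigma_mm: float = 2.0
    structure: str | int | None = None
    center_vox: tuple | None = None

    def __post_init__(self):
        if (self.structure is None) == (self.center_vox is None):
            raise InvalidArgumentError("give exactly one of structure or center_vox")


@dataclass
class PetPhantomSpec:
    """Regional background SUV levels plus planted focal lesions."""

    backgrounds: dict = field(
        default_factory=lambda: {
            "cervical": 5.0,
            "thoracic": 6.0,
            "lumbar": 7.0,
            "femur": 2.0,
            "liver": 1.0,
            "aorta": 1.5,
            "soft_tissue": 0.5,
        }
    )
    lesions: list = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.backgrounds.values()):
            raise InvalidArgumentError("background SUV levels must be positive")


@dataclass
class PhantomLesion:
    """Ground-truth record of one planted lesion."""

    center_vox: tuple
    center_mm: np.ndarray
    peak_suv: float
    sigma_mm: float
    structure: str | None


@dataclass
class PhantomTruth:
    """Geometric lesion truth: a VOI is positive iff a lesion center lies
    inside its mask (uptake thresholding plays no part in the truth)."""

    lesions: list

    def voi_truth(self, vois) -> dict:
        out = {}
        for voi in vois:
            out[voi.key] = any(bool(voi.mask[les.center_vox]) for les in self.lesions)
        return out


# ---------------------------------------------------------------------------
# LDCT generation
# ---------------------------------------------------------------------------


class _Painter:
    def __init__(self, shape):
        self.labels = np.zeros(shape, dtype=np.int32)
        self.hu = np.full(shape, _HU["background"], dtype=np.float32)

    def paint(self, mask, structure: str, hu: float, allow_soft=False):
        if not mask.any():
            raise GenerationError(f"structure {structure} came out empty")
        clash = self.labels[mask]
        if np.any(clash != 0):
            other = tax.ID_TO_NAME.get(int(clash[clash != 0][0]), "?")
            if not allow_soft:
                raise GenerationError(f"structure {structure} overlaps {other}")
            mask = mask & (self.labels == 0)
        self.labels[mask] = tax.STRUCTURE_IDS[structure]
        self.hu[mask] = hu


def _box(shape, i0, i1, j0, j1, k0, k1):
    m = np.zeros(shape, dtype=bool)
    m[max(i0, 0) : i1 + 1, max(j0, 0) : j1 + 1, max(k0, 0) : k1 + 1] = True
    return m


def _vox(mm: float, scale: float) -> int:
    return max(1, int(round(mm * scale / SPACING)))


def generate_phantom_ldct(spec: PhantomSpec | None = None):
    """Build one synthetic LDCT scan.

    Returns an ``(ImageVolume, LabelVolume)`` pair on the 4 mm grid.  The
    label volume contains all 24 vertebrae, the spinal cord, 24 ribs, the
    sacrum, both ilia and femurs, liver and aorta, each a single connected
    component, with bone brighter than soft tissue in the intensity image.
    """
    spec = spec or PhantomSpec()
    s = spec.scale
    rng = np.random.default_rng(spec.seed)

    # voxel extents per region
    dims = {}
    for region, (w_mm, d_mm, h_mm) in spec.vb_size_mm.items():
        dims[region] = (_vox(w_mm / 2, s), _vox(d_mm, s), _vox(h_mm, s))
    gap = max(1, int(round(spec.disk_gap_mm / SPACING)))
    hs = _vox(spec.sacrum_height_mm, s)

    nx, ny = 40, 42
    cx = 19  # midline between columns cx and cx+1
    jvb = 24  # anterior face of the canal: VBs start here

    # craniocaudal stacking (bottom-up): femur, sacrum, L5..L1, T12..T1, C7..C1
    zs = 20
    z0 = {}  # vertebra -> (z_start, z_stop) inclusive
    z = zs + hs - 1 + gap + 1
    for name in reversed(tax.VERTEBRAE):
        h = dims[tax.region_of(name)][2]
        z0[name] = (z, z + h - 1)
        z = z + h + gap
    nz = z + 6
    shape = (nx, ny, nz)
    p = _Painter(shape)

    def mirror(i: int) -> int:
        return 2 * cx + 1 - i

    # vertebrae with posterior arches
    for name in tax.VERTEBRAE:
        w, d, h = dims[tax.region_of(name)]
        ka, kb = z0[name]
        m = _box(shape, cx + 1 - w, cx + w, jvb, jvb + d - 1, ka, kb)  # body
        for lo, hi in ((cx + 3, cx + 4), (mirror(cx + 4), mirror(cx + 3))):
            m |= _box(shape, lo, hi, 20, 23, ka, kb)  # pedicles
            m |= _box(shape, lo, hi, 16, 19, ka, kb)  # lateral masses
        m |= _box(shape, cx - 1, cx + 2, 12, 17, ka, kb)  # lamina + spinous
        p.paint(m, name, _HU["bone_vertebra"])

    # spinal cord: spans every slice intersecting a vertebra
    ka = z0["L5"][0]
    kb = z0["C1"][1]
    cord = _box(shape, cx, cx + 1, 19, 21, ka, kb)
    p.paint(cord, tax.SPINAL_CORD, _HU["cord"])

    # ribs on all thoracic levels
    for n in range(1, 13):
        name = f"T{n}"
        ka, kb = z0[name]
        kmid = (ka + kb) // 2
        krng = (kmid, min(kmid + 1, kb))
        left = (
            _box(shape, cx + 6, cx + 7, 24, 27, *krng)  # head, faces the VB
            | _box(shape, cx + 6, cx + 7, 16, 19, *krng)  # tubercle, faces the mass
            | _box(shape, cx + 8, cx + 12, 17, 26, *krng)  # shaft
        )
        p.paint(left, f"rib_left_{n}", _HU["bone_rib"])
        right = (
            _box(shape, mirror(cx + 7), mirror(cx + 6), 24, 27, *krng)
            | _box(shape, mirror(cx + 7), mirror(cx + 6), 16, 19, *krng)
            | _box(shape, mirror(cx + 12), mirror(cx + 8), 17, 26, *krng)
        )
        p.paint(right, f"rib_right_{n}", _HU["bone_rib"])

    # sacrum and ilia with an oblique one/two-voxel joint gap
    sac = _box(shape, cx - 5, cx + 6, 16, 31, zs, zs + hs - 1)
    p.paint(sac, tax.SACRUM, _HU["bone_pelvis"])
    il_lo, il_hi = zs - 2, zs + hs + 1
    z_oblique = zs + hs // 2
    left = np.zeros(shape, dtype=bool)
    right = np.zeros(shape, dtype=bool)
    for k in range(il_lo, il_hi + 1):
        edge = cx + 8 if k < z_oblique else cx + 9
        left |= _box(shape, edge, cx + 12, 14, 30, k, k)
        right |= _box(shape, mirror(cx + 12), mirror(edge), 14, 30, k, k)
    p.paint(left, "ilium_left", _HU["bone_pelvis"])
    p.paint(right, "ilium_right", _HU["bone_pelvis"])

    # femurs below the ilia
    fem_top = il_lo - 2
    p.paint(_box(shape, cx + 8, cx + 11, 22, 27, 2, fem_top), "femur_left", _HU["bone_femur"])
    p.paint(
        _box(shape, mirror(cx + 11), mirror(cx + 8), 22, 27, 2, fem_top),
        "femur_right",
        _HU["bone_femur"],
    )

    # liver (right upper abdomen) and aorta (left of midline, anterior)
    zl = z0["T12"][0]
    p.paint(_box(shape, 7, 13, 28, 36, zl - 8, zl + 4), "liver", _HU["liver"])
    p.paint(
        _box(shape, cx + 1, cx + 3, 35, 37, z0["L5"][0], z0["T1"][0]),
        "aorta",
        _HU["aorta"],
    )

    hu = p.hu + rng.normal(0.0, spec.ct_noise_sd_hu, shape).astype(np.float32)
    ct = ImageVolume(hu.astype(np.float32), (SPACING,) * 3, (0.0, 0.0, 0.0), "CT-HU")
    labels = LabelVolume(p.labels, (SPACING,) * 3, (0.0, 0.0, 0.0), tax.default_taxonomy())

    if any(abs(r) > 1e-12 for r in spec.rotation_deg) or any(
        abs(t) > 1e-12 for t in spec.translation_mm
    ):
        center = labels.index_to_mm((np.asarray(shape) - 1) / 2.0)
        pose = SimilarityTransform.from_params(
            spec.rotation_deg, 1.0, spec.translation_mm, center
        )
        ct = apply_transform_to_volume(ct, pose, background=_HU["background"])
        labels = apply_transform_to_volume(labels, pose)
    return ct, labels


# ---------------------------------------------------------------------------
# PET generation
# ---------------------------------------------------------------------------

_REGION_OF_STRUCTURE = {}
for _v in tax.CERVICAL:
    _REGION_OF_STRUCTURE[_v] = "cervical"
for _v in tax.THORACIC:
    _REGION_OF_STRUCTURE[_v] = "thoracic"
for _n in range(1, 13):
    _REGION_OF_STRUCTURE[f"rib_left_{_n}"] = "thoracic"
    _REGION_OF_STRUCTURE[f"rib_right_{_n}"] = "thoracic"
for _v in tax.LUMBAR + [tax.SACRUM, "ilium_left", "ilium_right"]:
    _REGION_OF_STRUCTURE[_v] = "lumbar"
_REGION_OF_STRUCTURE["femur_left"] = "femur"
_REGION_OF_STRUCTURE["femur_right"] = "femur"
_REGION_OF_STRUCTURE["liver"] = "liver"
_REGION_OF_STRUCTURE["aorta"] = "aorta"


def _background_map(labels: LabelVolume, backgrounds: dict) -> np.ndarray:
    out = np.full(labels.shape, backgrounds["soft_tissue"], dtype=np.float32)
    for lab_id, name in labels.taxonomy.items():
        region = _REGION_OF_STRUCTURE.get(name)
        if region is None:
            continue
        out[labels.voxels == lab_id] = backgrounds[region]
    return out


def generate_phantom_pet(labels: LabelVolume, spec: PetPhantomSpec | None = None):
    """PET volume = regional backgrounds + Gaussian lesion blobs + noise.

    Returns ``(ImageVolume, PhantomTruth)``; the truth records the planted
    lesion centers so detection operating points can be swept against a
    fixed geometric ground truth.
    """
    spec = spec or PetPhantomSpec()
    rng = np.random.default_rng(spec.seed)
    pet = _background_map(labels, spec.backgrounds)
    sp = np.asarray(labels.spacing)
    shape = np.asarray(labels.shape)

    truth_lesions = []
    for les in spec.lesions:
        if les.structure is not None:
            if not labels.present(les.structure):
                raise InvalidArgumentError(f"lesion target {les.structure!r} absent from labels")
            smask = labels.mask(les.structure)
            center = tuple(round_half_away(center_of_mass(smask)))
            if not smask[center]:  # non-convex structure: snap to nearest voxel
                pts = np.argwhere(smask)
                center = tuple(pts[np.argmin(((pts - center) ** 2).sum(axis=1))])
            struct_name = (
                les.structure
                if isinstance(les.structure, str)
                else labels.taxonomy[les.structure]
            )
        else:
            center = tuple(int(c) for c in les.center_vox)
            if any(c < 0 or c >= n for c, n in zip(center, shape)):
                raise InvalidArgumentError(f"lesion center {center} outside the grid")
            struct_name = None
        lab_here = int(labels.voxels[center])
        region = _REGION_OF_STRUCTURE.get(labels.taxonomy.get(lab_here, ""), "soft_tissue")
        bg_here = spec.backgrounds.get(region, spec.backgrounds["soft_tissue"])
        if les.peak_suv <= bg_here:
            raise InvalidArgumentError("lesion peak must exceed its region background")
        reach = np.maximum(1, np.ceil(5 * les.sigma_mm / sp).astype(int))
        lo = np.maximum(0, np.asarray(center) - reach)
        hi = np.minimum(shape, np.asarray(center) + reach + 1)
        ii, jj, kk = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
        d2 = sum(((g - center[a]) * sp[a]) ** 2 for a, g in enumerate((ii, jj, kk)))
        pet[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += les.peak_suv * np.exp(
            -d2 / (2.0 * les.sigma_mm**2)
        ).astype(np.float32)
        truth_lesions.append(
            PhantomLesion(center, labels.index_to_mm(center), les.peak_suv, les.sigma_mm, struct_name)
        )

    if spec.noise_sd > 0:
        pet = pet + rng.normal(0.0, spec.noise_sd, tuple(shape)).astype(np.float32)
        np.clip(pet, 0.01, None, out=pet)
    vol = ImageVolume(pet.astype(np.float32), labels.spacing, labels.origin, "PET-SUV")
    return vol, PhantomTruth(truth_lesions)


def apply_known_similarity(vol, transform: SimilarityTransform, background=None):
    """Resample a volume under a known similarity transform (test fixture
    for registration and test-retest protocols)."""
    if background is None:
        background = _HU["background"] if getattr(vol, "modality", None) == "CT-HU" else 0.0
    return apply_transform_to_volume(vol, transform, background=background)
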