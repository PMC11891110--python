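"""Multi-atlas segmentation method.

An atlas library holds, for each of five atlas scans, 26 partial atlases:
cropped intensity/label pairs for every adjacent-vertebra pair (C1-C2 ...
L5-sacrum) plus the two sacrum+ilium boxes.  Atlas scans are picked at the
10th/30th/50th/70th/90th percentiles of the spinal length (the C1-sacrum
COM distance).  To segment a target scan, each unit's box is cropped from
the target, zero-padded by 10 voxels, and all five partial atlases are
co-registered with a similarity transform (mean-squares metric, gradient
descent, 100 iterations).  Propagated label maps are fused by majority
voting; joint centers are fused by averaging the five propagated points.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from . import taxonomy as tax
from .core import (
    ImageVolume,
    LabelVolume,
    SimilarityTransform,
    center_of_mass_mm,
    round_half_away,
)
from .errors import (
    InvalidArgumentError,
    MissingStructureError,
    RegistrationError,
)
from .segmentation import JointCenter, SegmentationOutput

#: label codes inside a partial-atlas label map
UPPER_CODE, MIDDLE_CODE, LOWER_CODE = 1, 2, 3  # VB/sacrum, IVD/SIJ, VB/ilium

DEFAULT_PERCENTILES = (10, 30, 50, 70, 90)
PAD_VOXELS = 10
CROP_MARGIN_VOXELS = 2
REGISTRATION_ITERATIONS = 100


# ---------------------------------------------------------------------------
# atlas selection
# ---------------------------------------------------------------------------


def spinal_length(labels: LabelVolume) -> float:
    """Spinal length estimate: mm distance between the C1 and sacrum COMs."""
    for name in ("C1", tax.SACRUM):
        if not labels.present(name):
            raise MissingStructureError(f"{name} missing: cannot measure spinal length")
    p1 = center_of_mass_mm(labels.mask("C1"), labels.spacing, labels.origin)
    p2 = center_of_mass_mm(labels.mask(tax.SACRUM), labels.spacing, labels.origin)
    return float(np.linalg.norm(p1 - p2))


def percentile_ranks(n: int, percentiles=DEFAULT_PERCENTILES) -> list[int]:
    """Nearest-rank (ceiling) 1-based ranks on an ascending sort; duplicate
    ranks step to the next unused rank."""
    if n < len(percentiles):
        raise InvalidArgumentError("need at least as many lengths as percentiles")
    ranks: list[int] = []
    for p in percentiles:
        r = max(1, math.ceil(p * n / 100.0))
        while r in ranks and r < n:
            r += 1
        while r in ranks and r > 1:
            r -= 1
        ranks.append(r)
    return ranks


def select_atlases(lengths, percentiles=DEFAULT_PERCENTILES) -> list[int]:
    """Indices (into the original list) of the scans sitting at the given
    spinal-length percentiles."""
    lengths = list(lengths)
    order = np.argsort(np.asarray(lengths, dtype=float), kind="stable")
    ranks = percentile_ranks(len(lengths), percentiles)
    return [int(order[r - 1]) for r in ranks]


# ---------------------------------------------------------------------------
# partial atlases
# ---------------------------------------------------------------------------


@dataclass
class PartialAtlas:
    """Cropped intensity + label pair for one adjacent-structure box."""

    unit: str  # unit id, e.g. "T4-T5" or "sacrum-ilium_left"
    ct: np.ndarray  # cropped intensity grid
    labels: np.ndarray  # cropped label codes (UPPER/MIDDLE/LOWER)
    origin: tuple  # mm origin of the crop in the source frame
    spacing: tuple
    bbox: tuple  # ((i0,j0,k0), (i1,j1,k1)) inclusive, source voxel frame
    joint_points: dict = field(default_factory=dict)  # (kind,level,side) -> mm

    def __post_init__(self):
        if self.ct.shape != self.labels.shape:
            raise InvalidArgumentError("atlas label map grid must match intensity grid")


def _joint_bbox(mask_a, mask_b, shape, margin=CROP_MARGIN_VOXELS):
    idx = np.argwhere(mask_a | mask_b)
    lo = np.maximum(0, idx.min(axis=0) - margin)
    hi = np.minimum(np.asarray(shape) - 1, idx.max(axis=0) + margin)
    return tuple(lo), tuple(hi)


def _unit_members(labels: LabelVolume, seg: SegmentationOutput, upper: str, lower: str):
    """(upper mask, middle mask, lower mask) for one unit, or None if a
    structure is missing."""
    uid = tax.unit_id(upper, lower)
    if upper == tax.SACRUM:  # sacro-iliac unit
        if not (labels.present(tax.SACRUM) and labels.present(lower)):
            return None
        side = lower.split("_")[1]
        mid = seg.sij.get(side)
        return labels.mask(tax.SACRUM), mid, labels.mask(lower)
    if not (labels.present(upper) and labels.present(lower)):
        return None
    up = seg.vb.get(upper)
    low = seg.sacrum if lower == tax.SACRUM else seg.vb.get(lower)
    return up, seg.ivd.get(uid), low


def make_partial_atlases(
    ct: ImageVolume,
    labels: LabelVolume,
    seg: SegmentationOutput,
    margin=CROP_MARGIN_VOXELS,
):
    """Cut one scan into its 26 partial atlases.

    ``labels`` is the skeletal input mask (defines the bounding boxes, as
    the target-side boxes will); ``seg`` supplies the reference label maps
    and joint centers stored in each crop.  Units whose structures are
    missing are skipped with a QC flag.
    """
    atlases: dict[str, PartialAtlas] = {}
    qc: list[str] = []
    centers_by_unit = _assign_centers_to_units(seg.joint_centers)
    for upper, lower in tax.ALL_UNITS:
        uid = tax.unit_id(upper, lower)
        members = _unit_members(labels, seg, upper, lower)
        if members is None or members[0] is None or members[2] is None:
            qc.append(f"unit {uid} skipped: structure missing")
            continue
        up_mask, mid_mask, low_mask = members
        box_a = labels.mask(upper if upper != tax.SACRUM else tax.SACRUM)
        box_b = labels.mask(lower)
        lo, hi = _joint_bbox(box_a, box_b, labels.shape, margin)
        sl = tuple(slice(lo[a], hi[a] + 1) for a in range(3))
        lab = np.zeros(ct.voxels[sl].shape, dtype=np.int16)
        lab[low_mask[sl]] = LOWER_CODE
        lab[up_mask[sl]] = UPPER_CODE
        if mid_mask is not None:
            lab[mid_mask[sl]] = MIDDLE_CODE
        origin = tuple(ct.index_to_mm(lo))
        points = {
            jc.key: np.asarray(jc.mm, dtype=float)
            for jc in centers_by_unit.get(uid, [])
        }
        atlases[uid] = PartialAtlas(
            uid, ct.voxels[sl].astype(np.float32), lab, origin, ct.spacing, (lo, hi), points
        )
    return atlases, qc


def _assign_centers_to_units(joint_centers) -> dict[str, list[JointCenter]]:
    """Each joint belongs to the unit whose upper member carries it: FJs to
    their own unit, CVJs/CTJs to the unit where their vertebra is upper."""
    upper_to_unit = {u: tax.unit_id(u, l) for u, l in tax.VERTEBRA_UNITS}
    out: dict[str, list[JointCenter]] = {}
    for jc in joint_centers:
        uid = jc.level if jc.kind == "FJ" else upper_to_unit.get(jc.level)
        if uid is not None:
            out.setdefault(uid, []).append(jc)
    return out


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels.T, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk_transform(t) -> SimilarityTransform:
    M = np.asarray(t.GetMatrix(), dtype=float).reshape(3, 3)
    scale = float(np.linalg.det(M)) ** (1.0 / 3.0)
    return SimilarityTransform(
        M / scale, scale, np.asarray(t.GetTranslation()), np.asarray(t.GetCenter())
    )


def pad_fixed(voxels: np.ndarray, spacing, origin, pad=PAD_VOXELS):
    """Zero-pad the (cropped) fixed image by ``pad`` voxels on every side;
    the padding keeps the moving image from scaling uncontrolledly outside
    the fixed box."""
    out = np.pad(voxels, pad, mode="constant")
    new_origin = tuple(np.asarray(origin) - pad * np.asarray(spacing))
    return out, new_origin


def register_similarity(
    fixed_voxels: np.ndarray,
    moving_voxels: np.ndarray,
    spacing,
    fixed_origin=(0.0, 0.0, 0.0),
    moving_origin=(0.0, 0.0, 0.0),
    iterations=REGISTRATION_ITERATIONS,
    lock_scale=False,
) -> SimilarityTransform:
    """Similarity registration: mean-squares metric, multi-resolution
    gradient descent, full (deterministic) metric sampling.

    The returned transform maps fixed-frame physical points to moving-frame
    points.  With ``lock_scale`` a rigid (Euler) transform is fitted
    instead, for the test-retest protocol.
    """
    if np.ptp(fixed_voxels) == 0 or np.ptp(moving_voxels) == 0:
        raise RegistrationError("cannot register constant images")
    spacing = tuple(np.broadcast_to(np.asarray(spacing, dtype=float), (3,)))
    fixed = _to_sitk(fixed_voxels, spacing, fixed_origin)
    moving = _to_sitk(moving_voxels, spacing, moving_origin)

    base = sitk.Euler3DTransform() if lock_scale else sitk.Similarity3DTransform()
    init = sitk.CenteredTransformInitializer(
        fixed, moving, base, sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetInitialTransform(init, inPlace=False)
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=iterations,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
    try:
        final = reg.Execute(fixed, moving)
    except RuntimeError as e:  # pragma: no cover - toolkit failure path
        raise RegistrationError(str(e)) from e
    final = final.Downcast() if hasattr(final, "Downcast") else final
    if isinstance(final, sitk.CompositeTransform):
        final = final.GetNthTransform(final.GetNumberOfTransforms() - 1).Downcast()
    return _from_sitk_transform(final)


def propagate_labels(
    atlas: PartialAtlas,
    transform: SimilarityTransform,
    out_shape,
    out_origin,
    spacing=None,
) -> np.ndarray:
    """Nearest-neighbour warp of an atlas label map into the target frame.

    ``transform`` maps target (fixed) physical points into the atlas
    (moving) frame, as returned by :func:`register_similarity`.
    """
    spacing = np.asarray(atlas.spacing if spacing is None else spacing, dtype=float)
    sp = np.broadcast_to(spacing, (3,))
    A = transform.linear
    b = transform.center + transform.translation - A @ transform.center
    org_f = np.asarray(out_origin, dtype=float)
    org_m = np.asarray(atlas.origin, dtype=float)
    matrix = (A * sp[None, :]) / sp[:, None]
    offset = (A @ org_f + b - org_m) / sp
    return ndimage.affine_transform(
        atlas.labels,
        matrix,
        offset=offset,
        output_shape=tuple(out_shape),
        order=0,
        mode="constant",
        cval=0,
    ).astype(atlas.labels.dtype)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------


def fuse_labels(propagated) -> np.ndarray:
    """Majority-vote label fusion: a voxel takes a label iff at least 3 of
    the 5 propagated maps assign it (a strict majority is unique)."""
    propagated = list(propagated)
    if len(propagated) != 5:
        raise InvalidArgumentError("majority voting is defined for exactly 5 atlases")
    shapes = {p.shape for p in propagated}
    if len(shapes) != 1:
        raise InvalidArgumentError("propagated label maps must share one grid")
    stack = np.stack(propagated)
    out = np.zeros(propagated[0].shape, dtype=propagated[0].dtype)
    for lab in np.unique(stack):
        if lab == 0:
            continue
        out[(stack == lab).sum(axis=0) >= 3] = lab
    return out


def fuse_joint_centers(points_mm, spacing, origin=(0.0, 0.0, 0.0)):
    """Mean of the five propagated joint locations, rounded to a voxel."""
    pts = np.asarray(points_mm, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise InvalidArgumentError("joint points must be finite")
    mean = pts.mean(axis=0)
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    ijk = tuple(int(v) for v in round_half_away((mean - np.asarray(origin)) / sp))
    mm = np.asarray(origin) + np.asarray(ijk) * sp
    return ijk, mm


# ---------------------------------------------------------------------------
# end-to-end atlas segmentation
# ---------------------------------------------------------------------------


def segment_atlas(
    target_ct: ImageVolume,
    target_labels: LabelVolume,
    library: list[dict],
    iterations=REGISTRATION_ITERATIONS,
) -> SegmentationOutput:
    """Segment a target scan with a 5-scan partial-atlas library.

    Per unit: crop the target with the skeletal-mask bounding box, add the
    10-voxel zero padding, register all five partial atlases, propagate
    and majority-vote their label maps, average their joint centers, and
    re-integrate the fused box into the target frame (craniocaudal unit
    order; later units never overwrite earlier non-background voxels).
    """
    if len(library) != 5:
        raise InvalidArgumentError("atlas library must contain exactly 5 atlas scans")
    sp = np.asarray(target_ct.spacing)
    out_arr = np.zeros(target_ct.shape, dtype=np.int32)
    out = SegmentationOutput(
        target_ct.spacing, target_ct.origin, target_ct.shape, source="atlas"
    )
    unit_index = {uid: i for i, uid in enumerate(tax.VERTEBRA_UNIT_IDS)}
    fused_points: list[JointCenter] = []
    done_units: set[str] = set()

    for upper, lower in tax.ALL_UNITS:
        uid = tax.unit_id(upper, lower)
        if not (target_labels.present(upper) and target_labels.present(lower)):
            out.qc.append(f"unit {uid} skipped: structure missing in target")
            continue
        scans = [scan for scan in library if uid in scan]
        if len(scans) != 5:
            out.qc.append(f"unit {uid} skipped: missing from {5 - len(scans)} atlases")
            continue
        lo, hi = _joint_bbox(
            target_labels.mask(upper), target_labels.mask(lower), target_labels.shape
        )
        sl = tuple(slice(lo[a], hi[a] + 1) for a in range(3))
        crop = target_ct.voxels[sl]
        crop_origin = tuple(target_ct.index_to_mm(lo))
        padded, pad_origin = pad_fixed(crop, sp, crop_origin)

        propagated, transforms, ok = [], [], True
        for scan in scans:
            at = scan[uid]
            try:
                t = register_similarity(
                    padded, at.ct, sp, pad_origin, at.origin, iterations
                )
            except RegistrationError:
                out.qc.append(f"unit {uid}: registration failure, unit omitted")
                ok = False
                break
            transforms.append(t)
            propagated.append(
                propagate_labels(at, t, crop.shape, crop_origin)
            )
        if not ok:
            continue
        fused = fuse_labels(propagated)

        # re-integrate: map unit codes onto global structure labels
        if upper == tax.SACRUM:
            side = lower.split("_")[1]
            mapping = {
                UPPER_CODE: tax.STRUCTURE_IDS[tax.SACRUM],
                MIDDLE_CODE: tax.SIJ_LABEL_LEFT if side == "left" else tax.SIJ_LABEL_RIGHT,
                LOWER_CODE: tax.STRUCTURE_IDS[lower],
            }
        else:
            mapping = {
                UPPER_CODE: tax.STRUCTURE_IDS[upper],
                MIDDLE_CODE: tax.IVD_LABEL_BASE + unit_index[uid],
                LOWER_CODE: tax.STRUCTURE_IDS[lower],
            }
        target_box = out_arr[sl]
        for code, lab in mapping.items():
            sel = (fused == code) & (target_box == 0)
            target_box[sel] = lab
        done_units.add(uid)

        # joint-center fusion over the keys all five atlases agree on
        keys = set.intersection(*[set(scan[uid].joint_points) for scan in scans])
        for key in sorted(keys):
            pts = [
                t.inverse().apply_points(scan[uid].joint_points[key])
                for t, scan in zip(transforms, scans)
            ]
            ijk, mm = fuse_joint_centers(pts, sp, target_ct.origin)
            ijk = tuple(
                int(np.clip(v, 0, n - 1)) for v, n in zip(ijk, target_ct.shape)
            )
            fused_points.append(JointCenter(key[0], key[1], key[2], ijk, mm))

    # unpack the global label volume into the segmentation output
    for name in tax.VERTEBRAE:
        mask = out_arr == tax.STRUCTURE_IDS[name]
        if mask.any():
            out.vb[name] = mask
    sac = out_arr == tax.STRUCTURE_IDS[tax.SACRUM]
    out.sacrum = sac if sac.any() else None
    for idx, uid in enumerate(tax.VERTEBRA_UNIT_IDS):
        if uid not in done_units:
            continue
        mask = out_arr == tax.IVD_LABEL_BASE + idx
        out.ivd[uid] = mask
        if not mask.any():
            out.qc.append(f"empty IVD for unit {uid}")
    for side, lab in (("left", tax.SIJ_LABEL_LEFT), ("right", tax.SIJ_LABEL_RIGHT)):
        mask = out_arr == lab
        if mask.any():
            out.sij[side] = mask
    out.joint_centers = fused_points
    return out


# ---------------------------------------------------------------------------
# library persistence
# ---------------------------------------------------------------------------


def save_atlas_library(library: list[dict], outdir) -> None:
    """Serialize a library as per-unit NIfTI crops plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, scan in enumerate(library):
        entry = {}
        for uid, at in scan.items():
            stem = f"scan{i}_{uid.replace('-', '_')}"
            ct_vol = ImageVolume(at.ct, at.spacing, at.origin, "CT-HU")
            from .core import write_image, write_labels  # local to avoid cycle

            write_image(ct_vol, outdir / f"{stem}_ct.nii.gz")
            lab_vol = LabelVolume(
                at.labels.astype(np.int32),
                at.spacing,
                at.origin,
                {UPPER_CODE: "upper", MIDDLE_CODE: "middle", LOWER_CODE: "lower"},
            )
            write_labels(lab_vol, outdir / f"{stem}_labels.nii.gz")
            entry[uid] = {
                "stem": stem,
                "bbox": [list(map(int, at.bbox[0])), list(map(int, at.bbox[1]))],
                "joint_points": {
                    "|".join(k): list(map(float, v)) for k, v in at.joint_points.items()
                },
            }
        manifest.append(entry)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_atlas_library(indir) -> list[dict]:
    from .core import read_image, read_labels

    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    library = []
    for entry in manifest:
        scan = {}
        for uid, meta in entry.items():
            ct = read_image(indir / f"{meta['stem']}_ct.nii.gz")
            lab = read_labels(indir / f"{meta['stem']}_labels.nii.gz")
            points = {
                tuple(k.split("|")): np.asarray(v, dtype=float)
                for k, v in meta["joint_points"].items()
            }
            scan[uid] = PartialAtlas(
                uid,
                ct.voxels,
                lab.voxels.astype(np.int16),
                ct.origin,
                ct.spacing,
                (tuple(meta["bbox"][0]), tuple(meta["bbox"][1])),
                points,
            )
        library.append(scan)
    return library
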