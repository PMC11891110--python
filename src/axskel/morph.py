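"""Morphological segmentation method.

Vertebrae are decomposed into vertebral body (VB) and left/right posterior
parts (LPV/RPV) using the spinal cord as a per-slice landmark.  Disks and
the sacro-iliac joints come out of a dilation-overlap construction: dilate
the two flanking bones, intersect, subtract bone.  The posterior joints
(facet, costovertebral, costotransverse) are segmented not as volumes but
as single points — the center of mass of the dilation overlap.

Landmark rule: for C1-T3 the most anterior cord voxel of each axial slice
is the reference (these vertebrae carry relatively anterior transverse
processes); for T4-L5 the cord-slice center is used.  Voxels strictly
anterior of the reference are VB; the reference column itself counts as
posterior.  The posterior remainder splits left/right at the sagittal
plane through the whole-cord center of mass.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import taxonomy as tax
from .core import (
    LabelVolume,
    StructuringElement,
    binary_dilate,
    center_of_mass,
    round_half_away,
)
from .errors import EmptyMaskError, InvalidArgumentError, MissingStructureError
from .segmentation import (
    CTJ_LEVELS,
    CVJ_LEVELS,
    JointCenter,
    SegmentationOutput,
    SpineDecomposition,
)

#: levels whose reference point is the most anterior cord voxel
ANTERIOR_RULE_LEVELS = frozenset(tax.CERVICAL + ["T1", "T2", "T3"])

#: vertical structuring-element lengths (mm) per spine region
ELEMENT_LENGTH_MM = {"cervical": 4.0, "thoracic": 8.0, "lumbar": 12.0}

#: spherical element used for joint overlap, matched to the voxel size
JOINT_SPHERE_MM = 4.0

MAX_DILATION_ITERS = 5


def split_vertebra(vertebra_mask, cord_mask, level: str):
    """Split one vertebra into (VB, LPV, RPV) masks.

    Returns the three masks plus a list of QC warnings.  Slices holding
    vertebra voxels but no cord voxels borrow the nearest cord slice's
    reference point.
    """
    vert = np.asarray(vertebra_mask, dtype=bool)
    cord = np.asarray(cord_mask, dtype=bool)
    if not vert.any():
        raise EmptyMaskError(f"vertebra mask for {level} is empty")
    if not cord.any():
        raise EmptyMaskError("spinal cord mask is empty")
    qc: list[str] = []

    anterior_rule = level in ANTERIOR_RULE_LEVELS
    nz = vert.shape[2]
    cord_any = cord.any(axis=(0, 1))
    cord_slices = np.flatnonzero(cord_any)
    jj = np.arange(vert.shape[1])

    # per-slice reference: most anterior cord voxel, or cord-slice center
    ref = np.full(nz, np.nan)
    for k in cord_slices:
        js = np.flatnonzero(cord[:, :, k].any(axis=0))
        ref[k] = js.max() if anterior_rule else js.mean()

    vb = np.zeros_like(vert)
    for k in np.flatnonzero(vert.any(axis=(0, 1))):
        r = ref[k]
        if np.isnan(r):
            nearest = cord_slices[np.argmin(np.abs(cord_slices - k))]
            r = ref[nearest]
            msg = f"{level}: no cord on slice {k}, using reference from slice {nearest}"
            qc.append(msg)
            warnings.warn(msg, stacklevel=2)
        vb[:, :, k] = vert[:, :, k] & (jj[None, :] > r)

    posterior = vert & ~vb
    com_i = center_of_mass(cord)[0]
    ii = np.arange(vert.shape[0])
    left = ii[:, None, None] > com_i
    lpv = posterior & left
    rpv = posterior & ~left
    return vb, lpv, rpv, qc


def segment_ivd_morph(upper_vb, lower_vb, region: str, bone_mask, spacing=4.0):
    """Disk = overlap of the vertically dilated adjacent VBs, minus bone."""
    upper_vb = np.asarray(upper_vb, dtype=bool)
    lower_vb = np.asarray(lower_vb, dtype=bool)
    if (upper_vb & lower_vb).any():
        raise InvalidArgumentError("adjacent VB masks must be disjoint")
    se = StructuringElement("vertical-line", ELEMENT_LENGTH_MM[region])
    overlap = binary_dilate(upper_vb, se, spacing) & binary_dilate(lower_vb, se, spacing)
    return overlap & ~np.asarray(bone_mask, dtype=bool)


def _dilate_until_overlap(a, b, spacing, max_iters=MAX_DILATION_ITERS):
    """Iteratively dilate both masks with the 4 mm sphere until they meet.

    Returns (overlap, n_iterations); overlap is empty if the cap is hit.
    """
    se = StructuringElement("sphere", JOINT_SPHERE_MM)
    da, db = np.asarray(a, dtype=bool), np.asarray(b, dtype=bool)
    for it in range(1, max_iters + 1):
        da = binary_dilate(da, se, spacing)
        db = binary_dilate(db, se, spacing)
        overlap = da & db
        if overlap.any():
            return overlap, it
    return np.zeros_like(da), max_iters


def segment_sij_morph(sacrum_mask, ilium_mask, bone_mask, spacing=4.0):
    """Sacro-iliac joint mask from iterative dilation overlap, minus bone."""
    sacrum_mask = np.asarray(sacrum_mask, dtype=bool)
    ilium_mask = np.asarray(ilium_mask, dtype=bool)
    if (sacrum_mask & ilium_mask).any():
        raise InvalidArgumentError("sacrum and ilium masks must be disjoint")
    overlap, _ = _dilate_until_overlap(sacrum_mask, ilium_mask, spacing)
    return overlap & ~np.asarray(bone_mask, dtype=bool)


def locate_joint_center_morph(mask_a, mask_b, spacing=4.0, origin=(0.0, 0.0, 0.0)):
    """Joint center = COM of the dilation overlap, rounded to a voxel.

    Returns ``(ijk, mm, n_iterations)`` or ``None`` when the masks never
    meet within the iteration cap.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if not mask_a.any() or not mask_b.any():
        raise EmptyMaskError("joint localisation requires two non-empty masks")
    if (mask_a & mask_b).any():
        raise InvalidArgumentError("joint partner masks must be disjoint")
    overlap, n = _dilate_until_overlap(mask_a, mask_b, spacing)
    if not overlap.any():
        return None
    com = center_of_mass(overlap)
    ijk = tuple(int(v) for v in round_half_away(com))
    mm = np.asarray(origin) + np.asarray(ijk) * np.asarray(
        spacing if np.ndim(spacing) else (spacing,) * 3
    )
    return ijk, mm, n


def segment_morph(labels: LabelVolume) -> SegmentationOutput:
    """Run the full morphological pipeline on a multi-label skeletal mask.

    Produces VB/LPV/RPV decompositions, IVD and SIJ masks, and the
    FJ/CVJ/CTJ joint-center inventory.
    """
    if not labels.present(tax.SPINAL_CORD):
        raise MissingStructureError("spinal cord missing from input labels")
    spacing = labels.spacing
    sp_scalar = spacing[0]
    cord = labels.mask(tax.SPINAL_CORD)
    bone = np.zeros(labels.shape, dtype=bool)
    for name in tax.BONE_STRUCTURES:
        if name in labels.name_to_id:
            bone |= labels.mask(name)

    out = SegmentationOutput(spacing, labels.origin, labels.shape, source="morph")
    deco = SpineDecomposition()
    for name in tax.VERTEBRAE:
        if not labels.present(name):
            out.qc.append(f"missing vertebra {name}")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vb, lpv, rpv, qc = split_vertebra(labels.mask(name), cord, name)
        out.qc.extend(qc)
        deco.entries[name] = (vb, lpv, rpv)
        out.vb[name] = vb
    out.decomposition = deco
    if labels.present(tax.SACRUM):
        out.sacrum = labels.mask(tax.SACRUM)

    def lower_part(lower: str, side: str | None = None):
        """Partner mask for the lower member of a unit (sacrum has no split)."""
        if lower == tax.SACRUM:
            return out.sacrum
        if side is None:
            return deco.vb(lower)
        return deco.posterior(lower, side)

    # disks and facet joints over the 24 adjacent-vertebra units
    for upper, lower in tax.VERTEBRA_UNITS:
        uid = tax.unit_id(upper, lower)
        if upper not in deco.entries or (
            lower not in deco.entries and not (lower == tax.SACRUM and out.sacrum is not None)
        ):
            out.qc.append(f"unit {uid} skipped: structure missing")
            continue
        region = tax.region_of(uid)
        low_vb = lower_part(lower)
        ivd = segment_ivd_morph(deco.vb(upper), low_vb, region, bone, sp_scalar)
        if not ivd.any():
            out.qc.append(f"empty IVD for unit {uid}")
        out.ivd[uid] = ivd
        for side in ("left", "right"):
            partner = (
                out.sacrum if lower == tax.SACRUM else deco.posterior(lower, side)
            )
            loc = locate_joint_center_morph(
                deco.posterior(upper, side), partner, sp_scalar, labels.origin
            )
            if loc is None:
                out.qc.append(f"FJ {uid} {side}: no dilation overlap")
                continue
            ijk, mm, _ = loc
            out.joint_centers.append(JointCenter("FJ", uid, side, ijk, mm))

    # costovertebral and costotransverse joints
    for lvl in CVJ_LEVELS:
        if lvl not in deco.entries:
            continue
        n = lvl[1:]
        for side in ("left", "right"):
            rib_name = f"rib_{side}_{n}"
            if not labels.present(rib_name):
                out.qc.append(f"CVJ {lvl} {side}: rib missing")
                continue
            rib = labels.mask(rib_name)
            loc = locate_joint_center_morph(rib, deco.vb(lvl), sp_scalar, labels.origin)
            if loc is None:
                out.qc.append(f"CVJ {lvl} {side}: no dilation overlap")
            else:
                out.joint_centers.append(JointCenter("CVJ", lvl, side, loc[0], loc[1]))
            if lvl in CTJ_LEVELS:
                loc = locate_joint_center_morph(
                    rib, deco.posterior(lvl, side), sp_scalar, labels.origin
                )
                if loc is None:
                    out.qc.append(f"CTJ {lvl} {side}: no dilation overlap")
                else:
                    out.joint_centers.append(JointCenter("CTJ", lvl, side, loc[0], loc[1]))

    # sacro-iliac joints
    if out.sacrum is not None:
        for side in ("left", "right"):
            name = f"ilium_{side}"
            if not labels.present(name):
                out.qc.append(f"SIJ {side}: ilium missing")
                continue
            sij = segment_sij_morph(out.sacrum, labels.mask(name), bone, sp_scalar)
            if not sij.any():
                out.qc.append(f"SIJ {side}: no dilation overlap")
            out.sij[side] = sij
    else:
        out.qc.append("sacrum missing: SIJs skipped")
    return out
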