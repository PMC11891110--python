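"""VOI composition: vertebral-body quadrants, discovertebral units,
spherical posterior-joint VOIs and the per-scan VOI inventory.

A complete scan carries 118 VOIs: 24 DVUs, 48 FJs, 24 CVJs, 20 CTJs and
2 SIJs.  A DVU is the four inferior quadrants of the upper vertebral body,
the intervertebral disk, and the four superior quadrants of the lower
body; posterior joints are 10 mm-radius spheres grown from the joint-center
points; the SIJ VOIs are the segmented joint masks themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import taxonomy as tax
from .core import StructuringElement, center_of_mass, round_half_away
from .errors import EmptyMaskError, InvalidArgumentError
from .segmentation import SegmentationOutput

SPHERE_RADIUS_MM = 10.0

#: deterministic corner order; distance ties go to the earlier corner
_CORNERS = ("AS", "AI", "PS", "PI")  # antero/postero x superior/inferior


@dataclass
class VoiRecord:
    """One anatomical VOI with its binary mask."""

    kind: str  # DVU | FJ | CVJ | CTJ | SIJ
    level: str
    side: str | None
    mask: np.ndarray
    source: str  # morph | atlas
    region: str  # cervical | thoracic | lumbar

    def __post_init__(self):
        if self.kind not in ("DVU", "FJ", "CVJ", "CTJ", "SIJ"):
            raise InvalidArgumentError(f"unknown VOI kind {self.kind!r}")
        if not self.mask.any():
            raise EmptyMaskError(f"VOI {self.kind} {self.level} {self.side} is empty")

    @property
    def key(self) -> tuple:
        return (self.kind, self.level, self.side)

    @property
    def voi_id(self) -> str:
        side = f"_{self.side}" if self.side else ""
        return f"{self.kind}_{self.level}{side}"


def split_vb_quadrants(vb_mask, spacing=4.0):
    """Split a vertebral body into 8 quadrants.

    The VB bounding box inside the COM mid-sagittal slice provides the four
    corner landmarks (antero/postero x superior/inferior); every VB voxel is
    assigned to the nearest corner by its (anteroposterior, craniocaudal)
    mm coordinates, and split left/right at the COM sagittal plane.  The 8
    sub-masks partition the VB.  Returns ``(quadrants, qc)`` with quadrant
    keys ``(side, corner)``.
    """
    vb = np.asarray(vb_mask, dtype=bool)
    if not vb.any():
        raise EmptyMaskError("cannot split an empty VB mask")
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    qc: list[str] = []
    com = center_of_mass(vb)
    i0 = int(np.clip(round_half_away(com[0]), 0, vb.shape[0] - 1))
    mid = vb[i0]
    if not mid.any():
        mid = vb.any(axis=0)
        qc.append("mid-sagittal slice empty; corners from whole-VB projection")
    js, ks = np.nonzero(mid)
    jmin, jmax = js.min(), js.max()
    kmin, kmax = ks.min(), ks.max()
    corners = {
        "AS": (jmax, kmax),
        "AI": (jmax, kmin),
        "PS": (jmin, kmax),
        "PI": (jmin, kmin),
    }
    idx = np.argwhere(vb)
    d2 = np.stack(
        [
            ((idx[:, 1] - cj) * sp[1]) ** 2 + ((idx[:, 2] - ck) * sp[2]) ** 2
            for cj, ck in (corners[c] for c in _CORNERS)
        ],
        axis=1,
    )
    nearest = np.argmin(d2, axis=1)  # ties -> earlier corner in _CORNERS
    left = idx[:, 0] > com[0]

    quadrants = {}
    for ci, cname in enumerate(_CORNERS):
        for side, sel_side in (("left", left), ("right", ~left)):
            m = np.zeros_like(vb)
            sel = idx[(nearest == ci) & sel_side]
            m[tuple(sel.T)] = True
            quadrants[(side, cname)] = m
    if vb.sum() == 1:
        qc.append("single-voxel VB: all in one quadrant")
    return quadrants, qc


def compose_dvu(upper_quadrants: dict, ivd_mask, lower_quadrants: dict) -> np.ndarray:
    """DVU = inferior quadrants (upper VB) + IVD + superior quadrants (lower VB)."""
    ivd = np.asarray(ivd_mask, dtype=bool)
    out = ivd.copy()
    for (side, corner), m in upper_quadrants.items():
        if corner.endswith("I"):
            if (m & ivd).any():
                raise InvalidArgumentError("DVU constituents must be pairwise disjoint")
            out |= m
    for (side, corner), m in lower_quadrants.items():
        if corner.endswith("S"):
            if (m & ivd).any():
                raise InvalidArgumentError("DVU constituents must be pairwise disjoint")
            out |= m
    return out


def sphere_voi(center_ijk, shape, spacing=4.0, radius_mm=SPHERE_RADIUS_MM) -> np.ndarray:
    """Closed-ball spherical VOI around a joint-center voxel, clipped at the
    grid boundary (81 voxels for the 10 mm sphere on the 4 mm grid)."""
    center = np.asarray(center_ijk, dtype=int)
    shape = np.asarray(shape, dtype=int)
    if np.any(center < 0) or np.any(center >= shape):
        raise InvalidArgumentError(f"sphere center {tuple(center)} outside the grid")
    off = StructuringElement("sphere", radius_mm).offsets(spacing)
    pts = center[None, :] + off
    keep = np.all((pts >= 0) & (pts < shape[None, :]), axis=1)
    m = np.zeros(tuple(shape), dtype=bool)
    m[tuple(pts[keep].T)] = True
    return m


def build_voi_inventory(seg: SegmentationOutput, sphere_radius_mm=SPHERE_RADIUS_MM):
    """Emit the full VOI inventory for one segmented scan.

    Missing structures simply yield fewer records; each absence is QC
    flagged.  Re-running on the same segmentation is bit-identical.
    """
    vois: list[VoiRecord] = []
    qc: list[str] = []
    sp = seg.spacing

    quad_cache: dict[str, dict] = {}

    def quadrants_of(name: str):
        if name in quad_cache:
            return quad_cache[name]
        mask = seg.sacrum if name == tax.SACRUM else seg.vb.get(name)
        if mask is None or not mask.any():
            return None
        q, q_qc = split_vb_quadrants(mask, sp)
        qc.extend(f"{name}: {m}" for m in q_qc)
        quad_cache[name] = q
        return q

    for upper, lower in tax.VERTEBRA_UNITS:
        uid = tax.unit_id(upper, lower)
        uq = quadrants_of(upper)
        lq = quadrants_of(lower)
        if uq is None or lq is None:
            qc.append(f"DVU {uid} skipped: vertebra missing")
            continue
        ivd = seg.ivd.get(uid)
        if ivd is None or not ivd.any():
            ivd = np.zeros(seg.shape, dtype=bool)
            qc.append(f"DVU {uid}: empty IVD (possible ankylosis)")
        mask = compose_dvu(uq, ivd, lq)
        vois.append(VoiRecord("DVU", uid, None, mask, seg.source, tax.region_of(uid)))

    for jc in sorted(seg.joint_centers, key=lambda j: (j.kind, j.level, j.side)):
        mask = sphere_voi(jc.ijk, seg.shape, sp, sphere_radius_mm)
        vois.append(
            VoiRecord(jc.kind, jc.level, jc.side, mask, seg.source, tax.region_of(jc.level))
        )

    for side in ("left", "right"):
        mask = seg.sij.get(side)
        if mask is None or not mask.any():
            qc.append(f"SIJ {side} missing from segmentation")
            continue
        vois.append(VoiRecord("SIJ", tax.SACRUM, side, mask, seg.source, "lumbar"))
    return vois, qc
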