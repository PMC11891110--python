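"""Shared segmentation output model: joint centers, decompositions, inventories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import taxonomy as tax
from .core import LabelVolume
from .errors import InvalidArgumentError

JOINT_KINDS = ("FJ", "CVJ", "CTJ")

#: costotransverse articulations exist on T1-T10 only (the T11/T12 ribs
#: lack transverse-process facets), fixing the 20-joint inventory
CTJ_LEVELS = [f"T{i}" for i in range(1, 11)]
CVJ_LEVELS = list(tax.THORACIC)


def legal_joint_inventory() -> list[tuple[str, str, str]]:
    """All (kind, level, side) combinations a complete scan must yield:
    48 FJs (24 adjacent-vertebra units x 2 sides), 24 CVJs, 20 CTJs."""
    inv = []
    for uid in tax.VERTEBRA_UNIT_IDS:
        for side in ("left", "right"):
            inv.append(("FJ", uid, side))
    for lvl in CVJ_LEVELS:
        for side in ("left", "right"):
            inv.append(("CVJ", lvl, side))
    for lvl in CTJ_LEVELS:
        for side in ("left", "right"):
            inv.append(("CTJ", lvl, side))
    return inv


@dataclass
class JointCenter:
    """A joint segmented as a single point: the joint-center voxel."""

    kind: str  # FJ | CVJ | CTJ
    level: str  # unit id for FJs (e.g. "C1-C2"), vertebra for CVJ/CTJ
    side: str  # left | right
    ijk: tuple  # voxel index
    mm: np.ndarray  # world coordinate of the voxel center

    def __post_init__(self):
        if self.kind not in JOINT_KINDS:
            raise InvalidArgumentError(f"unknown joint kind {self.kind!r}")
        if self.side not in ("left", "right"):
            raise InvalidArgumentError(f"unknown side {self.side!r}")
        self.ijk = tuple(int(x) for x in self.ijk)
        self.mm = np.asarray(self.mm, dtype=float)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.kind, self.level, self.side)


@dataclass
class SpineDecomposition:
    """Per-vertebra split into vertebral body and left/right posterior parts.

    Invariant: ``vb | lpv | rpv`` equals the original vertebra mask and the
    three parts are pairwise disjoint.
    """

    entries: dict = field(default_factory=dict)  # level -> (vb, lpv, rpv)

    def vb(self, level: str) -> np.ndarray:
        return self.entries[level][0]

    def lpv(self, level: str) -> np.ndarray:
        return self.entries[level][1]

    def rpv(self, level: str) -> np.ndarray:
        return self.entries[level][2]

    def posterior(self, level: str, side: str) -> np.ndarray:
        return self.entries[level][1 if side == "left" else 2]


@dataclass
class SegmentationOutput:
    """Everything one segmentation method produces for one scan."""

    spacing: tuple
    origin: tuple
    shape: tuple
    source: str  # "morph" | "atlas"
    vb: dict = field(default_factory=dict)  # vertebra -> mask
    sacrum: np.ndarray | None = None
    ivd: dict = field(default_factory=dict)  # unit id -> mask
    sij: dict = field(default_factory=dict)  # side -> mask
    joint_centers: list = field(default_factory=list)
    decomposition: SpineDecomposition | None = None  # morph only
    qc: list = field(default_factory=list)

    def find_center(self, kind: str, level: str, side: str) -> JointCenter | None:
        for jc in self.joint_centers:
            if jc.key == (kind, level, side):
                return jc
        return None

    def to_label_volume(self) -> LabelVolume:
        """Render the volumetric outputs into one multi-label volume
        (vertebral bodies, IVDs, SIJs, sacrum); earlier structures win."""
        out = np.zeros(self.shape, dtype=np.int32)
        taxonomy: dict[int, str] = {}

        def put(mask, lab, name):
            if mask is None:
                return
            sel = mask & (out == 0)
            out[sel] = lab
            taxonomy[lab] = name

        for name in tax.VERTEBRAE:
            if name in self.vb:
                put(self.vb[name], tax.STRUCTURE_IDS[name], name)
        put(self.sacrum, tax.STRUCTURE_IDS[tax.SACRUM], tax.SACRUM)
        for idx, uid in enumerate(tax.VERTEBRA_UNIT_IDS):
            if uid in self.ivd:
                put(self.ivd[uid], tax.IVD_LABEL_BASE + idx, f"ivd_{uid}")
        if "left" in self.sij:
            put(self.sij["left"], tax.SIJ_LABEL_LEFT, "sij_left")
        if "right" in self.sij:
            put(self.sij["right"], tax.SIJ_LABEL_RIGHT, "sij_right")
        return LabelVolume(out, self.spacing, self.origin, taxonomy)
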