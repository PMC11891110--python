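"""Structure taxonomy: the label dialect every pipeline stage speaks.

The pipeline consumes multi-label skeletal segmentations in the style of
TotalSegmentator output (one integer id per structure).  This module pins a
compact in-package id assignment, the vertebral ordering, the adjacent-pair
unit inventory and the mapping from TotalSegmentator structure names.

Axis convention used throughout the package (canonical "LAS" index order):

* axis 0 (``i``): increasing index = patient **left**
* axis 1 (``j``): increasing index = **anterior**
* axis 2 (``k``): increasing index = **superior** (craniocaudal)

so "anterior of" and "left of" are plain index comparisons.
"""

from __future__ import annotations

from .errors import MissingStructureError

# --- vertebrae, in total craniocaudal order ---------------------------------
CERVICAL = [f"C{i}" for i in range(1, 8)]
THORACIC = [f"T{i}" for i in range(1, 13)]
LUMBAR = [f"L{i}" for i in range(1, 6)]
VERTEBRAE = CERVICAL + THORACIC + LUMBAR  # 24 vertebrae, C1 first

SACRUM = "sacrum"
SPINAL_CORD = "spinal_cord"

# id assignment: vertebrae 1..24 in order, then the rest
STRUCTURE_IDS: dict[str, int] = {name: i + 1 for i, name in enumerate(VERTEBRAE)}
STRUCTURE_IDS[SACRUM] = 25
STRUCTURE_IDS[SPINAL_CORD] = 26
STRUCTURE_IDS["ilium_left"] = 27
STRUCTURE_IDS["ilium_right"] = 28
STRUCTURE_IDS["femur_left"] = 29
STRUCTURE_IDS["femur_right"] = 30
STRUCTURE_IDS["liver"] = 31
STRUCTURE_IDS["aorta"] = 32
for n in range(1, 13):
    STRUCTURE_IDS[f"rib_left_{n}"] = 40 + n
    STRUCTURE_IDS[f"rib_right_{n}"] = 52 + n

ID_TO_NAME: dict[int, str] = {v: k for k, v in STRUCTURE_IDS.items()}

#: structures counted as bone for the morphological set algebra
BONE_STRUCTURES = (
    VERTEBRAE
    + [SACRUM, "ilium_left", "ilium_right", "femur_left", "femur_right"]
    + [f"rib_left_{n}" for n in range(1, 13)]
    + [f"rib_right_{n}" for n in range(1, 13)]
)

# --- adjacent-structure units ------------------------------------------------
#: 24 adjacent vertebra pairs: C1-C2 ... L5-sacrum
VERTEBRA_UNITS: list[tuple[str, str]] = [
    (VERTEBRAE[i], VERTEBRAE[i + 1]) for i in range(len(VERTEBRAE) - 1)
] + [("L5", SACRUM)]
#: 2 sacro-iliac units
SIJ_UNITS: list[tuple[str, str]] = [(SACRUM, "ilium_left"), (SACRUM, "ilium_right")]
#: all 26 partial-atlas units, craniocaudal then sacro-iliac
ALL_UNITS: list[tuple[str, str]] = VERTEBRA_UNITS + SIJ_UNITS


def unit_id(upper: str, lower: str) -> str:
    return f"{upper}-{lower}"


UNIT_IDS = [unit_id(a, b) for a, b in ALL_UNITS]
VERTEBRA_UNIT_IDS = [unit_id(a, b) for a, b in VERTEBRA_UNITS]

#: label values for pipeline-output structures (disks, sacro-iliac joints)
IVD_LABEL_BASE = 100  # IVD of vertebra unit u -> 100 + index of u
SIJ_LABEL_LEFT = 201
SIJ_LABEL_RIGHT = 202


def region_of(level: str) -> str:
    """Spine region of a vertebral level or unit id.

    Cervical levels map to ``cervical``, thoracic to ``thoracic`` and
    lumbar/sacral to ``lumbar``.  For a two-structure unit id the upper
    member decides.
    """
    first = level.split("-")[0]
    if first.startswith("C"):
        return "cervical"
    if first.startswith("T"):
        return "thoracic"
    if first.startswith("L") or first == SACRUM or first.startswith("ilium"):
        return "lumbar"
    raise MissingStructureError(f"no spine region for level {level!r}")


def vertebra_order(name: str) -> int:
    """Total craniocaudal order: C1 < C2 < ... < L5 < sacrum."""
    if name == SACRUM:
        return len(VERTEBRAE)
    return VERTEBRAE.index(name)


# --- TotalSegmentator name mapping ------------------------------------------
#: maps TotalSegmentator v2 structure names to package structure names
TOTALSEGMENTATOR_NAMES: dict[str, str] = {
    **{f"vertebrae_{v}": v for v in VERTEBRAE},
    "sacrum": SACRUM,
    "spinal_cord": SPINAL_CORD,
    "hip_left": "ilium_left",
    "hip_right": "ilium_right",
    "femur_left": "femur_left",
    "femur_right": "femur_right",
    "liver": "liver",
    "aorta": "aorta",
    **{f"rib_left_{n}": f"rib_left_{n}" for n in range(1, 13)},
    **{f"rib_right_{n}": f"rib_right_{n}" for n in range(1, 13)},
}


def default_taxonomy() -> dict[int, str]:
    """Fresh id -> name mapping covering the full structure inventory."""
    return dict(ID_TO_NAME)
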