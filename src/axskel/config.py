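"""Pipeline configuration: one YAML-serialisable object holding every
tunable, with defaults matching the reference protocol (4 mm working grid,
12/8/4 mm vertical elements, 10 mm joint spheres, {10,30,50,70,90} atlas
percentiles, 100 registration iterations, TBR cut-offs 1.8/2.25 and raw
SUVmax cut-offs 10.4/13.0)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidArgumentError


@dataclass
class PipelineConfig:
    working_spacing_mm: float = 4.0
    element_length_mm: dict = field(
        default_factory=lambda: {"cervical": 4.0, "thoracic": 8.0, "lumbar": 12.0}
    )
    joint_sphere_mm: float = 4.0  # morphological overlap element
    voi_sphere_radius_mm: float = 10.0  # posterior-joint VOI radius
    suvpeak_radius_mm: float = 6.0
    atlas_percentiles: tuple = (10, 30, 50, 70, 90)
    registration_iterations: int = 100
    max_dilation_iterations: int = 5
    detection_rule: str = "tbr-suvmax"
    tbr_cutoffs: dict = field(default_factory=lambda: {"joint": 1.8, "dvu": 2.25})
    raw_suvmax_cutoffs: dict = field(default_factory=lambda: {"joint": 10.4, "dvu": 13.0})
    seed: int = 0
    output_dir: str = "axskel_out"

    def __post_init__(self):
        if self.working_spacing_mm <= 0:
            raise InvalidArgumentError("working spacing must be positive")
        if self.detection_rule not in ("tbr-suvmax", "raw-suvmax"):
            raise InvalidArgumentError(f"unknown detection rule {self.detection_rule!r}")
        if self.registration_iterations < 1:
            raise InvalidArgumentError("registration iterations must be >= 1")
        self.atlas_percentiles = tuple(self.atlas_percentiles)

    @property
    def cutoffs(self) -> dict:
        return self.tbr_cutoffs if self.detection_rule == "tbr-suvmax" else self.raw_suvmax_cutoffs

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["atlas_percentiles"] = list(self.atlas_percentiles)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
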