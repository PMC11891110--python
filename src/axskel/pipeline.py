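"""End-to-end pipeline orchestration and artifact writing.

Ties the stages together (phantom or file inputs -> segmentation -> VOI
inventory -> PET quantification -> detection) and writes the output bundle:
segmentation NIfTI, joint-center CSV, VOI manifest, detections CSV and a
QC report.  No stage mutates its inputs; everything lands in the output
directory, and a given seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import ImageVolume, LabelVolume, resample_to_grid, write_labels
from .detection import background_medians, classify_vois, measure_vois
from .morph import segment_morph
from .segmentation import SegmentationOutput
from .voi import build_voi_inventory


def load_inputs(ct_path, labels_path, pet_path=None, config: PipelineConfig | None = None):
    """Read NIfTI inputs and resample everything to the working grid."""
    from .core import read_image, read_labels

    config = config or PipelineConfig()
    sp = config.working_spacing_mm
    ct = resample_to_grid(read_image(ct_path, "CT-HU"), sp)
    labels = resample_to_grid(read_labels(labels_path), sp)
    pet = None
    if pet_path is not None:
        pet = resample_to_grid(read_image(pet_path, "PET-SUV"), sp)
    return ct, labels, pet


def joint_centers_frame(seg: SegmentationOutput) -> pd.DataFrame:
    rows = [
        {
            "kind": jc.kind,
            "level": jc.level,
            "side": jc.side,
            "i": jc.ijk[0],
            "j": jc.ijk[1],
            "k": jc.ijk[2],
            "x_mm": round(float(jc.mm[0]), 2),
            "y_mm": round(float(jc.mm[1]), 2),
            "z_mm": round(float(jc.mm[2]), 2),
        }
        for jc in sorted(seg.joint_centers, key=lambda j: (j.kind, j.level, str(j.side)))
    ]
    return pd.DataFrame(rows, columns=["kind", "level", "side", "i", "j", "k", "x_mm", "y_mm", "z_mm"])


def voi_manifest_frame(vois) -> pd.DataFrame:
    rows = [
        {
            "voi_id": v.voi_id,
            "kind": v.kind,
            "level": v.level,
            "side": v.side or "",
            "region": v.region,
            "voxels": int(v.mask.sum()),
        }
        for v in vois
    ]
    return pd.DataFrame(rows, columns=["voi_id", "kind", "level", "side", "region", "voxels"])


def detections_frame(measurements, predictions, config: PipelineConfig) -> pd.DataFrame:
    fam = lambda kind: "dvu" if kind == "DVU" else "joint"
    rows = []
    for m in measurements:
        v = m.voi
        rows.append(
            {
                "voi_id": v.voi_id,
                "suvmax": round(m.metrics.suv_max, 4),
                "suvpeak": round(m.metrics.suv_peak, 4),
                "suvmean": round(m.metrics.suv_mean, 4),
                "background_region": m.background_region,
                "suvmedian_bg": round(m.background, 4),
                "tbr": round(m.tbr, 4),
                "predicted": int(predictions[v.key]),
                "threshold": config.cutoffs[fam(v.kind)],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "voi_id",
            "suvmax",
            "suvpeak",
            "suvmean",
            "background_region",
            "suvmedian_bg",
            "tbr",
            "predicted",
            "threshold",
        ],
    )


def run_pipeline(
    ct: ImageVolume,
    labels: LabelVolume,
    pet: ImageVolume | None = None,
    config: PipelineConfig | None = None,
    outdir=None,
    atlas_library=None,
) -> dict:
    """Run segmentation (+ detection when PET given) and write the bundle.

    Uses the morphological method unless an atlas library is supplied.
    Returns a dict with the in-memory results and the QC flag list.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    qc: list[str] = []

    if atlas_library is not None:
        from .atlas import segment_atlas

        seg = segment_atlas(ct, labels, atlas_library, config.registration_iterations)
    else:
        seg = segment_morph(labels)
    qc.extend(seg.qc)

    vois, voi_qc = build_voi_inventory(seg, config.voi_sphere_radius_mm)
    qc.extend(voi_qc)

    write_labels(seg.to_label_volume(), outdir / "segmentation.nii.gz")
    joint_centers_frame(seg).to_csv(outdir / "joint_centers.csv", index=False)
    voi_manifest_frame(vois).to_csv(outdir / "voi_manifest.csv", index=False)

    result = {"segmentation": seg, "vois": vois, "qc": qc}
    if pet is not None:
        backgrounds = background_medians(pet, labels)
        measurements = measure_vois(pet, vois, backgrounds)
        skipped = len(vois) - len(measurements)
        if skipped:
            qc.append(f"{skipped} VOIs skipped: background region unavailable")
        predictions = classify_vois(measurements, config.detection_rule, config.cutoffs)
        detections_frame(measurements, predictions, config).to_csv(
            outdir / "detections.csv", index=False
        )
        result.update(
            backgrounds=backgrounds, measurements=measurements, predictions=predictions
        )

    config.to_yaml(outdir / "config_resolved.yaml")
    (outdir / "qc_report.json").write_text(json.dumps({"flags": qc}, indent=1))
    return result
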