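"""Read/write head models, implantation schemas and plan documents.

All format dialects are fixed here: NIfTI for volumes (uncompressed
``.nii`` written by default so repeated runs are bytes-identical;
``.nii.gz`` accepted on read), JSON for model metadata, schemas and
plans, CSV for metric tables. Voxel indices are 0-based with the
voxel-center convention; world units are millimetres; plans carry only
world coordinates — voxel indices never leak into a PlanDocument.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .metrics import METRIC_COLUMNS
from .phantom import HeadModel, ImplantationSchema

__all__ = [
    "WorldPoint",
    "PlannedElectrode",
    "PlanDocument",
    "voxel_to_world",
    "world_to_voxel",
    "save_head_model",
    "load_head_model",
    "save_schema",
    "load_schema",
    "write_plan",
    "read_plan",
    "plan_metrics_table",
    "model_fingerprint",
]

VOLUME_FILES = {
    "scalp_mask": "scalp",
    "brain_mask": "brain",
    "gm_mask": "gm",
    "sulci_mask": "sulci",
    "vessel_mask": "vessels",
    "roi_labels": "rois",
}


class WorldPoint(BaseModel):
    """A point in world space, mm."""

    model_config = ConfigDict(frozen=True)
    x: float
    y: float
    z: float

    @field_validator("x", "y", "z")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not np.isfinite(v):
            raise ValueError("coordinates must be finite")
        return v

    @classmethod
    def of(cls, xyz) -> "WorldPoint":
        x, y, z = (float(v) for v in np.asarray(xyz, float))
        return cls(x=x, y=y, z=z)

    def array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class PlannedElectrode(BaseModel):
    name: str
    entry: WorldPoint
    target: WorldPoint
    metrics: dict[str, float]
    provenance: Literal["plan2", "plan3", "plan4", "manual"]
    warnings: list[str] = []


class PlanDocument(BaseModel):
    """Serializable multi-electrode plan with plan-level summaries.

    ``plan_summary`` holds the arithmetic mean of each metric over
    electrodes; ``model_fingerprint`` ties the plan to the head model
    content it was planned on, so metrics remain recomputable.
    """

    electrodes: list[PlannedElectrode]
    plan_summary: dict[str, float]
    constraints: dict
    model_fingerprint: str
    provenance_info: dict = {}


def voxel_to_world(index, affine) -> np.ndarray:
    """Map a (possibly fractional) 0-based voxel index to world mm."""
    affine = np.asarray(affine, float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("singular affine")
    idx = np.asarray(index, float)
    return affine[:3, :3] @ idx + affine[:3, 3]


def world_to_voxel(point, affine) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`; returns continuous voxel coords."""
    affine = np.asarray(affine, float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("singular affine")
    return np.linalg.solve(affine[:3, :3], np.asarray(point, float) - affine[:3, 3])


def model_fingerprint(model: HeadModel) -> str:
    """Content hash of all volumes + affine (sha256, hex)."""
    h = hashlib.sha256()
    for attr in VOLUME_FILES:
        h.update(np.ascontiguousarray(getattr(model, attr)).tobytes())
    h.update(np.ascontiguousarray(model.affine).tobytes())
    return h.hexdigest()


def save_head_model(model: HeadModel, path, compress: bool = False) -> Path:
    """Write a head model as a directory of NIfTI volumes + model.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    for attr, stem in VOLUME_FILES.items():
        data = np.asarray(getattr(model, attr))
        dtype = np.int16 if attr == "roi_labels" else np.uint8
        img = nib.Nifti1Image(data.astype(dtype), model.affine)
        nib.save(img, path / f"{stem}{ext}")
    meta = {
        "voxel_spacing_mm": [float(v) for v in model.voxel_spacing],
        "affine": np.asarray(model.affine).tolist(),
        "region_names": {str(k): v for k, v in model.region_names.items()},
    }
    (path / "model.json").write_text(json.dumps(meta, indent=2) + "\n")
    return path


def _find_volume(path: Path, stem: str) -> Path:
    for ext in (".nii", ".nii.gz"):
        p = path / f"{stem}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(f"missing required volume {stem}.nii[.gz] in {path}")


def load_head_model(path) -> HeadModel:
    """Load a head-model directory; masks binarized as value > 0."""
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    volumes = {}
    shape = None
    affine = None
    ref_file = None
    for attr, stem in VOLUME_FILES.items():
        p = _find_volume(path, stem)
        img = nib.load(p)
        data = np.asarray(img.dataobj)
        if shape is None:
            shape, affine, ref_file = data.shape, img.affine, p.name
        else:
            if data.shape != shape:
                raise ValueError(
                    f"{p.name}: shape {data.shape} does not match {ref_file} {shape}"
                )
            if not np.allclose(img.affine, affine, atol=1e-6):
                raise ValueError(f"{p.name}: affine does not match {ref_file}")
        if attr == "roi_labels":
            volumes[attr] = data.astype(np.int16)
        else:
            volumes[attr] = data > 0
    region_names = {int(k): v for k, v in meta.get("region_names", {}).items()}
    present = set(int(v) for v in np.unique(volumes["roi_labels"])) - {0}
    for lbl in present - set(region_names):
        warnings.warn(f"label {lbl} present in rois volume but unnamed in model.json")
    model = HeadModel(affine=np.asarray(affine, float), region_names=region_names, **volumes)
    model.validate()
    return model


def save_schema(schema: ImplantationSchema, path) -> Path:
    path = Path(path)
    doc = {
        "electrodes": [
            {"name": n, "entry_region": int(e), "target_region": int(t)}
            for n, e, t in schema
        ]
    }
    path.write_text(json.dumps(doc, indent=2) + "\n")
    return path


def load_schema(path) -> ImplantationSchema:
    doc = json.loads(Path(path).read_text())
    return ImplantationSchema(
        tuple(
            (e["name"], int(e["entry_region"]), int(e["target_region"]))
            for e in doc["electrodes"]
        )
    )


def write_plan(plan: PlanDocument, path) -> Path:
    path = Path(path)
    path.write_text(plan.model_dump_json(indent=2) + "\n")
    return path


def read_plan(path) -> PlanDocument:
    """Parse and validate a plan JSON; errors name the offending field."""
    return PlanDocument.model_validate_json(Path(path).read_text())


def plan_metrics_table(plan: PlanDocument) -> pd.DataFrame:
    """One row per electrode with the clinically reported column names."""
    rows = []
    for e in plan.electrodes:
        row = {"Electrode": e.name, "Provenance": e.provenance}
        for key, col in METRIC_COLUMNS.items():
            row[col] = e.metrics.get(key, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
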