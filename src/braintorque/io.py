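"""Surface and table I/O.

Meshes are read from the formats a surface-reconstruction pipeline
typically leaves behind — OFF, PLY (ASCII or binary), GIFTI surface files,
and FreeSurfer binary surfaces — with coordinates taken as RAS mm.
Measurement records are written as CSV (rounded for reading) plus a JSON
sidecar holding full-precision values and the configuration that produced
them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import trimesh as _trimesh

from . import __version__
from .geometry import TriMesh
from .metrics import Configuration, DimensionRecord, TorqueRecord

__all__ = [
    "PipelineConfig",
    "read_surface",
    "write_surface",
    "write_records",
    "read_records",
    "RECORD_COLUMNS",
]

MESH_FORMATS = ("off", "ply", "gifti", "freesurfer")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the measurement pipeline.

    theta_max
        Medial-surface angle threshold in degrees: a vertex is medial when
        its outward normal is within this angle of the midline direction.
    central_fraction
        Fraction of the antero-posterior extent (centred on mid-brain)
        whose medial vertices feed the MSP fit.
    quarter_fraction
        Fraction of the antero-posterior extent defining the frontal and
        occipital regions for bending.
    tol, max_iter
        MSP alignment convergence: residual angle (degrees) and iteration cap.
    rounding
        Decimal places used when serialising reports (full precision is
        kept internally and in the JSON sidecar).
    """

    theta_max: float = 40.0
    central_fraction: float = 0.5
    quarter_fraction: float = 0.25
    tol: float = 0.01
    max_iter: int = 5
    rounding: int = 2
    seed: int = 0
    mesh_format: str = "off"

    def __post_init__(self) -> None:
        if not 0 < self.theta_max < 90:
            raise ValueError("theta_max must be in (0, 90) degrees")
        if not 0 < self.central_fraction <= 1:
            raise ValueError("central_fraction must be in (0, 1]")
        if not 0 < self.quarter_fraction <= 0.5:
            raise ValueError("quarter_fraction must be in (0, 0.5]")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")
        if self.mesh_format not in MESH_FORMATS:
            raise ValueError(f"mesh_format must be one of {MESH_FORMATS}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("off", "ply"):
        return suffix
    if suffix == "gii":
        return "gifti"
    if suffix in ("white", "pial", "inflated", "surf", "orig"):
        return "freesurfer"
    raise ValueError(f"cannot infer mesh format from {path.name!r}; "
                     "pass format explicitly")


def read_surface(path, side: str = "whole",
                 format: Optional[str] = None) -> TriMesh:
    """Read one hemisphere surface into a TriMesh (coordinates = RAS mm)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in MESH_FORMATS:
        raise ValueError(f"format must be one of {MESH_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt in ("off", "ply"):
            tm = _trimesh.load(path, file_type=fmt, process=False)
            vertices, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
        elif fmt == "gifti":
            import nibabel as nib
            img = nib.load(str(path))
            vertices = img.agg_data("pointset")
            faces = img.agg_data("triangle")
        else:  # freesurfer binary surface
            import nibabel.freesurfer as fs
            vertices, faces = fs.read_geometry(str(path))
    except Exception as exc:
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc
    faces = np.asarray(faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise ValueError(f"{path}: surface is not a triangle mesh "
                         f"(faces shape {faces.shape})")
    return TriMesh(np.asarray(vertices, dtype=float), faces, side=side)


def write_surface(mesh: TriMesh, path) -> Path:
    """Write a TriMesh as OFF or PLY (chosen by the file extension)."""
    path = Path(path)
    fmt = _infer_format(path)
    if fmt not in ("off", "ply"):
        raise ValueError("write_surface supports OFF and PLY only")
    tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    tm.export(path, file_type=fmt)
    return path


#: Stable column order of the measurement CSV.
RECORD_COLUMNS = [
    "subject_id", "species", "sex",
    "petalia_frontal", "petalia_occipital",
    "shift_frontal", "shift_occipital",
    "bending_frontal", "bending_occipital",
    "config_petalia", "config_shift", "config_bending",
    "tie_petalia", "tie_shift", "tie_bending",
    "left_length", "left_height", "left_width",
    "right_length", "right_height", "right_width",
    "whole_length", "whole_height", "whole_width",
    "delta_length", "delta_height", "delta_width",
    "length_width_ratio", "height_width_ratio",
]

_NUMERIC_COLUMNS = [c for c in RECORD_COLUMNS
                    if c not in ("subject_id", "species", "sex")
                    and not c.startswith(("config_", "tie_"))]


def record_to_row(record: TorqueRecord) -> dict:
    d = record.dimensions
    return {
        "subject_id": record.subject_id,
        "species": record.species,
        "sex": record.sex if record.sex is not None else "",
        "petalia_frontal": record.petalia_frontal,
        "petalia_occipital": record.petalia_occipital,
        "shift_frontal": record.shift_frontal,
        "shift_occipital": record.shift_occipital,
        "bending_frontal": record.bending_frontal,
        "bending_occipital": record.bending_occipital,
        "config_petalia": record.config_petalia.label,
        "config_shift": record.config_shift.label,
        "config_bending": record.config_bending.label,
        "tie_petalia": record.config_petalia.tie,
        "tie_shift": record.config_shift.tie,
        "tie_bending": record.config_bending.tie,
        "left_length": d.left_length, "left_height": d.left_height,
        "left_width": d.left_width,
        "right_length": d.right_length, "right_height": d.right_height,
        "right_width": d.right_width,
        "whole_length": d.whole_length, "whole_height": d.whole_height,
        "whole_width": d.whole_width,
        "delta_length": d.delta_length, "delta_height": d.delta_height,
        "delta_width": d.delta_width,
        "length_width_ratio": d.length_width_ratio,
        "height_width_ratio": d.height_width_ratio,
    }


def records_to_dataframe(records: Sequence[TorqueRecord]) -> pd.DataFrame:
    return pd.DataFrame([record_to_row(r) for r in records],
                        columns=RECORD_COLUMNS)


def write_records(records: Sequence[TorqueRecord], path,
                  config: Optional[PipelineConfig] = None) -> Path:
    """Write records as a rounded CSV plus a full-precision JSON sidecar.

    The sidecar (``<path>.json``) carries unrounded values, the pipeline
    configuration and the package version, so a report can always be
    traced back to the parameters that produced it.
    """
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    config = config or PipelineConfig()
    df = records_to_dataframe(records)
    rounded = df.copy()
    rounded[_NUMERIC_COLUMNS] = rounded[_NUMERIC_COLUMNS].round(config.rounding)
    rounded.to_csv(path, index=False)
    sidecar = {
        "version": __version__,
        "config": config.as_dict(),
        "records": df.to_dict(orient="records"),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, default=str))
    return path


def _row_to_record(row: pd.Series) -> TorqueRecord:
    dims = DimensionRecord(
        left_length=row["left_length"], left_height=row["left_height"],
        left_width=row["left_width"],
        right_length=row["right_length"], right_height=row["right_height"],
        right_width=row["right_width"],
        whole_length=row["whole_length"], whole_height=row["whole_height"],
        whole_width=row["whole_width"],
    )
    sex = row.get("sex", "")
    return TorqueRecord(
        subject_id=str(row["subject_id"]),
        species=str(row["species"]),
        sex=None if (pd.isna(sex) or sex == "") else str(sex),
        petalia_frontal=row["petalia_frontal"],
        petalia_occipital=row["petalia_occipital"],
        shift_frontal=row["shift_frontal"],
        shift_occipital=row["shift_occipital"],
        bending_frontal=row["bending_frontal"],
        bending_occipital=row["bending_occipital"],
        config_petalia=Configuration(row["config_petalia"], bool(row["tie_petalia"])),
        config_shift=Configuration(row["config_shift"], bool(row["tie_shift"])),
        config_bending=Configuration(row["config_bending"], bool(row["tie_bending"])),
        dimensions=dims,
    )


def read_records(path) -> list[TorqueRecord]:
    """Read a measurement CSV back into TorqueRecords.

    Prefers the JSON sidecar (full precision) when present.
    """
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        df = pd.DataFrame(data["records"])
    else:
        df = pd.read_csv(path)
    return [_row_to_record(row) for _, row in df.iterrows()]
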