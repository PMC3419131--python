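"""File formats: contour JSON, cohort CSV, velocity-series bundles, rules YAML.

Contour JSON (one file per patient)::

    {
      "patient_id": "P001",
      "slice_spacing_mm": 10.0,
      "n_slices": 10,
      "n_phases": 20,
      "contours": [
        {"structure": "RV_ENDO", "slice": 0, "phase": 0,
         "vertices": [[x, y], ...]},
        ...
      ],
      "landmarks": {                       # optional, per cine phase
        "ED": {"tricuspid_annulus": [x, y], "rv_apex": [x, y],
               "septal_mid": [x, y], "freewall_mid": [x, y],
               "rv_area_mm2": 2500.0,
               "d1_mm": 48.0, "d2_mm": 52.0},
        "ES": {...}
      }
    }

Velocity series live in a directory of plain-text grids:
``meta.yaml`` (pixel_area_cm2, rr_interval_s, bsa_m2, n_frames) plus
``frame_###_velocity.csv`` / ``frame_###_mask.csv`` per cardiac frame.

The cohort table is a flat CSV, one row per patient; metric columns carry
empty cells where a sub-study did not cover the patient.
"""

from __future__ import annotations

import json
import math
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .flow import VelocityFrameSeries
from .functional import CinePhase, FourChamberFrame, MidSliceDiameters
from .geometry import ContourStack, SliceContour, Structure
from .stats import Direction, Group, PatientRecord, Subgroup, ThresholdRule

NON_METRIC_COLUMNS = (
    "patient_id", "group", "subgroup", "mpap", "pvr", "bsa", "lge_present", "non_diagnostic",
)


# ------------------------------------------------------------- contour JSON


def read_contour_stack(path) -> ContourStack:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("patient_id", "slice_spacing_mm", "n_slices", "n_phases", "contours"):
        if key not in doc:
            raise ValidationError(f"{path}: missing required field {key!r}")
    contours = []
    for i, c in enumerate(doc["contours"]):
        try:
            contours.append(
                SliceContour(
                    structure=Structure(c["structure"]),
                    slice_index=int(c["slice"]),
                    phase_index=int(c["phase"]),
                    vertices=tuple((float(x), float(y)) for x, y in c["vertices"]),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: contours[{i}]: {exc}") from exc
    return ContourStack(
        patient_id=str(doc["patient_id"]),
        slice_spacing=float(doc["slice_spacing_mm"]),
        n_slices=int(doc["n_slices"]),
        n_phases=int(doc["n_phases"]),
        contours=contours,
    )


def write_contour_stack(stack: ContourStack, path, landmarks: dict | None = None) -> None:
    doc = {
        "patient_id": stack.patient_id,
        "slice_spacing_mm": stack.slice_spacing,
        "n_slices": stack.n_slices,
        "n_phases": stack.n_phases,
        "contours": [
            {
                "structure": c.structure.value,
                "slice": c.slice_index,
                "phase": c.phase_index,
                "vertices": [[x, y] for x, y in c.vertices],
            }
            for c in stack.contours
        ],
    }
    if landmarks:
        doc["landmarks"] = landmarks
    Path(path).write_text(json.dumps(doc))


def read_landmarks(path) -> dict[CinePhase, tuple[FourChamberFrame, MidSliceDiameters]]:
    """Load the per-phase landmark block of a contour JSON file."""
    path = Path(path)
    doc = json.loads(path.read_text())
    if "landmarks" not in doc:
        raise ValidationError(f"{path}: no 'landmarks' block")
    out = {}
    for phase_name, lm in doc["landmarks"].items():
        phase = CinePhase(phase_name)
        try:
            frame = FourChamberFrame(
                phase=phase,
                tricuspid_annulus=tuple(lm["tricuspid_annulus"]),
                rv_apex=tuple(lm["rv_apex"]),
                septal_mid=tuple(lm["septal_mid"]),
                freewall_mid=tuple(lm["freewall_mid"]),
                rv_area=float(lm["rv_area_mm2"]),
            )
            diam = MidSliceDiameters(phase=phase, d1=float(lm["d1_mm"]), d2=float(lm["d2_mm"]))
        except (KeyError, ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: landmarks[{phase_name}]: {exc}") from exc
        out[phase] = (frame, diam)
    return out


# --------------------------------------------------------- velocity bundles


def write_velocity_series(series: VelocityFrameSeries, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "pixel_area_cm2": series.pixel_area,
        "rr_interval_s": series.rr_interval,
        "bsa_m2": series.bsa,
        "n_frames": series.n_frames,
    }
    (directory / "meta.yaml").write_text(yaml.safe_dump(meta))
    for i, (vel, mask) in enumerate(series.frames):
        np.savetxt(directory / f"frame_{i:03d}_velocity.csv", vel, delimiter=",")
        np.savetxt(directory / f"frame_{i:03d}_mask.csv", mask.astype(int), delimiter=",", fmt="%d")


def read_velocity_series(directory) -> VelocityFrameSeries:
    directory = Path(directory)
    meta_path = directory / "meta.yaml"
    if not meta_path.exists():
        raise ValidationError(f"{directory}: missing meta.yaml")
    meta = yaml.safe_load(meta_path.read_text())
    frames = []
    for i in range(int(meta["n_frames"])):
        vpath = directory / f"frame_{i:03d}_velocity.csv"
        mpath = directory / f"frame_{i:03d}_mask.csv"
        if not vpath.exists() or not mpath.exists():
            raise ValidationError(f"{directory}: missing grids for frame {i}")
        vel = np.loadtxt(vpath, delimiter=",")
        mask = np.loadtxt(mpath, delimiter=",").astype(bool)
        frames.append((vel, mask))
    return VelocityFrameSeries(
        frames=frames,
        pixel_area=float(meta["pixel_area_cm2"]),
        rr_interval=float(meta["rr_interval_s"]),
        bsa=float(meta["bsa_m2"]),
    )


# --------------------------------------------------------------- cohort CSV


def cohort_to_dataframe(records: list[PatientRecord]) -> pd.DataFrame:
    metric_names = sorted({m for r in records for m in r.metrics})
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "group": r.group.value,
            "subgroup": r.subgroup.value,
            "mpap": r.mpap,
            "pvr": r.pvr,
            "bsa": r.bsa,
            "lge_present": r.lge_present,
            "non_diagnostic": r.non_diagnostic,
        }
        for m in metric_names:
            row[m] = r.metrics.get(m, math.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(NON_METRIC_COLUMNS) + metric_names)


def dataframe_to_cohort(df: pd.DataFrame, source: str = "<dataframe>") -> list[PatientRecord]:
    for col in ("patient_id", "group", "mpap"):
        if col not in df.columns:
            raise ValidationError(f"{source}: missing required column {col!r}")
    metric_cols = [c for c in df.columns if c not in NON_METRIC_COLUMNS]
    records = []
    for i, row in df.iterrows():
        try:
            lge = row.get("lge_present")
            if lge is None or (isinstance(lge, float) and math.isnan(lge)) or pd.isna(lge):
                lge = None
            else:
                lge = bool(lge)
            pvr = row.get("pvr")
            bsa = row.get("bsa")
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    group=Group(row["group"]),
                    subgroup=Subgroup(row["subgroup"]) if "subgroup" in df.columns and pd.notna(row.get("subgroup")) else Subgroup.NONE,
                    mpap=float(row["mpap"]),
                    pvr=None if pvr is None or pd.isna(pvr) else float(pvr),
                    bsa=None if bsa is None or pd.isna(bsa) else float(bsa),
                    metrics={
                        m: float(row[m]) for m in metric_cols if pd.notna(row[m])
                    },
                    lge_present=lge,
                    non_diagnostic=bool(row.get("non_diagnostic", False))
                    if pd.notna(row.get("non_diagnostic", False)) else False,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{source}: row {i} (patient {row.get('patient_id')}): {exc}") from exc
    return records


def write_cohort_csv(records: list[PatientRecord], path) -> None:
    cohort_to_dataframe(records).to_csv(path, index=False, lineterminator="\n")


def read_cohort_csv(path) -> list[PatientRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: cohort table is empty")
    return dataframe_to_cohort(df, source=str(path))


# ---------------------------------------------------------------- rules YAML


def read_rules(path) -> list[ThresholdRule]:
    doc = yaml.safe_load(Path(path).read_text())
    rules = []
    for i, r in enumerate(doc.get("rules", [])):
        try:
            rules.append(
                ThresholdRule(
                    metric_name=str(r["metric"]),
                    cutpoint=float(r["cutpoint"]),
                    direction=Direction(r["direction"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValidationError(f"{path}: rules[{i}]: {exc}") from exc
    return rules
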