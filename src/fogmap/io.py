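"""Readers and writers for the standard formats.

Images travel as NIfTI-1 with full affines (nibabel), streamlines as TRK
(nibabel.streamlines), cohorts as CSV with a documented column set, ground
truth and run configuration as YAML, and every pipeline stage emits a JSON
provenance record (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .images import Image3D
from .lead_vta import LeadModel, LeadSpec, StimulationSetting, build_lead
from .synth import SIDES, GroundTruth, PatientRecord, StreamlineSet


# ---------------------------------------------------------------------------
# images

def write_image(img: Image3D, path) -> None:
    data = img.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, img.affine), str(path))


def read_image(path) -> Image3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        nii = nib.load(str(path))
        return Image3D(np.asarray(nii.dataobj), nii.affine)
    except Exception as exc:  # garbled header etc.
        raise IOError(f"cannot read NIfTI image {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# streamlines

def write_streamlines(sset: StreamlineSet, path, grid: Image3D | None = None) -> None:
    """Save as TRK; coordinates are world mm (RAS)."""
    affine = grid.affine if grid is not None else np.eye(4)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in sset.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    header = {}
    if grid is not None:
        header[nib.streamlines.trk.Field.VOXEL_SIZES] = tuple(grid.spacing)
        header[nib.streamlines.trk.Field.DIMENSIONS] = tuple(grid.data.shape[:3])
        header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = affine.astype(np.float32)
    nib.streamlines.save(tractogram, str(path), header=header)


def read_streamlines(path) -> StreamlineSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"streamline file not found: {path}")
    trk = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s) for s in trk.tractogram.streamlines]
    if not streamlines:
        warnings.warn(f"empty streamline file: {path}")
    return StreamlineSet(streamlines)


# ---------------------------------------------------------------------------
# cohort CSV

def write_cohort(cohort: list[PatientRecord], path) -> None:
    from .synth import cohort_to_frame

    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort(path, lead_spec: LeadSpec = LeadSpec()) -> list[PatientRecord]:
    """Load a cohort CSV, recomputing %change and groups on the fly.

    Rows violating the preconditions (pre-operative FOG-Q < 1, missing
    lead columns) are reported with their row number.  Missing covariate
    cells are tolerated (NaN) and only excluded from covariate-adjusted
    analyses.
    """
    df = pd.read_csv(path)
    records = []
    errors = []
    for i, row in df.iterrows():
        try:
            leads, settings = {}, {}
            for side in SIDES:
                p = "r" if side == "right" else "l"
                tip = (row[f"{p}_tip_x"], row[f"{p}_tip_y"], row[f"{p}_tip_z"])
                direction = (row[f"{p}_dir_x"], row[f"{p}_dir_y"], row[f"{p}_dir_z"])
                leads[side] = build_lead(
                    tip, direction, lead_spec, hemisphere=side,
                    active_contact=int(row[f"{p}_active_contact"]),
                )
                settings[side] = StimulationSetting(
                    amplitude=float(row[f"{p}_amplitude"]),
                    pulse_width=float(row[f"{p}_pulse_width"]),
                    frequency=float(row[f"{p}_frequency"]),
                )
            post = row.get("post_fogq")
            records.append(
                PatientRecord(
                    id=str(row["id"]),
                    pre_fogq=int(row["pre_fogq"]),
                    post_fogq=None if pd.isna(post) else int(post),
                    sex=str(row["sex"]),
                    disease_duration=float(row.get("disease_duration", np.nan)),
                    pre_moca=float(row.get("pre_moca", np.nan)),
                    pre_hama=float(row.get("pre_hama", np.nan)),
                    pre_hamd=float(row.get("pre_hamd", np.nan)),
                    ledd_reduction=float(row.get("ledd_reduction", np.nan)),
                    updrs3_percent_change=float(row.get("updrs3_percent_change", np.nan)),
                    leads=leads,
                    settings=settings,
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError("invalid cohort rows:\n" + "\n".join(errors))
    return records


def complete_covariate_mask(cohort: list[PatientRecord]) -> np.ndarray:
    """True for patients whose adjustment covariates are all present."""
    from .synth import covariate_table

    return covariate_table(cohort).notna().all(axis=1).to_numpy()


# ---------------------------------------------------------------------------
# YAML sidecars

def write_lead_yaml(lead: LeadModel, path) -> None:
    doc = {
        "hemisphere": lead.hemisphere,
        "contact_centres": np.asarray(lead.contact_centres).tolist(),
        "trajectory_direction": np.asarray(lead.trajectory_direction).tolist(),
        "contact_length": float(lead.contact_length),
        "contact_spacing": float(lead.contact_spacing),
        "contact_radius": float(lead.contact_radius),
        "active_contact_index": int(lead.active_contact_index),
    }
    Path(path).write_text(yaml.safe_dump(doc))


def read_lead_yaml(path) -> LeadModel:
    doc = yaml.safe_load(Path(path).read_text())
    return LeadModel(
        hemisphere=doc["hemisphere"],
        contact_centres=np.asarray(doc["contact_centres"], dtype=float),
        trajectory_direction=np.asarray(doc["trajectory_direction"], dtype=float),
        contact_length=doc["contact_length"],
        contact_spacing=doc["contact_spacing"],
        contact_radius=doc["contact_radius"],
        active_contact_index=doc["active_contact_index"],
    )


def write_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(truth)))


def read_truth(path) -> GroundTruth:
    doc = yaml.safe_load(Path(path).read_text())
    for key in ("sweet_centre_right", "sweet_centre_left",
                "sour_centre_right", "sour_centre_left"):
        doc[key] = tuple(doc[key])
    return GroundTruth(**doc)


def write_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict()))


def read_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# provenance

def config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_provenance(config: RunConfig, stage: str, path, extra: dict | None = None) -> None:
    doc = {
        "stage": stage,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "fogmap_version": __version__,
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
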