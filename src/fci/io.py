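"""File formats: NIfTI image stacks with JSON sidecars, CSV profile tables.

An image set is stored as a single 3-D NIfTI volume (x, y, volume-index)
plus a ``<stem>.json`` sidecar listing, per volume, the evolution field (mT)
and evolution time (ms), together with the full protocol constants.  Label
maps are integer NIfTI volumes; ground truth and manifests are JSON;
dispersion profiles travel as tidy CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from fci.phantom import FciImageSet, TissueDispersionTruth, TissueLabel
from fci.protocol import AcquisitionProtocol
from fci.dispersion import NmrdProfile

__all__ = [
    "save_image_set",
    "load_image_set",
    "save_label_map",
    "load_label_map",
    "save_truths",
    "profiles_to_csv",
    "profiles_from_csv",
]

PROFILE_COLUMNS = ["subject_id", "roi_role", "field_mT", "r1_per_s", "r1_stderr_per_s"]


def save_image_set(images: FciImageSet, path: str | Path) -> Path:
    """Write an image set as ``<path>.nii`` + ``<path>.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    grid = list(images.protocol.grid())
    data = np.stack([images.volumes[key] for key in grid], axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path.with_suffix(".nii")))
    sidecar = {
        "volumes": [
            {"index": i, "evolution_field_mT": f, "evolution_time_ms": t}
            for i, (f, t) in enumerate(grid)
        ],
        "protocol": images.protocol.to_dict(),
        "provenance": images.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    if images.label_map is not None:
        save_label_map(images.label_map, path.with_name(path.stem + "_labels"))
    return path.with_suffix(".nii")


def load_image_set(path: str | Path) -> FciImageSet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    protocol = AcquisitionProtocol.from_dict(sidecar["protocol"])
    data = np.asarray(nib.load(str(path.with_suffix(".nii"))).dataobj, dtype=float)
    volumes = {}
    for entry in sidecar["volumes"]:
        key = (float(entry["evolution_field_mT"]), float(entry["evolution_time_ms"]))
        volumes[key] = data[..., int(entry["index"])]
    label_path = path.with_name(path.stem + "_labels").with_suffix(".nii")
    label_map = load_label_map(label_path) if label_path.exists() else None
    return FciImageSet(
        volumes=volumes,
        protocol=protocol,
        label_map=label_map,
        provenance=sidecar.get("provenance", ""),
    )


def save_label_map(label_map: np.ndarray, path: str | Path) -> Path:
    path = Path(path).with_suffix(".nii")
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(label_map, dtype=np.int16), affine=np.eye(4)), str(path))
    return path


def load_label_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.int32)


def save_truths(truths: dict[TissueLabel, TissueDispersionTruth], path: str | Path) -> Path:
    path = Path(path).with_suffix(".json")
    payload = {
        str(int(label)): {
            "tissue_label": label.name,
            "alpha": t.alpha,
            "beta": t.beta,
            "qp_amplitude": t.qp_amplitude,
            "qp_center_mT": t.qp_center_mT,
            "qp_width_mT": t.qp_width_mT,
            "proton_density_scale": t.proton_density_scale,
        }
        for label, t in truths.items()
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def profiles_to_csv(profiles: Sequence[NmrdProfile], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "subject_id": p.subject_id,
            "roi_role": p.roi_role,
            "field_mT": f,
            "r1_per_s": r1,
            "r1_stderr_per_s": err,
        }
        for p in profiles
        for f, r1, err in p.points
    ]
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)
    return path


def profiles_from_csv(path: str | Path) -> list[NmrdProfile]:
    df = pd.read_csv(path)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns {sorted(missing)}")
    profiles = []
    for (subject, role), sub in df.groupby(["subject_id", "roi_role"], dropna=False):
        points = tuple(
            (row.field_mT, row.r1_per_s, row.r1_stderr_per_s) for row in sub.itertuples()
        )
        profiles.append(
            NmrdProfile(points=points, roi_role=str(role), subject_id=str(subject))
        )
    return profiles
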