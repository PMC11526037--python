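"""End-to-end orchestration: simulate -> fit -> dispersion -> metrics -> stats.

Each stage reads the previous stage's files from the run directory, so a run
can be split across invocations; a manifest records the seed, a hash of the
configuration and every per-stage output, and reruns with the same config
and seed are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

import fci
from fci import io as fci_io
from fci.dispersion import build_profile, profile_biomarkers
from fci.metrics import cohort_metrics_summary, metrics_table
from fci.phantom import FciImageSet, PhantomSpec, TissueLabel, make_cohort, simulate_acquisition
from fci.protocol import AcquisitionProtocol, default_protocol
from fci.relaxometry import RoiSet, fit_roi_r1, t1_map
from fci.stats import biomarker_report

log = logging.getLogger("fci.pipeline")

STAGES = ("sim", "fit", "dispersion", "metrics", "stats")

#: ROI roles for which dispersion profiles are extracted.
PROFILE_ROLES = ("tumour", "glandular", "adipose")


@dataclass
class RunConfig:
    """Configuration of an end-to-end run."""

    seed: int = 0
    output_dir: Path = Path("fci_run")
    stages: tuple[str, ...] = STAGES
    n_invasive: int = 4
    n_noninvasive: int = 6
    variability: float = 0.15
    shape: tuple[int, int] = (32, 64)
    noise_sigma: float | None = None
    protocol: AcquisitionProtocol | None = None

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        # stages must be executable in pipeline order
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise ValueError("stages must follow the sim->fit->dispersion/metrics->stats order")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = raw.pop("cohort", {})
        protocol = raw.pop("protocol", None)
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "fci_run")),
            stages=tuple(raw.get("stages", STAGES)),
            n_invasive=int(cohort.get("n_invasive", 4)),
            n_noninvasive=int(cohort.get("n_noninvasive", 6)),
            variability=float(cohort.get("variability", 0.15)),
            shape=tuple(cohort.get("shape", (32, 64))),
            noise_sigma=cohort.get("noise_sigma"),
            protocol=AcquisitionProtocol.from_dict(protocol) if protocol else None,
        )
        return cfg

    def canonical(self) -> dict:
        return {
            "seed": self.seed,
            "stages": list(self.stages),
            "cohort": {
                "n_invasive": self.n_invasive,
                "n_noninvasive": self.n_noninvasive,
                "variability": self.variability,
                "shape": list(self.shape),
                "noise_sigma": self.noise_sigma,
            },
            "protocol": self.protocol.to_dict() if self.protocol else None,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path}, which is produced by stage '{produced_by}'; "
            f"run '{produced_by}' first"
        )
    return path


def _subject_ids(sim_dir: Path) -> list[str]:
    cohort = json.loads((sim_dir / "cohort.json").read_text())
    return [s["subject_id"] for s in cohort["subjects"]]


def run_sim(config: RunConfig) -> list[Path]:
    """Generate the cohort phantoms and simulate every acquisition."""
    sim_dir = config.output_dir / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    kwargs: dict[str, Any] = dict(
        n_invasive=config.n_invasive,
        n_noninvasive=config.n_noninvasive,
        variability=config.variability,
        rng_seed=config.seed,
        shape=config.shape,
    )
    if config.noise_sigma is not None:
        kwargs["noise_sigma"] = config.noise_sigma
    cohort = make_cohort(**kwargs)
    outputs = []
    subjects_meta = []
    for spec in cohort:
        images = simulate_acquisition(spec, config.protocol)
        outputs.append(fci_io.save_image_set(images, sim_dir / spec.subject_id))
        fci_io.save_truths(spec.tissue_truths, sim_dir / f"{spec.subject_id}_truth")
        subjects_meta.append(
            {
                "subject_id": spec.subject_id,
                "invasive": spec.tumour_label == TissueLabel.tumour_invasive,
                "rng_seed": spec.rng_seed,
                "noise_sigma": spec.noise_sigma,
            }
        )
    (sim_dir / "cohort.json").write_text(json.dumps({"subjects": subjects_meta}, indent=2))
    log.info("sim: wrote %d subjects to %s", len(cohort), sim_dir)
    return outputs


def run_fit(config: RunConfig) -> dict[str, Path]:
    """ROI-level relaxation fits (NMRD profiles) and voxelwise T1 maps."""
    sim_dir = config.output_dir / "sim"
    _require(sim_dir / "cohort.json", "fit", "sim")
    fit_dir = config.output_dir / "fit"
    fit_dir.mkdir(parents=True, exist_ok=True)
    profiles = []
    n_nonconverged = 0
    for subject in _subject_ids(sim_dir):
        images = fci_io.load_image_set(sim_dir / subject)
        rois = RoiSet.from_label_map(images.label_map)
        for role in PROFILE_ROLES:
            if not rois[role].any():
                continue
            fits = {}
            for f in images.protocol.evolution_fields_mT:
                fit = fit_roi_r1(images, rois[role], f)
                if not fit.converged:
                    n_nonconverged += 1
                fits[f] = fit
            profiles.append(build_profile(fits, roi_role=role, subject_id=subject))
        # voxelwise maps only where the contrast metrics need them
        contrast_mask = rois["tumour"] | rois["adjacent_healthy"]
        maps = {}
        for f in images.protocol.evolution_fields_mT:
            t1_img, err_img = t1_map(images, f, mask=contrast_mask)
            maps[f] = (t1_img, err_img)
        data = np.stack(
            [np.stack([maps[f][0], maps[f][1]], axis=-1) for f in images.protocol.evolution_fields_mT],
            axis=-1,
        )
        np.save(fit_dir / f"{subject}_t1maps.npy", data)
        (fit_dir / f"{subject}_t1maps.json").write_text(
            json.dumps({"fields_mT": list(images.protocol.evolution_fields_mT)})
        )
    if n_nonconverged:
        log.warning("fit: %d ROI fits did not converge", n_nonconverged)
    out = fit_dir / "profiles.csv"
    fci_io.profiles_to_csv(profiles, out)
    return {"profiles": out}


def _load_t1_maps(fit_dir: Path, subject: str) -> dict[float, np.ndarray]:
    meta = json.loads((fit_dir / f"{subject}_t1maps.json").read_text())
    data = np.load(fit_dir / f"{subject}_t1maps.npy")
    return {f: data[..., 0, i] for i, f in enumerate(meta["fields_mT"])}


def run_dispersion(config: RunConfig) -> dict[str, Path]:
    """Fit power laws and QP amplitudes for every profile; tidy biomarker CSV."""
    fit_dir = config.output_dir / "fit"
    _require(fit_dir / "profiles.csv", "dispersion", "fit")
    disp_dir = config.output_dir / "dispersion"
    disp_dir.mkdir(parents=True, exist_ok=True)
    profiles = fci_io.profiles_from_csv(fit_dir / "profiles.csv")
    rows = []
    for p in profiles:
        for biomarker, value in profile_biomarkers(p).items():
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "roi_role": p.roi_role,
                    "biomarker": biomarker,
                    "value": value,
                }
            )
    out = disp_dir / "biomarkers.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return {"biomarkers": out}


def run_metrics(config: RunConfig) -> dict[str, Path]:
    """Per-subject SNR/CNR/deltaT1%% rows and the cohort summary table."""
    sim_dir = config.output_dir / "sim"
    fit_dir = config.output_dir / "fit"
    _require(sim_dir / "cohort.json", "metrics", "sim")
    metrics_dir = config.output_dir / "metrics"
    metrics_dir.mkdir(parents=True, exist_ok=True)
    per_subject = []
    records = []
    for subject in _subject_ids(sim_dir):
        _require(fit_dir / f"{subject}_t1maps.npy", "metrics", "fit")
        images = fci_io.load_image_set(sim_dir / subject)
        rois = RoiSet.from_label_map(images.label_map)
        t1_maps = _load_t1_maps(fit_dir, subject)
        rows = metrics_table(images, t1_maps, rois)
        per_subject.append(rows)
        for row in rows:
            records.append(
                {
                    "subject_id": subject,
                    "field_mT": row.field,
                    "SNR": row.snr,
                    "CNR": row.cnr,
                    "pct_delta_t1": row.delta_t1_percent,
                    "evolution_time_ms": row.evolution_time_used,
                }
            )
    out = metrics_dir / "metrics.csv"
    pd.DataFrame(records).to_csv(out, index=False)
    summary = cohort_metrics_summary(per_subject)
    summary_out = metrics_dir / "metrics_summary.csv"
    summary.to_csv(summary_out, index=False)
    return {"metrics": out, "summary": summary_out}


def run_stats(config: RunConfig) -> dict[str, Path]:
    """Group comparisons on the dispersion biomarkers."""
    disp_dir = config.output_dir / "dispersion"
    sim_dir = config.output_dir / "sim"
    _require(disp_dir / "biomarkers.csv", "stats", "dispersion")
    _require(sim_dir / "cohort.json", "stats", "sim")
    stats_dir = config.output_dir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    biomarkers = pd.read_csv(disp_dir / "biomarkers.csv")
    cohort = json.loads((sim_dir / "cohort.json").read_text())
    grouping = {s["subject_id"]: bool(s["invasive"]) for s in cohort["subjects"]}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = biomarker_report(biomarkers, invasive_by_subject=grouping)
    out = stats_dir / "report.csv"
    report.to_csv(out, index=False)
    (stats_dir / "report.json").write_text(report.to_json(orient="records", indent=2))
    return {"report": out}


_STAGE_RUNNERS = {
    "sim": run_sim,
    "fit": run_fit,
    "dispersion": run_dispersion,
    "metrics": run_metrics,
    "stats": run_stats,
}


def run(config: RunConfig) -> dict:
    """Execute the requested stages in order and write the run manifest."""
    config.output_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "fci_version": fci.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.canonical(),
        "stages": {},
    }
    for stage in config.stages:
        result = _STAGE_RUNNERS[stage](config)
        if isinstance(result, dict):
            manifest["stages"][stage] = {k: str(v) for k, v in result.items()}
        else:
            manifest["stages"][stage] = [str(p) for p in result]
    (config.output_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def validate_inputs(paths: Sequence[str | Path]) -> list[dict]:
    """Check volume/sidecar consistency, ROI disjointness and CSV schemas.

    Returns a machine-readable issue list; never raises unless a file is
    unreadable in a way that prevents any check.
    """
    issues: list[dict] = []
    for raw in paths:
        path = Path(raw)
        if not path.exists():
            issues.append({"path": str(path), "issue": "missing file"})
            continue
        if path.suffix == ".json" and path.with_suffix(".nii").exists():
            issues.extend(_validate_image_pair(path))
        elif path.suffix == ".nii":
            if not path.with_suffix(".json").exists():
                if "labels" in path.stem or "t1map" in path.stem:
                    continue
                issues.append({"path": str(path), "issue": "no JSON sidecar"})
            else:
                issues.extend(_validate_image_pair(path.with_suffix(".json")))
        elif path.suffix == ".csv":
            issues.extend(_validate_csv(path))
    return issues


def _validate_image_pair(sidecar_path: Path) -> list[dict]:
    import nibabel as nib

    issues = []
    try:
        sidecar = json.loads(sidecar_path.read_text())
        protocol = AcquisitionProtocol.from_dict(sidecar["protocol"])
        listed = {(v["evolution_field_mT"], v["evolution_time_ms"]) for v in sidecar["volumes"]}
        grid = set(protocol.grid())
        if listed != grid:
            issues.append(
                {
                    "path": str(sidecar_path),
                    "issue": "sidecar volume list does not match the protocol grid",
                    "missing": sorted(grid - listed),
                    "extra": sorted(listed - grid),
                }
            )
        data = nib.load(str(sidecar_path.with_suffix(".nii")))
        if data.shape[-1] != len(sidecar["volumes"]):
            issues.append(
                {"path": str(sidecar_path), "issue": "volume count differs from sidecar"}
            )
        label_path = sidecar_path.with_name(sidecar_path.stem + "_labels.nii")
        if label_path.exists():
            lm = fci_io.load_label_map(label_path)
            try:
                RoiSet.from_label_map(lm)
            except ValueError as exc:
                issues.append({"path": str(label_path), "issue": f"bad ROI set: {exc}"})
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        issues.append({"path": str(sidecar_path), "issue": f"unreadable sidecar: {exc}"})
    return issues


def _validate_csv(path: Path) -> list[dict]:
    issues = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # unreadable CSV is an issue, not a crash
        return [{"path": str(path), "issue": f"unreadable CSV: {exc}"}]
    if "r1_per_s" in df.columns:
        missing = set(fci_io.PROFILE_COLUMNS) - set(df.columns)
        if missing:
            issues.append({"path": str(path), "issue": f"missing columns {sorted(missing)}"})
        elif (df["r1_per_s"] <= 0).any():
            issues.append({"path": str(path), "issue": "non-positive r1 values"})
    elif "biomarker" in df.columns:
        missing = {"subject_id", "roi_role", "biomarker", "value"} - set(df.columns)
        if missing:
            issues.append({"path": str(path), "issue": f"missing columns {sorted(missing)}"})
    return issues
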