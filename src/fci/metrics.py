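"""Image-quality and contrast metrics: SNR, CNR and the T1 contrast ratio.

SNR and CNR are read off the magnitude image acquired at the longest
evolution time of each field.  The 0.66 Rayleigh correction factor accounts
for the mean of the background magnitude-noise distribution; it multiplies
the signal in the SNR and divides the noise in the CNR — the two placements
are deliberately kept exactly as conventionally printed, not harmonised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MetricsRow", "snr", "cnr", "delta_t1_percent", "metrics_table", "SNR_CAP"]

RAYLEIGH_FACTOR = 0.66

#: Sentinel cap reported for SNR/CNR on noiseless images (zero background).
SNR_CAP = 1e6


@dataclass(frozen=True)
class MetricsRow:
    field: float
    snr: float
    cnr: float
    delta_t1_percent: float
    evolution_time_used: float

    def __post_init__(self) -> None:
        if self.snr < 0 or self.cnr < 0:
            raise ValueError("snr and cnr must be non-negative")
        if not -200.0 < self.delta_t1_percent < 200.0:
            raise ValueError("delta_t1_percent out of (-200, 200)")


def _longest_time_image(images, field_mT: float) -> tuple[np.ndarray, float]:
    t = images.protocol.longest_time(field_mT)
    return images.volume(field_mT, t), t


def _mean(img: np.ndarray, mask: np.ndarray, name: str) -> float:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"{name} ROI is empty")
    return float(img[mask].mean())


def snr(images, rois, field_mT: float) -> float:
    """SNR = 0.66 * mean(healthy-tissue ROI) / mean(background ROI).

    Measured on the magnitude image at the longest evolution time of the
    field.  The healthy-tissue ROI is the glandular mask when present (the
    contralateral-breast convention), else the adjacent-healthy ROI.  A zero
    background mean (noiseless images) is reported as the ``SNR_CAP``
    sentinel with a warning.
    """
    img, _ = _longest_time_image(images, field_mT)
    role = "glandular" if "glandular" in rois else "adjacent_healthy"
    s_sig = _mean(img, rois[role], role)
    s_noise = _mean(img, rois["background"], "background")
    if s_noise == 0:
        warnings.warn("zero background mean: noiseless images, SNR capped")
        return SNR_CAP
    return RAYLEIGH_FACTOR * s_sig / s_noise


def cnr(images, rois, field_mT: float) -> float:
    """CNR = |mean(tumour) - mean(adjacent healthy)| / (mean(background) * 0.66)."""
    img, _ = _longest_time_image(images, field_mT)
    s_t = _mean(img, rois["tumour"], "tumour")
    s_h = _mean(img, rois["adjacent_healthy"], "adjacent_healthy")
    s_n = _mean(img, rois["background"], "background")
    if s_n == 0:
        warnings.warn("zero background mean: noiseless images, CNR capped")
        return SNR_CAP
    return abs(s_t - s_h) / (s_n * RAYLEIGH_FACTOR)


def delta_t1_percent(t1_img: np.ndarray, rois) -> float:
    """Tumour-to-background T1 contrast, percent of the average T1.

    100 * (T1_T - T1_H) / ((T1_T + T1_H) / 2) with ROI means taken over the
    voxelwise T1 map (NaN no-data voxels ignored).  Antisymmetric in the two
    ROIs and bounded in (-200, 200) for positive means.
    """
    t1_img = np.asarray(t1_img, dtype=float)

    def roi_mean_t1(role: str) -> float:
        mask = np.asarray(rois[role], dtype=bool)
        if not mask.any():
            raise ValueError(f"{role} ROI is empty")
        vals = t1_img[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"no fitted voxels in {role} ROI")
        return float(vals.mean())

    t1_t = roi_mean_t1("tumour")
    t1_h = roi_mean_t1("adjacent_healthy")
    if t1_t <= 0 or t1_h <= 0:
        raise ValueError("non-positive mean T1")
    return 100.0 * (t1_t - t1_h) / ((t1_t + t1_h) / 2.0)


def metrics_table(images, t1_maps: dict[float, np.ndarray], rois) -> list[MetricsRow]:
    """One MetricsRow (SNR, CNR, deltaT1%) per evolution field."""
    rows = []
    for f in images.protocol.evolution_fields_mT:
        if f not in t1_maps:
            raise ValueError(f"missing T1 map for field {f} mT")
        rows.append(
            MetricsRow(
                field=f,
                snr=snr(images, rois, f),
                cnr=cnr(images, rois, f),
                delta_t1_percent=delta_t1_percent(t1_maps[f], rois),
                evolution_time_used=images.protocol.longest_time(f),
            )
        )
    return rows


def cohort_metrics_summary(per_subject_rows: list[list[MetricsRow]]) -> pd.DataFrame:
    """Median and min-max range of each metric per field across subjects."""
    records = []
    for subject_rows in per_subject_rows:
        for row in subject_rows:
            records.append(
                {
                    "field_mT": row.field,
                    "SNR": row.snr,
                    "CNR": row.cnr,
                    "pct_delta_t1": row.delta_t1_percent,
                }
            )
    df = pd.DataFrame(records)
    out = df.groupby("field_mT").agg(["median", "min", "max"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
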