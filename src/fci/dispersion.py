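"""NMRD dispersion profiles: power-law fits and quadrupolar-peak amplitude.

An NMRD profile is the table of R1 = 1/T1 against evolution field.  The
dispersion model is the power law R1(B) = alpha * B^(-beta): log-log linear,
with alpha the R1 level at 1 mT and beta the (positive-down) slope.  The
quadrupolar peak amplitude at 65.8 mT is the excess of the measured R1 over
a baseline interpolated between the flanking fields; interpolation is linear
in (ln B, ln R1), which makes the estimate exactly zero under the power-law
model itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fci.relaxometry import RelaxationFit

__all__ = [
    "NmrdProfile",
    "DispersionFit",
    "QpEstimate",
    "build_profile",
    "fit_power_law",
    "qp_amplitude",
    "global_beta",
    "summarize_cohort",
    "QP_FIELD_MT",
    "BETA_SPLIT_MT",
]

QP_FIELD_MT = 65.8
#: Field separating the low-field (beta_L) and high-field (beta_H) fits.
BETA_SPLIT_MT = 22.0


@dataclass(frozen=True)
class NmrdProfile:
    """Per-ROI dispersion profile: (field mT, R1 s^-1, R1 stderr s^-1)."""

    points: tuple[tuple[float, float, float], ...]
    roi_role: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        pts = tuple(sorted((float(f), float(r), float(e)) for f, r, e in self.points))
        fields = [p[0] for p in pts]
        if any(f <= 0 for f in fields):
            raise ValueError("fields must be positive")
        if len(set(fields)) != len(fields):
            raise ValueError("duplicate fields in profile")
        if any(p[1] <= 0 for p in pts):
            raise ValueError("r1 values must be positive")
        object.__setattr__(self, "points", pts)

    @property
    def fields(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.points)

    def r1(self, field_mT: float) -> float:
        for f, r, _ in self.points:
            if f == field_mT:
                return r
        raise KeyError(f"field {field_mT} mT not in profile")


@dataclass(frozen=True)
class DispersionFit:
    """Power-law fit: R1 = alpha * B^(-beta) over ``fields_used``."""

    alpha: float
    beta: float
    fields_used: tuple[float, ...]
    fit_stderr: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if len(self.fields_used) < 2:
            raise ValueError("need >= 2 fields")


@dataclass(frozen=True)
class QpEstimate:
    """Quadrupolar-peak amplitude: R1 at the peak minus interpolated baseline."""

    amplitude: float
    baseline_r1: float
    peak_field: float = QP_FIELD_MT


def build_profile(
    fits: Mapping[float, RelaxationFit], roi_role: str = "", subject_id: str = ""
) -> NmrdProfile:
    """Assemble an NMRD profile from per-field ROI relaxation fits.

    r1 = 1000/t1 (t1 in ms) and the stderr is propagated by the delta
    method: r1_stderr = t1_stderr * 1000 / t1^2.
    """
    if len(fits) < 2:
        raise ValueError("need fits at >= 2 fields")
    pts = []
    for f, fit in fits.items():
        err = fit.r1_stderr if np.isfinite(fit.t1_stderr) else np.inf
        pts.append((float(f), fit.r1, err))
    return NmrdProfile(points=tuple(pts), roi_role=roi_role, subject_id=subject_id)


def fit_power_law(profile: NmrdProfile, fields_used: Sequence[float] | None = None) -> DispersionFit:
    """Least squares of ln R1 = ln alpha - beta ln B over the chosen fields.

    With exactly two fields this reduces to the closed form
    beta = ln(r1_a / r1_b) / ln(field_b / field_a).
    """
    if fields_used is None:
        fields_used = profile.fields
    fields_used = tuple(float(f) for f in fields_used)
    missing = [f for f in fields_used if f not in profile.fields]
    if missing:
        raise ValueError(f"fields {missing} not in profile")
    if len(fields_used) < 2:
        raise ValueError("need >= 2 fields to fit a power law")
    x = np.log(np.array(fields_used))
    y = np.log(np.array([profile.r1(f) for f in fields_used]))
    if len(fields_used) == 2:
        beta = float((y[0] - y[1]) / (x[1] - x[0]))
        alpha = float(np.exp(y[0] + beta * x[0]))
        stderr = 0.0
    else:
        (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
        beta = float(-slope)
        alpha = float(np.exp(intercept))
        stderr = float(np.sqrt(cov[0, 0]))
    return DispersionFit(alpha=alpha, beta=beta, fields_used=fields_used, fit_stderr=stderr)


def qp_amplitude(profile: NmrdProfile, peak_field: float = QP_FIELD_MT) -> QpEstimate:
    """Quadrupolar-peak amplitude by baseline subtraction at 65.8 mT.

    The baseline is the log-log linear interpolation between the nearest
    measured fields flanking the peak; the amplitude is R1(peak) - baseline
    and may be negative on noisy data.
    """
    if peak_field not in profile.fields:
        raise ValueError(f"profile has no point at {peak_field} mT")
    below = [f for f in profile.fields if f < peak_field]
    above = [f for f in profile.fields if f > peak_field]
    if not below or not above:
        raise ValueError("need at least one field on each side of the peak")
    f_lo, f_hi = max(below), min(above)
    frac = np.log(peak_field / f_lo) / np.log(f_hi / f_lo)
    log_base = np.log(profile.r1(f_lo)) + frac * (np.log(profile.r1(f_hi)) - np.log(profile.r1(f_lo)))
    baseline = float(np.exp(log_base))
    return QpEstimate(
        amplitude=float(profile.r1(peak_field) - baseline),
        baseline_r1=baseline,
        peak_field=peak_field,
    )


def global_beta(profile: NmrdProfile, exclude_qp: bool = True) -> DispersionFit:
    """Single dispersion exponent over all fields, excluding the QP field.

    This is the beta used for the invasive vs non-invasive comparison; the
    65.8 mT point is dropped to avoid quadrupolar contamination.
    """
    fields = [f for f in profile.fields if not (exclude_qp and f == QP_FIELD_MT)]
    return fit_power_law(profile, fields)


def beta_low(profile: NmrdProfile, split_mT: float = BETA_SPLIT_MT) -> DispersionFit:
    """beta_L: power-law fit over fields <= the 22 mT split (boundary shared)."""
    return fit_power_law(profile, [f for f in profile.fields if f <= split_mT])


def beta_high(profile: NmrdProfile, split_mT: float = BETA_SPLIT_MT) -> DispersionFit:
    """beta_H: fit over fields >= the split, excluding the QP field."""
    fields = [f for f in profile.fields if f >= split_mT and f != QP_FIELD_MT]
    return fit_power_law(profile, fields)


def profile_biomarkers(profile: NmrdProfile) -> dict[str, float]:
    """All scalar biomarkers of one profile (per-field R1, betas, QP)."""
    out = {f"r1_{f:g}mT": profile.r1(f) for f in profile.fields}
    try:
        out["beta_L"] = beta_low(profile).beta
        out["beta_H"] = beta_high(profile).beta
        out["beta"] = global_beta(profile).beta
    except ValueError:
        pass
    try:
        out["A_QP"] = qp_amplitude(profile).amplitude
    except ValueError:
        pass
    return out


def summarize_cohort(
    profiles: Sequence[NmrdProfile], grouping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-class median (IQR) of every biomarker across a cohort of profiles.

    ``grouping`` maps subject_id to a class name; without it, profiles are
    grouped by their ROI role.  Classes with no profiles are omitted with a
    warning.  Quartiles use the linear-interpolation convention.
    """
    rows = []
    for p in profiles:
        cls = grouping.get(p.subject_id, p.roi_role) if grouping else p.roi_role
        for biomarker, value in profile_biomarkers(p).items():
            rows.append(
                {"subject_id": p.subject_id, "class": cls, "biomarker": biomarker, "value": value}
            )
    if not rows:
        warnings.warn("no profiles to summarise")
        return pd.DataFrame(columns=["class", "biomarker", "n", "median", "q25", "q75"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["class", "biomarker"])["value"]
        .agg(
            n="count",
            median="median",
            q25=lambda v: float(np.percentile(v, 25)),
            q75=lambda v: float(np.percentile(v, 75)),
        )
        .reset_index()
    )
    return out
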