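"""T1/R1 estimation from multi-evolution-time magnitude data.

The field-cycling relaxation model S(t) = A[(M0_P - M0_E) exp(-t/T1) + M0_E]
is fitted in the identifiable reparameterisation

    S(t) = a * exp(-t / T1) + b,   b >= 0, T1 > 0

since A, M0_P and M0_E only enter through the products a = A(M0_P - M0_E)
and b = A*M0_E.  The amplitude a is sign-free: at evolution fields close to
the polarisation field the equilibrium magnetisation exceeds the partially
polarised one and the signal recovers upward (a < 0).  Magnitude (Rician)
bias is not corrected: magnitudes are fitted directly, which is a
documented limitation at low SNR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["RelaxationFit", "RoiSet", "roi_mean_signal", "fit_t1", "t1_map", "fit_roi_r1"]

_ROI_ROLES = ("tumour", "adipose", "glandular", "adjacent_healthy", "background")


@dataclass(frozen=True)
class RelaxationFit:
    """Result of a mono-exponential decay fit.

    t1 in ms, r1 = 1000/t1 in s^-1; ``amp_decay`` and ``amp_floor`` are the
    fitted a and b; ``t1_stderr`` is the 1-sigma standard error from the fit
    covariance (inf when T1 is unidentifiable).
    """

    t1: float
    amp_decay: float
    amp_floor: float
    t1_stderr: float
    residual_rms: float
    n_points: int
    converged: bool

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError("t1 must be positive")
        if self.t1_stderr < 0:
            raise ValueError("t1_stderr must be non-negative")

    @property
    def r1(self) -> float:
        """Relaxation rate in s^-1 (t1 in ms)."""
        return 1000.0 / self.t1

    @property
    def r1_stderr(self) -> float:
        """Delta-method standard error of r1: stderr * 1000 / t1^2."""
        return self.t1_stderr * 1000.0 / self.t1**2


@dataclass
class RoiSet:
    """Named voxel masks (boolean arrays of the image shape), disjoint."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        total = None
        for role, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            self.masks[role] = m
            if total is None:
                total = np.zeros_like(m, dtype=np.int32)
            if m.shape != total.shape:
                raise ValueError("all ROI masks must share one shape")
            total += m
        if total is not None and np.any(total > 1):
            raise ValueError("ROI masks must be disjoint")

    def __getitem__(self, role: str) -> np.ndarray:
        return self.masks[role]

    def __contains__(self, role: str) -> bool:
        return role in self.masks

    @classmethod
    def from_label_map(cls, label_map: np.ndarray, ring_width: int = 2) -> "RoiSet":
        """Build the standard ROI set from a phantom label map.

        The adjacent-healthy ROI is a ring of non-tumour tissue around the
        tumour (a glandular/adipose mix by phantom construction); ring voxels
        are removed from the tissue-class masks to keep the set disjoint.
        """
        from scipy.ndimage import binary_dilation

        from fci.phantom import TissueLabel

        lm = np.asarray(label_map)
        tumour = (lm == TissueLabel.tumour_invasive) | (lm == TissueLabel.tumour_noninvasive)
        tissue = lm != TissueLabel.background
        ring = binary_dilation(tumour, iterations=ring_width) & ~tumour & tissue
        return cls(
            masks={
                "tumour": tumour,
                "adjacent_healthy": ring,
                "glandular": (lm == TissueLabel.glandular) & ~ring,
                "adipose": (lm == TissueLabel.adipose) & ~ring,
                "background": lm == TissueLabel.background,
            }
        )


def roi_mean_signal(images, mask: np.ndarray, field_mT: float) -> list[tuple[float, float]]:
    """ROI-mean magnitude at each evolution time of one field.

    Returns one (evolution_time_ms, mean_signal) pair per evolution time in
    protocol order.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    if field_mT not in images.protocol.evolution_times_ms:
        raise ValueError(f"field {field_mT} mT not in protocol")
    out = []
    for t in images.protocol.evolution_times_ms[field_mT]:
        out.append((t, float(images.volume(field_mT, t)[mask].mean())))
    return out


def _decay(t, a, b, t1):
    return a * np.exp(-t / t1) + b


def _initial_guess(t: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    # floor from the long-time end; amplitude (sign-free) from the span
    b0 = float(s[-1])
    a0 = float(s[0] - s[-1])
    t1_0 = float(np.median(t))
    if a0 != 0:
        # time at which the curve crosses b0 + a0/e (works for both signs)
        target = b0 + a0 / np.e
        crossed = np.nonzero((s - target) * np.sign(a0) <= 0)[0]
        if crossed.size and crossed[0] > 0:
            i = crossed[0]
            s0, s1 = s[i - 1], s[i]
            if s0 != s1:
                frac = (s0 - target) / (s0 - s1)
                t1_0 = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return a0 if a0 != 0 else 1e-12, max(b0, 0.0), max(t1_0, 1e-6)


def fit_t1(
    samples: Iterable[tuple[float, float]],
    init: tuple[float, float, float] | None = None,
) -> RelaxationFit:
    """Nonlinear least-squares mono-exponential fit of (t_evo_ms, signal).

    Requires >= 3 samples with distinct times (three free parameters).
    Non-convergence and unidentifiable decays (constant signal) are flagged
    via ``converged``/infinite ``t1_stderr``, never raised.
    """
    pts = sorted((float(t), float(s)) for t, s in samples)
    t = np.array([p[0] for p in pts])
    s = np.array([p[1] for p in pts])
    if len(np.unique(t)) < 3:
        raise ValueError("need >= 3 samples with distinct evolution times")
    p0 = init if init is not None else _initial_guess(t, s)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _decay,
                t,
                s,
                p0=p0,
                bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=20000,
            )
        a, b, t1 = (float(x) for x in popt)
        var = pcov[2, 2]
        stderr = float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else np.inf
        resid = s - _decay(t, a, b, t1)
        rms = float(np.sqrt(np.mean(resid**2)))
        # |a| ~ 0 means there is no time dependence: T1 is unidentifiable
        converged = bool(np.isfinite(stderr)) and abs(a) > 1e-10 * max(b, 1.0)
        return RelaxationFit(
            t1=t1,
            amp_decay=a,
            amp_floor=b,
            t1_stderr=stderr if converged else np.inf,
            residual_rms=rms,
            n_points=len(t),
            converged=converged,
        )
    except RuntimeError:
        a0, b0, t1_0 = p0
        return RelaxationFit(
            t1=max(t1_0, 1e-9),
            amp_decay=a0,
            amp_floor=b0,
            t1_stderr=np.inf,
            residual_rms=float(np.sqrt(np.mean((s - s.mean()) ** 2))),
            n_points=len(t),
            converged=False,
        )


def fit_roi_r1(images, mask: np.ndarray, field_mT: float) -> RelaxationFit:
    """ROI-level fit: fit the ROI-mean decay (not the mean of voxel fits)."""
    return fit_t1(roi_mean_signal(images, mask, field_mT))


def t1_map(
    images,
    field_mT: float,
    mask: np.ndarray | None = None,
    max_rel_stderr: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise T1 map (ms) and 1-sigma stderr map at one evolution field.

    Voxels whose fit does not converge, whose relative T1 standard error
    exceeds ``max_rel_stderr``, or whose T1 lands outside the identifiable
    window of the time grid ([0.5 * t_min, 10 * t_max]; pure-noise voxels
    collapse to an unsampled instantaneous decay) are set to NaN in both
    maps.  ``mask`` optionally restricts the fit to a voxel subset.
    """
    if field_mT not in images.protocol.evolution_times_ms:
        raise ValueError(f"field {field_mT} mT not in protocol")
    times = images.protocol.evolution_times_ms[field_mT]
    stack = np.stack([images.volume(field_mT, t) for t in times], axis=0)
    shape = stack.shape[1:]
    t1_img = np.full(shape, np.nan)
    err_img = np.full(shape, np.nan)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    t1_lo, t1_hi = 0.5 * min(times), 10.0 * max(times)
    for iy, ix in zip(*np.nonzero(mask)):
        fit = fit_t1(zip(times, stack[:, iy, ix]))
        if not t1_lo <= fit.t1 <= t1_hi:
            continue
        if fit.converged and np.isfinite(fit.t1_stderr) and fit.t1_stderr <= max_rel_stderr * fit.t1:
            t1_img[iy, ix] = fit.t1
            err_img[iy, ix] = fit.t1_stderr
    return t1_img, err_img
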