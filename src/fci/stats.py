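"""Exact and asymptotic nonparametric group comparisons.

Implements from first principles the small-sample rank tests used for
biomarker comparisons:

* Mann-Whitney U (unpaired), with the exact null distribution of U built by
  dynamic programming over rank assignments and a normal approximation with
  mid-ranks and tie-corrected variance;
* Wilcoxon signed-rank (paired), zero differences dropped, normal
  approximation without continuity correction, exact p by enumeration of
  sign patterns;
* effect size r = |Z| / sqrt(N) and median/IQR summaries.

Two-sided exact p values follow the "doubled lower tail" convention:
p = 2 * P(U <= u_obs) for the smaller of the two U statistics, capped at 1.
The alternative "total mass of both tails at least as extreme" convention is
available via ``two_sided="tail_mass"``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb, sqrt
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "median_iqr",
    "biomarker_report",
    "mann_whitney_u_counts",
    "exact_mw_p",
    "mw_z",
    "signed_rank_counts",
    "exact_wilcoxon_p",
    "wilcoxon_z",
]

_EXACT_MW_LIMIT = 25  # total N up to which the exact U distribution is computed
_EXACT_TIE_LIMIT = 12  # total N up to which ties are handled by enumeration
_EXACT_WILCOXON_LIMIT = 15  # pairs up to which sign patterns are enumerated


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-sample or paired rank test.

    ``statistic`` is U (Mann-Whitney) or W (Wilcoxon), always the smaller of
    the two possible values.  ``n2`` is 0 for paired tests.  ``p_exact`` is
    NaN when the exact computation is out of range.
    """

    statistic: float
    n1: int
    n2: int
    z: float
    p_exact: float
    p_normal: float
    effect_size_r: float
    method: str

    def __post_init__(self) -> None:
        for p in (self.p_exact, self.p_normal):
            if np.isfinite(p) and not 0.0 <= p <= 1.0:
                raise ValueError("p values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def mann_whitney_u_counts(n1: int, n2: int) -> np.ndarray:
    """Exact null counts of the Mann-Whitney U statistic for one group.

    ``counts[u]`` is the number of the C(n1+n2, n1) equally likely rank
    assignments in which the first group attains U = u.  Built by dynamic
    programming over pooled rank positions: when position ``i`` (1-based) is
    the k-th member of group one, it contributes ``i - k`` pairs won against
    group two.
    """
    n = n1 + n2
    umax = n1 * n2
    # dp[k, u]: ways to place k group-one members among the first i positions
    dp = np.zeros((n1 + 1, umax + 1), dtype=object)
    dp[0, 0] = 1
    for i in range(1, n + 1):
        for k in range(min(i, n1), 0, -1):
            contrib = i - k
            if contrib > umax:
                continue
            dp[k, contrib:] = dp[k, contrib:] + dp[k - 1, : umax + 1 - contrib]
    counts = dp[n1]
    assert sum(counts) == comb(n, n1)
    return counts


def exact_mw_p(u: float, n1: int, n2: int, two_sided: str = "double") -> float:
    """Exact two-sided p for an observed Mann-Whitney U (no ties).

    ``u`` is folded to the smaller of (u, n1*n2 - u).  With
    ``two_sided="double"`` the p value is twice the lower-tail cumulative
    probability P(U <= u), capped at 1; ``"tail_mass"`` sums the null mass
    of all U at least as far from n1*n2/2 as observed.
    """
    counts = mann_whitney_u_counts(n1, n2)
    total = comb(n1 + n2, n1)
    u = min(u, n1 * n2 - u)
    iu = int(np.floor(u + 1e-9))
    if two_sided == "double":
        p = 2.0 * float(sum(counts[: iu + 1])) / total
    elif two_sided == "tail_mass":
        mid = n1 * n2 / 2.0
        dev = abs(u - mid)
        mask = [abs(k - mid) >= dev - 1e-9 for k in range(len(counts))]
        p = float(sum(c for c, m in zip(counts, mask) if m)) / total
    else:
        raise ValueError("two_sided must be 'double' or 'tail_mass'")
    return min(p, 1.0)


def mw_z(u: float, n1: int, n2: int, tie_term: float = 0.0) -> float:
    """Normal-approximation deviate of U, optional tie-corrected variance.

    Z = (U - n1 n2 / 2) / sqrt(n1 n2 (n1+n2+1) / 12); with ties the variance
    is n1 n2 / 12 * (n+1 - sum(t^3 - t) / (n (n-1))) for tie-group sizes t.
    """
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if tie_term else n1 * n2 * (n + 1) / 12.0
    if var <= 0:
        return 0.0
    return (u - n1 * n2 / 2.0) / sqrt(var)


def _tie_term(pooled_ranks: np.ndarray) -> float:
    _, counts = np.unique(pooled_ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _exact_mw_p_with_ties(ranks_a: np.ndarray, ranks_b: np.ndarray, two_sided: str) -> float:
    """Exact p by enumerating assignments of the observed mid-ranks."""
    pooled = np.concatenate([ranks_a, ranks_b])
    n1, n2 = len(ranks_a), len(ranks_b)
    n = n1 + n2
    offset = n1 * (n1 + 1) / 2.0
    u_obs = min(ranks_a.sum() - offset, n1 * n2 - (ranks_a.sum() - offset))
    mid = n1 * n2 / 2.0
    hits = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        ra = pooled[list(idx)].sum() - offset
        u = min(ra, n1 * n2 - ra)
        total += 1
        if two_sided == "double":
            if u <= u_obs + 1e-9:
                hits += 1
        else:
            if abs(ra - mid) >= abs(u_obs - mid) - 1e-9:
                hits += 1
    # min(U_a, U_b) <= u_obs already covers both tails
    return min(1.0, hits / total)


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], two_sided: str = "double"
) -> GroupComparison:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns the smaller U, the tie-corrected normal deviate Z, the exact p
    (full enumeration; NaN beyond the exact range), the asymptotic p and the
    effect size r = |Z| / sqrt(n1 + n2).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # mid-ranks for ties
    ranks_a, ranks_b = ranks[:n1], ranks[n1:]
    u_a = float(ranks_a.sum() - n1 * (n1 + 1) / 2.0)
    u = min(u_a, n1 * n2 - u_a)
    has_ties = len(np.unique(pooled)) < n
    tie_term = _tie_term(ranks) if has_ties else 0.0
    z = mw_z(u, n1, n2, tie_term)
    if np.all(pooled == pooled[0]):
        # fully degenerate: no information
        return GroupComparison(u, n1, n2, 0.0, 1.0, 1.0, 0.0, "mann_whitney")
    p_normal = min(1.0, 2.0 * norm.cdf(-abs(z)))
    if not has_ties and n <= _EXACT_MW_LIMIT:
        p_exact = exact_mw_p(u, n1, n2, two_sided)
    elif has_ties and n <= _EXACT_TIE_LIMIT:
        p_exact = _exact_mw_p_with_ties(ranks_a, ranks_b, two_sided)
    else:
        p_exact = float("nan")
    r = abs(z) / sqrt(n)
    return GroupComparison(u, n1, n2, z, p_exact, p_normal, r, "mann_whitney")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def signed_rank_counts(ranks: Sequence[float]) -> tuple[np.ndarray, int]:
    """Null counts of the positive-rank sum over all 2^n sign patterns.

    Ranks may be mid-ranks; they are doubled internally so sums stay
    integral.  Returns (counts over doubled sums, total patterns).
    """
    doubled = [int(round(2 * r)) for r in ranks]
    if any(abs(2 * r - d) > 1e-9 for r, d in zip(ranks, doubled)):
        raise ValueError("ranks must be integers or half-integers")
    smax = sum(doubled)
    counts = np.zeros(smax + 1, dtype=object)
    counts[0] = 1
    for d in doubled:
        shifted = np.zeros_like(counts)
        shifted[d:] = counts[: smax + 1 - d]
        counts = counts + shifted
    return counts, 2 ** len(doubled)


def exact_wilcoxon_p(w: float, ranks: Sequence[float]) -> float:
    """Exact two-sided p: P(min(W+, W-) <= w) over all sign patterns."""
    counts, total = signed_rank_counts(ranks)
    smax = len(counts) - 1  # doubled total rank sum
    hits = 0
    for s2, c in enumerate(counts):
        if c and min(s2, smax - s2) <= 2 * w + 1e-9:
            hits += int(c)
    return min(1.0, hits / total)


def wilcoxon_z(w: float, n: int) -> float:
    """Z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24), no continuity correction."""
    var = n * (n + 1) * (2 * n + 1) / 24.0
    if var <= 0:
        return 0.0
    return (w - n * (n + 1) / 4.0) / sqrt(var)


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test of paired samples.

    Zero differences are dropped before ranking; W is the smaller signed-rank
    sum; Z uses no continuity correction; the exact p enumerates the 2^n sign
    patterns for n <= 15 pairs; r = |Z| / sqrt(n).
    """
    a = np.asarray(list(paired_a), dtype=float)
    b = np.asarray(list(paired_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need >= 2 pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return GroupComparison(0.0, a.size, 0, 0.0, 1.0, 1.0, 0.0, "wilcoxon_signed_rank")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    z = wilcoxon_z(w, n)
    p_normal = min(1.0, 2.0 * norm.cdf(-abs(z)))
    p_exact = exact_wilcoxon_p(w, ranks) if n <= _EXACT_WILCOXON_LIMIT else float("nan")
    r = abs(z) / sqrt(n)
    return GroupComparison(w, n, 0, z, p_exact, p_normal, r, "wilcoxon_signed_rank")


# ---------------------------------------------------------------------------
# Summaries and the biomarker report
# ---------------------------------------------------------------------------


def median_iqr(values: Iterable[float]) -> tuple[float, float, float]:
    """(median, 25th, 75th percentile) with linear interpolation."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    return (
        float(np.percentile(v, 50)),
        float(np.percentile(v, 25)),
        float(np.percentile(v, 75)),
    )


def biomarker_report(
    biomarkers: pd.DataFrame,
    invasive_by_subject: Mapping[str, bool] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-biomarker group comparisons mirroring a clinical summary table.

    ``biomarkers`` is tidy with columns subject_id, roi_role, biomarker,
    value.  For each biomarker: paired Wilcoxon signed-rank tests of tumour
    vs glandular and tumour vs adipose (pairing on subject_id; subjects
    missing one ROI reduce n), and, when ``invasive_by_subject`` is given,
    an unpaired Mann-Whitney test of tumour values between invasive and
    non-invasive subjects.  Classes with fewer than 2 observations are
    skipped with a warning.
    """
    required = {"subject_id", "roi_role", "biomarker", "value"}
    if not required.issubset(biomarkers.columns):
        raise ValueError(f"biomarkers table needs columns {sorted(required)}")
    rows = []
    for biomarker, df in biomarkers.groupby("biomarker"):
        by_role = {
            role: sub.set_index("subject_id")["value"] for role, sub in df.groupby("roi_role")
        }
        summary = {}
        for role, vals in by_role.items():
            med, q25, q75 = median_iqr(vals)
            summary[role] = {"n": len(vals), "median": med, "q25": q25, "q75": q75}
        tumour = by_role.get("tumour")
        for other in ("glandular", "adipose"):
            if tumour is None or other not in by_role:
                continue
            common = tumour.index.intersection(by_role[other].index)
            if len(common) < 2:
                warnings.warn(f"{biomarker}: <2 pairs for tumour vs {other}, test skipped")
                continue
            cmp = wilcoxon_signed_rank(tumour.loc[common], by_role[other].loc[common])
            rows.append(
                _report_row(biomarker, f"tumour_vs_{other}", summary, cmp, n_pairs=len(common))
            )
        if invasive_by_subject is not None and tumour is not None:
            inv = [v for s, v in tumour.items() if invasive_by_subject.get(s)]
            noninv = [v for s, v in tumour.items() if s in invasive_by_subject and not invasive_by_subject[s]]
            if len(inv) >= 2 and len(noninv) >= 2:
                cmp = mann_whitney(inv, noninv)
                rows.append(
                    _report_row(biomarker, "invasive_vs_noninvasive", summary, cmp, n_pairs=None)
                )
            else:
                warnings.warn(f"{biomarker}: <2 per invasiveness class, test skipped")
    return pd.DataFrame(rows)


def _report_row(biomarker, comparison, summary, cmp: GroupComparison, n_pairs):
    row = {
        "biomarker": biomarker,
        "comparison": comparison,
        "method": cmp.method,
        "statistic": cmp.statistic,
        "n": n_pairs if n_pairs is not None else cmp.n1 + cmp.n2,
        "z": cmp.z,
        "p_exact": cmp.p_exact,
        "p_normal": cmp.p_normal,
        "effect_size_r": cmp.effect_size_r,
    }
    for role, s in summary.items():
        row[f"{role}_median"] = s["median"]
        row[f"{role}_iqr"] = f"{s['q25']:.3g}-{s['q75']:.3g}"
        row[f"{role}_n"] = s["n"]
    return row
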