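"""Morphometric indices of Hakim's disease and cohort comparison statistics.

Hakim's disease (idiopathic normal-pressure hydrocephalus) is characterized
morphologically by disproportionate ventricular enlargement, summarized by
linear/angular indices measured on brain MRI:

* Evans index — maximal frontal-horn width / maximal inner cranial width;
* Z-Evans index — the same ratio along the z axis on a coronal plane;
* BVR (brain-per-ventricle ratio) — brain width just above the lateral
  ventricles / maximal ventricular width, at the anterior- and
  posterior-commissure coronal planes;
* callosal angle — the angle of the ventricular roof at the posterior
  commissure plane, taken here from three landmark coordinates.

Group comparisons follow the usual nonparametric battery (Kruskal-Wallis
across the three healthy age bands, Mann-Whitney-Wilcoxon for Hakim vs.
elderly, chi-square / Fisher exact for proportions), and associations are
summarized by Pearson's r with a Fisher z-transform 95% CI.  Hypothesis
tests are delegated to scipy.stats; the Fisher-z interval and the
pairwise-complete correlation matrix are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GROUPS",
    "CorrelationResult",
    "evans_index",
    "z_evans_index",
    "bvr",
    "callosal_angle",
    "pearson_with_ci",
    "pearson_ci_from_r",
    "correlation_matrix",
    "group_compare",
    "benjamini_hochberg",
]

#: Cohort group vocabulary: three healthy age bands plus the patient group.
GROUPS = ("under40", "40to59", "over60", "hakim")

_Z95 = 1.96  # normal quantile for the 95% Fisher-z interval


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with Fisher-z 95% confidence interval and t-test p-value."""

    r: float
    ci_low: float
    ci_high: float
    n: int
    p: float

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("correlation requires n >= 4")
        if not (-1 <= self.ci_low <= self.r <= self.ci_high <= 1):
            raise ValueError("confidence interval must bracket r within [-1, 1]")


def evans_index(frontal_horn_width: float, max_inner_cranial_width: float) -> float:
    """Evans index: maximal frontal-horn width over maximal inner cranial
    width (both mm, x dimension)."""
    if frontal_horn_width <= 0 or max_inner_cranial_width <= 0:
        raise ValueError("widths must be positive")
    return frontal_horn_width / max_inner_cranial_width


def z_evans_index(frontal_horn_z_length: float, cranial_z_length: float) -> float:
    """Z-Evans index: maximal z-axial frontal-horn length over maximal
    cranial z-axial length on the AC coronal plane (both mm)."""
    if frontal_horn_z_length <= 0 or cranial_z_length <= 0:
        raise ValueError("lengths must be positive")
    return frontal_horn_z_length / cranial_z_length


def bvr(brain_width: float, ventricle_width: float) -> float:
    """Brain-per-ventricle ratio: brain width just above the lateral
    ventricles over maximal ventricular width (both mm)."""
    if brain_width <= 0 or ventricle_width <= 0:
        raise ValueError("widths must be positive")
    return brain_width / ventricle_width


def callosal_angle(
    left_point: Sequence[float],
    apex_point: Sequence[float],
    right_point: Sequence[float],
) -> float:
    """Interior angle (degrees) at ``apex_point`` formed by the ventricular
    roof landmarks, on the posterior-commissure coronal plane.

    Points are 2D or 3D mm coordinates; collinear points raise.
    """
    a = np.asarray(left_point, dtype=float) - np.asarray(apex_point, dtype=float)
    b = np.asarray(right_point, dtype=float) - np.asarray(apex_point, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("landmark points must be distinct")
    cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    # tolerance absorbs floating-point slack in the arccos around 0/180 deg
    if angle < 1e-4 or angle > 180.0 - 1e-4:
        raise ValueError("landmark points are collinear")
    return angle


def pearson_ci_from_r(r: float, n: int) -> CorrelationResult:
    """Fisher-z 95% CI and t-test p for a given correlation and sample size.

    CI = tanh(atanh(r) +/- 1.96 / sqrt(n - 3)); p is two-sided from the
    t distribution with n - 2 degrees of freedom.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not -1 < r < 1:
        raise ValueError("r must lie strictly inside (-1, 1) for the z-transform")
    z = np.arctanh(r)
    half = _Z95 / np.sqrt(n - 3)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(
        r=float(r),
        ci_low=float(np.tanh(z - half)),
        ci_high=float(np.tanh(z + half)),
        n=int(n),
        p=p,
    )


def pearson_with_ci(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(sps.pearsonr(x, y).statistic)
    if abs(r) == 1.0:  # degenerate perfect fit: CI collapses to r
        return CorrelationResult(r=r, ci_low=r, ci_high=r, n=int(x.size), p=0.0)
    return pearson_ci_from_r(r, int(x.size))


def correlation_matrix(
    indices: pd.DataFrame,
    foi: pd.DataFrame,
    min_n: int = 4,
) -> pd.DataFrame:
    """Cellwise Pearson correlations of morphometric indices against ROI FOIs.

    Both inputs are wide subject-indexed tables (rows = subjects, columns =
    index names / ROI names).  Each cell uses pairwise-complete observations
    (missing data points do not affect other cells); cells with fewer than
    ``min_n`` complete pairs, or with zero variance, are returned with NaN
    results and flagged.  Returns a long DataFrame with columns
    (index, roi, r, ci_low, ci_high, n, p).
    """
    indices, foi = indices.align(foi, join="inner", axis=0)
    rows = []
    for index_name in indices.columns:
        for roi_name in foi.columns:
            x = indices[index_name]
            y = foi[roi_name]
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < min_n or x[ok].std() == 0 or y[ok].std() == 0:
                rows.append((index_name, roi_name, np.nan, np.nan, np.nan, n, np.nan))
                continue
            res = pearson_with_ci(x[ok].to_numpy(), y[ok].to_numpy())
            rows.append(
                (index_name, roi_name, res.r, res.ci_low, res.ci_high, res.n, res.p)
            )
    return pd.DataFrame(
        rows, columns=["index", "roi", "r", "ci_low", "ci_high", "n", "p"]
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default in the
    correlation matrix, which reports raw p like the source analysis)."""
    p = np.asarray(p_values, dtype=float)
    return sps.false_discovery_control(p, method="bh")


def group_compare(
    data: Mapping[str, Sequence[float]] | np.ndarray,
    test: str,
) -> tuple[float, float]:
    """Run one of the cohort hypothesis tests; returns (statistic, p).

    ``test`` is one of:

    * ``"kruskal_wallis"`` — tie-corrected rank test across >= 2 groups
      (``data`` maps group name -> values);
    * ``"mann_whitney"`` — two-group rank test; exact p by enumeration when
      both groups have <= 8 observations and no ties, normal approximation
      with tie correction otherwise;
    * ``"chi_square"`` / ``"fisher_exact"`` — on a contingency table
      (``data`` is a 2D count array; Fisher requires 2x2, two-sided by
      summation of tables no more probable than the observed one).
    """
    if test == "kruskal_wallis":
        groups = _as_groups(data, minimum=2)
        stat, p = sps.kruskal(*groups)
        return float(stat), float(p)
    if test == "mann_whitney":
        groups = _as_groups(data, minimum=2)
        if len(groups) != 2:
            raise ValueError("mann_whitney requires exactly 2 groups")
        a, b = groups
        pooled = np.concatenate([a, b])
        small = len(a) <= 8 and len(b) <= 8
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if small and not has_ties else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "chi_square":
        table = _as_table(data)
        res = sps.chi2_contingency(table)
        return float(res.statistic), float(res.pvalue)
    if test == "fisher_exact":
        table = _as_table(data)
        if table.shape != (2, 2):
            raise ValueError("fisher_exact requires a 2x2 table")
        res = sps.fisher_exact(table, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test '{test}'")


def _as_groups(data, minimum: int) -> list[np.ndarray]:
    if not isinstance(data, Mapping):
        raise ValueError("rank tests need a mapping of group name -> values")
    groups = [np.asarray(v, dtype=float) for v in data.values()]
    if len(groups) < minimum or any(g.size < 1 for g in groups):
        raise ValueError(f"need >= {minimum} nonempty groups")
    return groups


def _as_table(data) -> np.ndarray:
    table = np.asarray(data)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("contingency tests need a 2D nonnegative count table")
    return table
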