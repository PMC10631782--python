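"""Group statistics and cross-band CAP comparison.

Group differences in CAP dynamics use the classical independent-samples
Student t-test (pooled variance; Welch selectable); demographics use a
Pearson chi-square without continuity correction for sex and a one-way
ANOVA for age, the latter reconstructable from printed group summaries
(mean, SE, n) alone. Clinical coupling uses Pearson correlation between a
CAP characteristic and the MMSE score. Significance is reported
uncorrected at alpha = 0.05 by default, with an optional
Benjamini-Hochberg flag.

Cross-band similarity of CAP spatial maps is a Pearson correlation matrix
over voxels between the z-maps of two fitted models, with an optimal
(Hungarian) one-to-one matching — CAPs that look alike in two bands need
not share a CAP number, since numbering follows band-specific occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.optimize import linear_sum_assignment

from .cap import CapClustering
from .types import ValidationError

__all__ = [
    "compare_groups",
    "chi_square_2x2",
    "anova_from_summary",
    "correlate_with_score",
    "cross_band_correlation",
    "CrossBandMatrix",
    "METRIC_COLUMNS",
]

#: Dynamic characteristics compared between groups.
METRIC_COLUMNS = (
    "occurrence",
    "entry_count",
    "entry_rate_per_min",
    "mean_duration_frames",
)


def _pooled_t(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float, float]:
    """(t, df, p) for an independent two-sample test; assumes len >= 2 each."""
    res = scipy.stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        ) if (va + vb) > 0 else np.nan
    else:
        df = a.size + b.size - 2
    return float(res.statistic), float(df), float(res.pvalue)


def compare_groups(
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    *,
    group_col: str = "group",
    groups: tuple[str, str] = ("AD", "NC"),
    alpha: float = 0.05,
    welch: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Independent-samples t-tests per (band, cap, metric).

    ``metrics`` is the tidy table from :func:`capdyn.dynamics.metrics_table`;
    ``cohort`` maps subject_id to group. Missing values (e.g. dwell time of
    a never-visited state) are dropped per test. Degenerate cells — fewer
    than two subjects in a group, or zero pooled variance — are flagged
    ``untestable`` rather than raising.

    Returns one row per (band, cap, metric) with group means/SEs, t, df, p
    and a significance flag at ``alpha``.
    """
    merged = metrics.merge(
        cohort[["subject_id", group_col]], on="subject_id", how="left"
    )
    if merged[group_col].isna().any():
        missing = merged.loc[merged[group_col].isna(), "subject_id"].unique()
        raise ValidationError(f"subjects missing from cohort table: {missing}")
    ga, gb = groups
    rows = []
    for (band, cap), cell in merged.groupby(["band", "cap"], sort=True):
        for metric in METRIC_COLUMNS:
            if metric not in cell.columns:
                continue
            a = cell.loc[cell[group_col] == ga, metric].dropna().to_numpy(float)
            b = cell.loc[cell[group_col] == gb, metric].dropna().to_numpy(float)
            row = {
                "band": band,
                "cap": cap,
                "metric": metric,
                f"mean_{ga}": a.mean() if a.size else np.nan,
                f"se_{ga}": a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else np.nan,
                f"mean_{gb}": b.mean() if b.size else np.nan,
                f"se_{gb}": b.std(ddof=1) / np.sqrt(b.size) if b.size > 1 else np.nan,
                "n_" + ga: a.size,
                "n_" + gb: b.size,
            }
            pooled_var = (
                a.var(ddof=1) + b.var(ddof=1) if a.size > 1 and b.size > 1 else np.nan
            )
            if a.size < 2 or b.size < 2 or pooled_var == 0:
                row.update(t=np.nan, df=np.nan, p=np.nan, untestable=True, significant=False)
            else:
                t, df, p = _pooled_t(a, b, welch)
                if not np.isfinite(t):
                    row.update(t=np.nan, df=np.nan, p=np.nan, untestable=True, significant=False)
                else:
                    row.update(t=t, df=df, p=p, untestable=False, significant=False)
            rows.append(row)
    out = pd.DataFrame(rows)
    testable = ~out["untestable"]
    if fdr:
        p = out.loc[testable, "p"].to_numpy()
        out.loc[testable, "p_adj"] = _bh_adjust(p)
        out.loc[testable, "significant"] = out.loc[testable, "p_adj"] < alpha
    else:
        out.loc[testable, "significant"] = out.loc[testable, "p"] < alpha
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def chi_square_2x2(table: np.ndarray, *, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table (df = 1, two-sided p).

    No continuity correction by default; set ``correction=True`` for the
    Yates-corrected variant.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValidationError("table must contain nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("all margins must be positive")
    chi2, p, _, _ = scipy.stats.chi2_contingency(t, correction=correction)
    return float(chi2), float(p)


def anova_from_summary(
    means, ses, ns
) -> tuple[float, float]:
    """One-way ANOVA reconstructed from group summaries (mean, SE, n).

    Group variances are recovered as ``s^2 = SE^2 * n``; between/within
    mean squares follow from the summaries, giving F on (g-1, sum(n)-g)
    degrees of freedom. For two groups F equals the square of the pooled
    two-sample t statistic.
    """
    means = np.asarray(means, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (means.size == ses.size == ns.size) or means.size < 2:
        raise ValidationError("need equal-length summaries for >= 2 groups")
    if np.any(ns < 2):
        raise ValidationError("every group needs n >= 2")
    if np.any(ses <= 0):
        raise ValidationError("SEs must be positive")
    g = means.size
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ssb = (ns * (means - grand) ** 2).sum()
    variances = ses**2 * ns
    ssw = ((ns - 1) * variances).sum()
    msb = ssb / (g - 1)
    msw = ssw / (n_total - g)
    f = msb / msw
    p = float(scipy.stats.f.sf(f, g - 1, n_total - g))
    return float(f), p


def correlate_with_score(values, scores) -> tuple[float, float]:
    """Pearson r and two-sided p between a CAP characteristic and a score.

    NaN pairs are dropped; needs >= 3 complete pairs and non-constant
    vectors, otherwise raises.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size:
        raise ValidationError("values and scores must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("constant input: correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CrossBandMatrix:
    """Pearson correlations between the CAP z-maps of two bands.

    ``r[i, j]`` correlates CAP i+1 of band A with CAP j+1 of band B over
    voxels. ``matching[i]`` gives, for CAP i+1 of band A, the 0-based index
    of its Hungarian-matched CAP in band B (the bijection maximizing total
    matched correlation); ``matched_r`` are the corresponding correlations.
    """

    band_a: str
    band_b: str
    r: np.ndarray
    matching: np.ndarray
    matched_r: np.ndarray


def cross_band_correlation(
    model_a: CapClustering, model_b: CapClustering
) -> CrossBandMatrix:
    """Correlation matrix and optimal CAP matching between two bands."""
    za, zb = model_a.zmaps_, model_b.zmaps_
    if za.shape[1] != zb.shape[1]:
        raise ValidationError(
            f"voxel spaces differ: {za.shape[1]} vs {zb.shape[1]}"
        )
    ka, kb = za.shape[0], zb.shape[0]
    r = np.empty((ka, kb))
    for i in range(ka):
        for j in range(kb):
            r[i, j] = np.corrcoef(za[i], zb[j])[0, 1]
    row, col = linear_sum_assignment(-r)
    matching = np.empty(min(ka, kb), dtype=int)
    matching[row] = col
    return CrossBandMatrix(
        band_a=model_a.band_tag_,
        band_b=model_b.band_tag_,
        r=r,
        matching=matching,
        matched_r=r[np.arange(matching.size), matching],
    )
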