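"""Participant-level paired comparisons of trend indices.

The experimental unit is the participant: trial-level trends are first
averaged per participant within each group, then the two group means are
compared with a paired one-tailed t test (expected direction: group A
lower than group B, e.g. short-RT trials carrying a smaller upward trend
than long-RT trials).  Effect sizes are paired Cohen's d (mean of the
differences over their sample SD; the pooled-SD variant is reported
alongside).  Within a contrast, the family of smoothing windows is
jointly corrected with the Benjamini-Hochberg step-up procedure;
decomposed-trend p values are reported uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "participant_means",
    "paired_t_one_tailed",
    "cohens_d_paired",
    "cohens_d_pooled",
    "bh_fdr",
    "run_contrast",
    "results_table",
]


@dataclass
class ComparisonResult:
    """One paired group comparison at one method/scale."""

    contrast: str
    method: str
    scale_ms: float
    n_participants: int
    mean_a: float
    mean_b: float
    mean_diff_px: float
    t_stat: float
    dof: int
    p_one_tailed: float
    cohens_d: float
    cohens_d_pooled: float
    p_fdr: float | None = None
    degenerate: bool = False
    group_a: str = ""
    group_b: str = ""


def participant_means(joined: pd.DataFrame, assignment: pd.DataFrame) -> pd.DataFrame:
    """Mean trend per participant x group x method x scale.

    ``joined`` carries one row per (participant, trial_index, method,
    scale_ms, value_px); ``assignment`` maps trials to groups.  Only
    participants contributing at least one complete trend to *both*
    groups of a scheme survive into the paired comparison (enforced
    downstream, where the pairing is formed).
    """
    if len(assignment) == 0:
        raise ValueError("empty group assignment")
    keys = ["participant", "trial_index"]
    merged = joined.merge(assignment, on=keys, how="inner")
    if len(merged) == 0:
        raise ValueError("comparison impossible: no trial has both a trend and a group")
    return (
        merged.groupby(["participant", "group", "method", "scale_ms"], sort=False)["value_px"]
        .mean()
        .reset_index()
    )


def paired_t_one_tailed(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float, bool]:
    """Paired t test of H1: mean(a - b) < 0.

    Returns ``(t, dof, p_one_tailed, degenerate)``.  With zero variance
    of the differences the statistic is undefined; the p value is then 0
    or 1 by the sign of the mean difference (0.5 when all differences are
    zero) and the result is flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length paired samples of size >= 2")
    d = a - b
    dof = d.size - 1
    sd = d.std(ddof=1)
    if sd == 0:
        m = d.mean()
        p = 0.5 if m == 0 else (0.0 if m < 0 else 1.0)
        t = 0.0 if m == 0 else float(np.sign(m) * np.inf)
        return t, dof, p, True
    res = sps.ttest_rel(a, b, alternative="less")
    return float(res.statistic), dof, float(res.pvalue), False


def cohens_d_paired(a: np.ndarray, b: np.ndarray) -> float:
    """Paired Cohen's d: mean(a - b) / sd(a - b), sample SD (n-1).

    With n pairs, |d| = |t| / sqrt(n) for the paired t statistic.
    Returns NaN (degenerate) when the differences have zero variance.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float(d.mean() / sd)


def cohens_d_pooled(a: np.ndarray, b: np.ndarray) -> float:
    """Classical Cohen's d with the pooled group SD (reported alongside
    the paired variant since published effect sizes use either)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt((va * (a.size - 1) + vb * (b.size - 1)) / (a.size + b.size - 2))
    if pooled == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# group ordering per scheme: (a, b) with expected direction mean(a) < mean(b)
_SCHEME_GROUPS = {
    "mean_split": ("short", "long"),
    "quartile_split": ("short", "long"),
    "accuracy": ("correct", "incorrect"),
    "alerting": ("center_cue", "no_cue"),
    "executive": ("congruent", "incongruent"),
}


def run_contrast(
    joined: pd.DataFrame,
    assignment: pd.DataFrame,
    contrast: str | None = None,
) -> list[ComparisonResult]:
    """Run the full comparison grid for one group assignment.

    For every (method, scale) present in ``joined``, participants with a
    mean trend in both groups are paired and tested one-tailed for the
    a-lower-than-b direction.  Benjamini-Hochberg correction is applied
    across the family of smoothing windows within the contrast; the
    conservative and decomposed families are reported uncorrected.
    """
    scheme = assignment["scheme"].iloc[0]
    group_a, group_b = _SCHEME_GROUPS[scheme]
    label = contrast or scheme
    means = participant_means(joined, assignment)

    results: list[ComparisonResult] = []
    for (method, scale), sub in means.groupby(["method", "scale_ms"], sort=True):
        wide = sub.pivot(index="participant", columns="group", values="value_px")
        if group_a not in wide.columns or group_b not in wide.columns:
            continue
        wide = wide.dropna(subset=[group_a, group_b])
        if len(wide) < 2:
            raise ValueError(
                f"comparison impossible for {label}/{method}/{scale}: "
                f"fewer than 2 participants with both groups"
            )
        a = wide[group_a].to_numpy()
        b = wide[group_b].to_numpy()
        t, dof, p, degenerate = paired_t_one_tailed(a, b)
        results.append(
            ComparisonResult(
                contrast=label,
                method=method,
                scale_ms=float(scale),
                n_participants=len(wide),
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                mean_diff_px=float((a - b).mean()),
                t_stat=t,
                dof=dof,
                p_one_tailed=p,
                cohens_d=cohens_d_paired(a, b),
                cohens_d_pooled=cohens_d_pooled(a, b),
                degenerate=degenerate,
                group_a=group_a,
                group_b=group_b,
            )
        )
    # FDR across the smoothing-window family only
    smoothed = [r for r in results if r.method == "smoothed"]
    if smoothed:
        adj = bh_fdr([r.p_one_tailed for r in smoothed])
        for r, q in zip(smoothed, adj):
            r.p_fdr = float(q)
    return results


def results_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results into a delimited-text-friendly table."""
    rows = [vars(r).copy() for r in results]
    return pd.DataFrame(rows)
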