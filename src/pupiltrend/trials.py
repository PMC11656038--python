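"""Trial bookkeeping: exclusion rules, trend attachment, group splits.

Behavioural sessions come in as one event row per trial (target onset,
reaction time, correctness, condition labels).  This module applies the
standard vigilance/working-memory hygiene rules — drop misses,
anticipations at or under 150 ms, errors, and the first few percent of
trials while the pupil adapts to the dark screen — and then forms the
comparison groups: per-participant reaction-time splits (below-mean vs
at-or-above-mean, or lower- vs upper-quartile), correct-vs-incorrect, and
the attention-network-test condition contrasts (alerting: center cue vs
no cue; executive: congruent vs incongruent flankers).

Exclusions are recorded as flags with reasons, never as deletions, so
that the accuracy contrast can re-admit incorrect trials.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "exclude_trials",
    "attach_trends",
    "split_by_rt",
    "split_by_accuracy",
    "split_by_condition",
    "read_events",
    "valid_trial_counts",
]

EVENT_COLUMNS = ["participant", "task", "trial_index", "t_target_ms", "rt_ms", "correct"]

ANTICIPATION_MS = 150.0
FIRST_FRACTION = 0.05

REASON_MISS = "miss"
REASON_FAST = "anticipation_or_false_alarm"
REASON_INCORRECT = "incorrect"
REASON_FIRST = "task_initiation"


def read_events(path) -> pd.DataFrame:
    """Read a delimited event table.

    Required columns: participant, task, trial_index, t_target_ms, rt_ms,
    correct; ANT tables additionally carry cue and target_type.  An empty
    rt_ms field denotes a miss.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event file {path} missing columns {missing}")
    return df


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def exclude_trials(
    events: pd.DataFrame,
    first_fraction: float = FIRST_FRACTION,
    anticipation_ms: float = ANTICIPATION_MS,
) -> pd.DataFrame:
    """Flag trials excluded from the trend analyses.

    Per participant, flags (with a recorded reason):

    * misses / no-responses (missing reaction time);
    * false alarms and anticipations: rt <= ``anticipation_ms`` (boundary
      inclusive), or rows explicitly marked as false alarms;
    * incorrect responses where a correctness column is present;
    * the first round-half-up(``first_fraction`` * N) trials in
      presentation order, N being that participant's total trial count
      (e.g. 116 -> 6, 158 -> 8 at the default 5%).

    Returns a copy with boolean ``excluded`` and string ``reason``
    columns; nothing is deleted.
    """
    if len(events) == 0:
        raise ValueError("no trials in event table")
    df = events.copy()
    df["excluded"] = False
    df["reason"] = ""

    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    miss = rt.isna()
    fast = rt.le(anticipation_ms) & ~miss
    if "false_alarm" in df.columns:
        fast |= df["false_alarm"].fillna(False).astype(bool)

    def flag(mask: pd.Series, reason: str) -> None:
        new = mask & ~df["excluded"]
        df.loc[new, "reason"] = reason
        df.loc[new, "excluded"] = True

    flag(miss, REASON_MISS)
    flag(fast, REASON_FAST)
    if "correct" in df.columns and df["correct"].notna().any():
        incorrect = ~df["correct"].fillna(True).astype(bool)
        flag(incorrect, REASON_INCORRECT)

    for _, grp in df.groupby("participant", sort=False):
        n_first = _round_half_up(first_fraction * len(grp))
        if n_first == 0:
            continue
        first_idx = grp.sort_values("trial_index").index[:n_first]
        mask = pd.Series(False, index=df.index)
        mask.loc[first_idx] = True
        flag(mask, REASON_FIRST)
    return df


def valid_trial_counts(flagged: pd.DataFrame) -> pd.Series:
    """Per-reason exclusion counts plus totals; overlap-aware.

    Each trial contributes to exactly one reason (the first rule that hit
    it), so ``total = valid + sum(per-reason counts)`` always balances.
    """
    counts = flagged.loc[flagged["excluded"], "reason"].value_counts()
    counts["valid"] = int((~flagged["excluded"]).sum())
    counts["total"] = len(flagged)
    return counts


def attach_trends(events: pd.DataFrame, trends: pd.DataFrame) -> pd.DataFrame:
    """Inner-join trend values onto event rows.

    ``trends`` has one row per (participant, trial_index, method,
    scale_ms, value_px, quality).  Trials whose trend is not complete for
    a given method/scale are dropped for that method/scale only,
    mirroring the loss of edge trials to smoothing-window constraints.
    """
    keys = ["participant", "trial_index"]
    if trends.duplicated(subset=keys + ["method", "scale_ms"]).any():
        raise ValueError("duplicate (trial, method, scale) rows in trend table")
    if events.duplicated(subset=keys).any():
        raise ValueError("duplicate trial rows in event table")
    if len(trends) == 0:
        import warnings

        warnings.warn("empty trend table: join produces no rows")
        return events.iloc[0:0].merge(trends, on=keys, how="inner")
    complete = trends[trends["quality"] == "complete"]
    return events.merge(complete, on=keys, how="inner")


def split_by_rt(events: pd.DataFrame, scheme: str = "mean_split") -> pd.DataFrame:
    """Per-participant reaction-time split of non-excluded trials.

    ``mean_split``: short = rt strictly below the participant's mean,
    long = rt at or above it (every valid RT trial is assigned).
    ``quartile_split``: short = rt < 25th percentile, long = rt > 75th
    percentile (middle trials unassigned); percentiles use linear
    interpolation between order statistics (numpy's default), and at
    least four valid RT trials are required per participant.

    Returns rows (participant, trial_index, group, scheme).
    """
    if scheme not in ("mean_split", "quartile_split"):
        raise ValueError(f"unknown scheme {scheme!r}")
    min_n = 4 if scheme == "quartile_split" else 2
    valid = events[~events.get("excluded", pd.Series(False, index=events.index))]
    rt = pd.to_numeric(valid["rt_ms"], errors="coerce")
    valid = valid[rt.notna()]
    out = []
    for pid, grp in valid.groupby("participant", sort=False):
        r = pd.to_numeric(grp["rt_ms"]).to_numpy(dtype=float)
        if len(r) < min_n:
            continue  # participant omitted from this analysis
        if scheme == "mean_split":
            m = r.mean()
            group = np.where(r < m, "short", "long")
            sel = np.ones(len(r), dtype=bool)
        else:
            q25, q75 = np.percentile(r, [25, 75])
            group = np.where(r < q25, "short", np.where(r > q75, "long", ""))
            sel = group != ""
        out.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "trial_index": grp["trial_index"].to_numpy()[sel],
                    "group": group[sel],
                    "scheme": scheme,
                }
            )
        )
    if not out:
        raise ValueError("no participant has enough valid RT trials for this split")
    return pd.concat(out, ignore_index=True)


def split_by_accuracy(events: pd.DataFrame) -> pd.DataFrame:
    """Correct-vs-incorrect split (working-memory accuracy contrast).

    Incorrect trials are re-admitted for this scheme: only trials
    excluded for reasons *other than* incorrectness are dropped.
    Participants with no incorrect (or no correct) trials are omitted.
    """
    if "correct" not in events.columns or events["correct"].isna().all():
        raise ValueError("correctness labels required for the accuracy split")
    excluded = events.get("excluded", pd.Series(False, index=events.index))
    reason = events.get("reason", pd.Series("", index=events.index))
    keep = ~excluded | (reason == REASON_INCORRECT)
    valid = events[keep & events["correct"].notna()]
    out = []
    for pid, grp in valid.groupby("participant", sort=False):
        corr = grp["correct"].astype(bool)
        if corr.all() or (~corr).all():
            continue  # no contrast possible for this participant
        out.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "trial_index": grp["trial_index"].to_numpy(),
                    "group": np.where(corr, "correct", "incorrect"),
                    "scheme": "accuracy",
                }
            )
        )
    if not out:
        raise ValueError("no participant has both correct and incorrect trials")
    return pd.concat(out, ignore_index=True)


def split_by_condition(events: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Attention-network-test condition split.

    ``alerting``: center-cue vs no-cue trials regardless of target type
    (double and spatial cues unassigned; the double-vs-no-cue comparison
    is avoided because the cues differ in luminance).  ``executive``:
    congruent vs incongruent targets irrespective of cue (neutral targets
    unassigned).
    """
    if contrast == "alerting":
        col, a, b, ga, gb = "cue", "center", "none", "center_cue", "no_cue"
    elif contrast == "executive":
        col, a, b, ga, gb = "target_type", "congruent", "incongruent", "congruent", "incongruent"
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    if col not in events.columns or events[col].isna().any():
        raise ValueError(f"missing condition labels in column {col!r}")
    excluded = events.get("excluded", pd.Series(False, index=events.index))
    valid = events[~excluded]
    sel = valid[col].isin([a, b])
    sub = valid[sel]
    return pd.DataFrame(
        {
            "participant": sub["participant"].to_numpy(),
            "trial_index": sub["trial_index"].to_numpy(),
            "group": np.where(sub[col] == a, ga, gb),
            "scheme": contrast,
        }
    )
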