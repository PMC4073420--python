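"""Filtering and aggregation rules applied before any group statistics.

RT trimming is two-pass and order-matters: fast guesses (< 200 ms) are
dropped first so they cannot inflate the within-participant SD used by the
second pass, which removes RTs above mean + 2.5 SD of the remainder.  The
SD rule is one-sided (slow outliers only).  Error-based exclusion on the
symbolic task removes participants with strictly more than 20% errors.
The counting-strategy sensitivity filter for the duration task keeps only
trials whose reference/target difference is at most 1200 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import BinAccuracy
from .tasks import SYMBOLIC_TASK, TIME_TASK

MIN_RT_MS = 200.0
SD_MULTIPLIER = 2.5
ERROR_RATE_THRESHOLD = 0.20
COUNTING_WINDOW_MS = 1200.0

DEFAULT_SCOPE = ("participant_id", "task")


def _test_trials(df: pd.DataFrame) -> pd.DataFrame:
    if "is_practice" in df.columns:
        return df[~df["is_practice"].astype(bool)]
    return df


def trim_rts(
    df: pd.DataFrame,
    scope: tuple[str, ...] = DEFAULT_SCOPE,
    min_rt_ms: float = MIN_RT_MS,
    sd_multiplier: float = SD_MULTIPLIER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-pass RT trimming within each scope group.

    Pass 1 drops ``rt_ms < min_rt_ms``; pass 2 computes mean and SD
    (ddof=1) of the remainder per scope group and drops
    ``rt_ms > mean + sd_multiplier * SD``.  With fewer than two records
    surviving pass 1 the SD is undefined; pass 2 is skipped and the group
    flagged.  Returns (retained rows, removal log with one row per group).
    """
    if df.empty:
        log = pd.DataFrame(
            columns=[*scope, "n_input", "n_fast", "n_slow", "n_retained", "sd_skipped"]
        )
        return df.copy(), log

    keep = np.ones(len(df), dtype=bool)
    rt = df["rt_ms"].to_numpy(dtype=float)
    log_rows = []
    for key, idx in df.groupby(list(scope), dropna=False, sort=True).indices.items():
        key = key if isinstance(key, tuple) else (key,)
        grp_rt = rt[idx]
        fast = grp_rt < min_rt_ms
        survivors = grp_rt[~fast]
        sd_skipped = survivors.size < 2
        if sd_skipped:
            slow = np.zeros_like(fast)
        else:
            cutoff = survivors.mean() + sd_multiplier * survivors.std(ddof=1)
            slow = (~fast) & (grp_rt > cutoff)
        keep[idx[fast | slow]] = False
        log_rows.append(
            dict(
                zip(scope, key),
                n_input=int(grp_rt.size),
                n_fast=int(fast.sum()),
                n_slow=int(slow.sum()),
                n_retained=int(grp_rt.size - fast.sum() - slow.sum()),
                sd_skipped=bool(sd_skipped),
            )
        )
    return df[keep], pd.DataFrame(log_rows)


def bin_accuracies(df: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-ratio-bin accuracy for discrimination tasks.

    Practice trials are never counted.  Returns a tidy frame with columns
    participant_id, task, bin, ratio, n_trials, n_correct, accuracy.
    """
    test = _test_trials(df)
    test = test[test["bin"].notna()]
    grouped = (
        test.groupby(["participant_id", "task", "bin"], sort=True)
        .agg(
            ratio=("bin_ratio", "first"),
            n_trials=("correct", "size"),
            n_correct=("correct", "sum"),
        )
        .reset_index()
    )
    grouped["n_correct"] = grouped["n_correct"].astype(int)
    grouped["accuracy"] = grouped["n_correct"] / grouped["n_trials"]
    return grouped


def bins_for_participant(
    bin_table: pd.DataFrame, participant_id: str, task: str
) -> list[BinAccuracy]:
    """Convert one participant/task slice of :func:`bin_accuracies` output."""
    sel = bin_table[
        (bin_table["participant_id"] == participant_id) & (bin_table["task"] == task)
    ]
    return [
        BinAccuracy(ratio=row.ratio, n_trials=int(row.n_trials), n_correct=int(row.n_correct))
        for row in sel.itertuples()
    ]


def symbolic_clean(df: pd.DataFrame) -> pd.DataFrame:
    """Per-participant symbolic-task summary.

    The RT mean uses correct, RT-trimmed responses only; the error rate is
    computed over all test trials (before any trimming).  Returns columns
    participant_id, group, n_trials, n_errors, error_rate, mean_rt_ms,
    n_rt_used.
    """
    sym = _test_trials(df[df["task"] == SYMBOLIC_TASK])
    err = (
        sym.groupby(["participant_id", "group"], sort=True)
        .agg(n_trials=("correct", "size"), n_errors=("correct", lambda c: int((~c.astype(bool)).sum())))
        .reset_index()
    )
    err["error_rate"] = err["n_errors"] / err["n_trials"]

    correct = sym[sym["correct"].astype(bool)]
    trimmed, _ = trim_rts(correct, scope=("participant_id",))
    rts = (
        trimmed.groupby("participant_id", sort=True)
        .agg(mean_rt_ms=("rt_ms", "mean"), n_rt_used=("rt_ms", "size"))
        .reset_index()
    )
    return err.merge(rts, on="participant_id", how="left")


def exclude_high_error(
    summary: pd.DataFrame, threshold: float = ERROR_RATE_THRESHOLD
) -> tuple[pd.DataFrame, list[str]]:
    """Drop participants with error rate strictly above ``threshold``.

    Exactly 20% survives ("more than 20%" read as a strict inequality).
    Returns (kept rows, excluded participant ids).
    """
    bad = summary["error_rate"] > threshold
    return summary[~bad], summary.loc[bad, "participant_id"].tolist()


def distance_split(df: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean correct clean RT by numerical distance class.

    Feeds the 3 x 2 (group x distance) mixed ANOVA.  Participants missing a
    condition get NaN for it.  Returns participant_id, group,
    mean_rt_small, mean_rt_large.
    """
    sym = _test_trials(df[df["task"] == SYMBOLIC_TASK])
    correct = sym[sym["correct"].astype(bool)]
    trimmed, _ = trim_rts(correct, scope=("participant_id",))
    means = (
        trimmed.groupby(["participant_id", "group", "distance_class"], sort=True)["rt_ms"]
        .mean()
        .unstack("distance_class")
        .reindex(columns=["small", "large"])
        .rename(columns={"small": "mean_rt_small", "large": "mean_rt_large"})
        .reset_index()
    )
    means.columns.name = None
    return means


def filter_counting_window(
    df: pd.DataFrame, max_diff_ms: float = COUNTING_WINDOW_MS
) -> pd.DataFrame:
    """Keep duration trials with |target - reference| <= ``max_diff_ms``.

    Under the default design this removes the whole 1:2 bin (3000 ms
    difference both directions), leaving bins 3:4, 4:5 and 5:6.
    """
    is_time = df["task"] == TIME_TASK
    diff = (df["target_ms"] - df["reference_ms"]).abs()
    return df[~is_time | (diff <= max_diff_ms)]
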