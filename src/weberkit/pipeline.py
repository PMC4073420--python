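"""End-to-end orchestration: simulate -> preprocess -> fit -> analyze.

Every stage is a plain function over tidy DataFrames so the numbered
analysis drivers, the CLI and the tests all share one code path.  When an
output directory is given, each stage's inputs and outputs are written to
disk (CSV for tables, JSON for structured results) with the config digest
embedded, and every exclusion is logged with participant ids and the rule
that removed it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import preprocess, stats, tasks
from .config import RunConfig
from .model import InsufficientDataError, fit_weber
from .preprocess import bins_for_participant
from .simulate import RESPONSE_COLUMNS, GroupDataset, simulate_group_study
from .stats import MWResult, MixedAnovaResult, OutcomeReport


class SchemaError(ValueError):
    """A response table is missing required columns."""


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read a tidy response CSV, validating the column schema."""
    df = pd.read_csv(path)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"response table missing columns: {missing}")
    df["correct"] = df["correct"].astype(bool)
    df["is_practice"] = df["is_practice"].astype(bool)
    return df


def write_responses(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def fit_discrimination_sessions(
    responses: pd.DataFrame, r2_threshold: float | None = None
) -> pd.DataFrame:
    """Fit one Weber fraction per participant per discrimination task.

    Returns a tidy frame: participant_id, task, w, r_squared, converged,
    excluded, n_bins_used.
    """
    kwargs = {} if r2_threshold is None else {"r2_threshold": r2_threshold}
    bin_table = preprocess.bin_accuracies(responses)
    rows = []
    for (pid, task), _ in bin_table.groupby(["participant_id", "task"], sort=True):
        bins = bins_for_participant(bin_table, pid, task)
        try:
            est = fit_weber(bins, **kwargs)
        except InsufficientDataError:
            continue
        rows.append({"participant_id": pid, "task": task, **dataclasses.asdict(est)})
    return pd.DataFrame(rows)


def participant_summary(
    responses: pd.DataFrame,
    participants: pd.DataFrame,
    weber: pd.DataFrame,
    error_rate_threshold: float = preprocess.ERROR_RATE_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One row per participant with every analysis outcome.

    Applies the exclusion rules: poor-fit Weber estimates become NaN for
    that task, and symbolic RT outcomes are NaN for participants above the
    error-rate threshold.  Returns (summary, exclusion log).
    """
    out = participants.copy()
    exclusions: dict[str, list[str]] = {}

    for task, col in ((tasks.NUMBER_TASK, "w_number"), (tasks.TIME_TASK, "w_time")):
        sub = weber[weber["task"] == task].set_index("participant_id")
        out[col] = out["participant_id"].map(sub["w"])
        bad = sub.index[sub["excluded"]].tolist()
        out.loc[out["participant_id"].isin(bad), col] = np.nan
        exclusions[f"{col}_poor_fit"] = bad

    test = responses[~responses["is_practice"]]
    hits = (
        test[test["task"] == tasks.NUMBER_TASK]
        .groupby("participant_id")["correct"]
        .sum()
    )
    out["number_hits"] = out["participant_id"].map(hits).astype(float)

    sym = preprocess.symbolic_clean(responses)
    kept, high_error = preprocess.exclude_high_error(sym, error_rate_threshold)
    out["symbolic_rt"] = out["participant_id"].map(
        kept.set_index("participant_id")["mean_rt_ms"]
    )
    out["symbolic_error_rate"] = out["participant_id"].map(
        sym.set_index("participant_id")["error_rate"]
    )
    exclusions["symbolic_high_error"] = high_error

    enum = test[test["task"] == tasks.ENUMERATION_TASK]
    trimmed, _ = preprocess.trim_rts(enum, scope=("participant_id",))
    correct = trimmed[trimmed["correct"]]
    subit = correct[correct["n1"].isin(tasks.SUBITIZING_SIZES)]
    count = correct[correct["n1"].isin(tasks.ENUMERATION_SIZES)]
    out["subitizing_rt"] = out["participant_id"].map(
        subit.groupby("participant_id")["rt_ms"].mean()
    )
    out["enumeration_rt"] = out["participant_id"].map(
        count.groupby("participant_id")["rt_ms"].mean()
    )
    return out, exclusions


@dataclass
class PipelineResult:
    """Artifact bundle from one full run."""

    config: RunConfig
    dataset: GroupDataset
    removal_log: pd.DataFrame
    weber: pd.DataFrame
    summary: pd.DataFrame
    exclusions: dict[str, list[str]]
    reports: dict[str, OutcomeReport]
    distance_anova: MixedAnovaResult
    mann_whitney: dict[str, MWResult]
    fitted_group_means: pd.DataFrame


def analyze_dataset(dataset: GroupDataset, config: RunConfig) -> PipelineResult:
    """Preprocess, fit and compare groups for an in-memory dataset."""
    th = config.thresholds
    responses = dataset.responses
    _, removal_log = preprocess.trim_rts(responses[~responses["is_practice"]])
    weber = fit_discrimination_sessions(responses, r2_threshold=th.r2_exclusion)
    summary, exclusions = participant_summary(
        responses, dataset.participants, weber, th.error_rate_threshold
    )
    reports = stats.analysis_policy(
        summary,
        config.stats.outcomes,
        alpha=config.stats.alpha,
        levene_center=config.stats.levene_center,
    )
    splits = preprocess.distance_split(responses)
    splits = splits[~splits["participant_id"].isin(exclusions["symbolic_high_error"])]
    distance_anova = stats.mixed_anova_distance(splits)

    # Rank-based comparisons and descriptive group means of the fitted w
    # use every converged fit: the rank test is insensitive to extreme
    # (clipped) estimates, so the poor-fit exclusion is not applied here.
    fitted = weber[weber["converged"]].merge(
        dataset.participants[["participant_id", "group"]], on="participant_id"
    )
    fitted_group_means = (
        fitted.groupby(["task", "group"])["w"].agg(["mean", "median", "std", "size"])
        .reset_index()
    )
    mw: dict[str, MWResult] = {}
    for task, label in ((tasks.NUMBER_TASK, "w_number"), (tasks.TIME_TASK, "w_time")):
        sub = fitted[fitted["task"] == task]
        for a, b in (("DD", "TA4"), ("DD", "TA2")):
            wa = sub.loc[sub["group"] == a, "w"]
            wb = sub.loc[sub["group"] == b, "w"]
            if len(wa) and len(wb):
                mw[f"{label}_{a}_vs_{b}"] = stats.mann_whitney(wa, wb)

    return PipelineResult(
        config=config, dataset=dataset, removal_log=removal_log, weber=weber,
        summary=summary, exclusions=exclusions, reports=reports,
        distance_anova=distance_anova, mann_whitney=mw,
        fitted_group_means=fitted_group_means,
    )


def run_pipeline(config: RunConfig | None = None, outdir: str | Path | None = None) -> PipelineResult:
    """Simulate a study under ``config`` and analyze it end to end."""
    config = config or RunConfig()
    dataset = simulate_group_study(config.groups, config.seed)
    result = analyze_dataset(dataset, config)
    if outdir is not None:
        write_bundle(result, outdir)
    return result


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 4)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def results_to_dict(result: PipelineResult) -> dict:
    """Structured, JSON-ready view of every statistical result."""
    return {
        "config_digest": result.config.digest(),
        "seed": result.config.seed,
        "outcomes": {k: _jsonable(v) for k, v in result.reports.items()},
        "distance_mixed_anova": _jsonable(result.distance_anova),
        "mann_whitney": {k: _jsonable(v) for k, v in result.mann_whitney.items()},
        "exclusions": result.exclusions,
    }


def format_report(result: PipelineResult) -> str:
    """Markdown report shaped like a group-descriptives table with
    significance flags, followed by the test statistics."""
    group_labels = sorted(result.summary["group"].unique())
    lines = [
        f"# Group comparison report (seed {result.config.seed}, "
        f"config {result.config.digest()})",
        "",
        "| Outcome | " + " | ".join(f"{g} M (SD)" for g in group_labels)
        + " | test | F | df | p | partial eta^2 | sig. pairs |",
        "|---|" + "---|" * (len(group_labels) + 6),
    ]
    for name, rep in result.reports.items():
        cells = [name]
        for g in sorted(rep.group_means):
            cells.append(f"{rep.group_means[g]:.4f} ({rep.group_sds[g]:.4f})")
        method = rep.anova.correction if rep.anova.correction != "none" else (
            "ancova" if rep.covariates_used else "anova"
        )
        sig = [
            f"{p.group_a}-{p.group_b}" for p in rep.posthoc if p.p < 0.05
        ]
        cells += [
            method,
            f"{rep.anova.F:.4f}",
            f"({rep.anova.df1:.0f}, {rep.anova.df2:.1f})",
            f"{rep.anova.p:.4f}",
            f"{rep.anova.partial_eta_sq:.4f}",
            ", ".join(sig) or "none",
        ]
        lines.append("| " + " | ".join(cells) + " |")
    d = result.distance_anova
    lines += [
        "",
        "Distance (small vs large) mixed ANOVA: "
        f"group F({d.between.df1:.0f}, {d.between.df2:.0f}) = {d.between.F:.4f}, "
        f"p = {d.between.p:.4f}; distance F({d.within.df1:.0f}, {d.within.df2:.0f}) "
        f"= {d.within.F:.4f}, p = {d.within.p:.4f}; interaction p = {d.interaction.p:.4f}.",
    ]
    for label, mwr in result.mann_whitney.items():
        lines.append(
            f"Mann-Whitney {label}: U = {mwr.U:.1f}, z = {mwr.z:.4f}, "
            f"p = {mwr.p:.4f}, r = {mwr.r:.4f}."
        )
    return "\n".join(lines) + "\n"


def write_bundle(result: PipelineResult, outdir: str | Path) -> None:
    """Write every stage artifact of a run to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "config.yaml")
    write_responses(result.dataset.responses, outdir / "responses.csv")
    result.dataset.participants.to_csv(outdir / "participants.csv", index=False)
    result.removal_log.to_csv(outdir / "rt_removal_log.csv", index=False)
    result.weber.to_csv(outdir / "weber_estimates.csv", index=False)
    result.summary.to_csv(outdir / "participant_summary.csv", index=False)
    (outdir / "stats_results.json").write_text(
        json.dumps(results_to_dict(result), indent=2)
    )
    (outdir / "report.md").write_text(format_report(result))
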