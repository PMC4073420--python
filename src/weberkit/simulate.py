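"""Synthetic observers: latent acuities, model-driven choices, nuisance RTs.

Participants are sampled per group (DD = developmental dyscalculia, TA4 =
age-matched typical achievers, TA2 = younger ability-matched typical
achievers) with latent Weber fractions drawn from log-normal distributions
moment-matched to the group means and SDs reported for school-age cohorts
(number w 0.89/0.26/0.49, time w 0.66/0.28/0.46 for DD/TA4/TA2), which
captures the positive skew such samples show.  Choices on the two
discrimination tasks are sampled from the same Gaussian representation the
analysis fits, so long-run simulated accuracy equals the closed-form
prediction.  RTs are nuisance data — log-normal around a per-task median
with fast-guess and slow-outlier contaminants — present only so the
trimming rules have something to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import tasks
from .tasks import (
    ENUMERATION_TASK,
    NUMBER_TASK,
    SYMBOLIC_TASK,
    TIME_TASK,
    TrialSpec,
)

DEFAULT_SEED = 20140675

RESPONSE_COLUMNS = [
    "participant_id", "group", "task", "trial_index", "is_practice",
    "n1", "n2", "bin", "bin_ratio", "distance_class",
    "reference_ms", "target_ms", "response", "correct", "rt_ms",
]


@dataclass(frozen=True)
class RTModel:
    """Log-normal base RT with contaminants.

    ``median_ms`` maps task name to the base median; fast guesses are
    uniform on [80, 199) ms, slow outliers uniform on [5, 8) x median.
    ``small_distance_factor`` slows symbolic small-distance trials, giving
    the distance effect in RT.
    """

    median_ms: dict[str, float]
    log_sd: float = 0.30
    fast_guess_rate: float = 0.02
    slow_outlier_rate: float = 0.02
    small_distance_factor: float = 1.17
    subitizing_median_ms: float = 1200.0
    enumeration_median_ms: float = 3500.0


@dataclass(frozen=True)
class GroupParams:
    """Generating parameters for one group.

    ``w_number`` / ``w_time`` are (mean, sd) targets of the latent
    log-normal acuity distributions; ``covariate_rpm`` is the nonverbal-IQ
    raw score (truncated normal on [0, 36]); ``covariate_ran`` the
    colour-naming time in seconds (truncated normal on [15, 120]).
    ``w_symbolic`` reuses the Gaussian comparison model on digit
    magnitudes; ``enumeration_error`` is the per-trial error probability
    for set sizes 5-8 (sizes 1-4 are error-free).
    """

    name: str
    n_participants: int
    w_number: tuple[float, float]
    w_time: tuple[float, float]
    covariate_rpm: tuple[float, float]
    covariate_ran: tuple[float, float]
    rt_model: RTModel
    w_symbolic: float = 0.10
    enumeration_error: float = 0.03


def _default_rt(symbolic_median: float, subit: float, enum_: float) -> RTModel:
    return RTModel(
        median_ms={
            NUMBER_TASK: 1578.0,
            TIME_TASK: 800.0,
            SYMBOLIC_TASK: symbolic_median,
        },
        subitizing_median_ms=subit,
        enumeration_median_ms=enum_,
    )


DEFAULT_GROUPS: tuple[GroupParams, ...] = (
    GroupParams(
        name="DD", n_participants=19,
        w_number=(0.89, 0.89), w_time=(0.66, 0.43),
        covariate_rpm=(18.42, 6.17), covariate_ran=(59.16, 14.75),
        rt_model=_default_rt(1054.0, 1198.0, 3560.0),
        w_symbolic=0.115, enumeration_error=0.06,
    ),
    GroupParams(
        name="TA4", n_participants=32,
        w_number=(0.26, 0.11), w_time=(0.28, 0.18),
        covariate_rpm=(25.69, 3.30), covariate_ran=(44.88, 8.90),
        rt_model=_default_rt(891.0, 1181.0, 3200.0),
        w_symbolic=0.10, enumeration_error=0.02,
    ),
    GroupParams(
        name="TA2", n_participants=31,
        w_number=(0.49, 0.32), w_time=(0.46, 0.30),
        covariate_rpm=(21.55, 5.32), covariate_ran=(53.35, 10.82),
        rt_model=_default_rt(1162.0, 1207.0, 3740.0),
        w_symbolic=0.12, enumeration_error=0.045,
    ),
)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and sd."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


@dataclass
class ParticipantSession:
    participant_id: str
    group: str
    true_w_number: float
    true_w_time: float
    rpm: float
    ran: float
    responses: pd.DataFrame | None = None


def sample_participant(
    params: GroupParams, rng: np.random.Generator, participant_id: str = "p0"
) -> ParticipantSession:
    """Draw one participant's latent acuities and covariates (no responses)."""
    mu_n, sg_n = lognormal_params(*params.w_number)
    mu_t, sg_t = lognormal_params(*params.w_time)
    return ParticipantSession(
        participant_id=participant_id,
        group=params.name,
        true_w_number=float(rng.lognormal(mu_n, sg_n)),
        true_w_time=float(rng.lognormal(mu_t, sg_t)),
        rpm=_truncated_normal(*params.covariate_rpm, 0.0, 36.0, rng),
        ran=_truncated_normal(*params.covariate_ran, 15.0, 120.0, rng),
    )


def sample_choices(
    n1: np.ndarray, n2: np.ndarray, w: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized Gaussian-comparison choices; True where correct.

    Internal draws are N(n, w*n) per magnitude; the response follows the
    larger draw, ties (measure zero) resolved by a fair coin.
    """
    if w <= 0:
        raise ValueError("w must be > 0")
    d1 = rng.normal(n1, w * np.asarray(n1, dtype=float))
    d2 = rng.normal(n2, w * np.asarray(n2, dtype=float))
    correct = d1 > d2
    ties = d1 == d2
    if np.any(ties):
        correct = np.where(ties, rng.integers(2, size=correct.shape) == 1, correct)
    return correct


def simulate_choice(trial: TrialSpec, w_true: float, rng: np.random.Generator) -> bool:
    """Single-trial convenience wrapper around :func:`sample_choices`."""
    return bool(sample_choices(np.array([trial.n1]), np.array([trial.n2]), w_true, rng)[0])


def simulate_rt(
    medians: np.ndarray, rt_model: RTModel, rng: np.random.Generator
) -> np.ndarray:
    """Sample RTs: log-normal base, contaminated by fast guesses and
    slow outliers at the model's stated rates."""
    n = len(medians)
    rt = medians * np.exp(rng.normal(0.0, rt_model.log_sd, size=n))
    u = rng.random(n)
    fast = u < rt_model.fast_guess_rate
    slow = (u >= rt_model.fast_guess_rate) & (
        u < rt_model.fast_guess_rate + rt_model.slow_outlier_rate
    )
    rt[fast] = rng.uniform(80.0, 199.0, size=int(fast.sum()))
    rt[slow] = medians[slow] * rng.uniform(5.0, 8.0, size=int(slow.sum()))
    return rt


def _task_medians(trials_df: pd.DataFrame, task: str, rt_model: RTModel) -> np.ndarray:
    if task == SYMBOLIC_TASK:
        base = rt_model.median_ms[task]
        factor = np.where(
            trials_df["distance_class"].to_numpy() == "small",
            rt_model.small_distance_factor, 1.0,
        )
        return base * factor
    if task == ENUMERATION_TASK:
        size = trials_df["n1"].to_numpy()
        med = np.where(
            size <= 3, rt_model.subitizing_median_ms, rt_model.enumeration_median_ms
        )
        mid = 0.5 * (rt_model.subitizing_median_ms + rt_model.enumeration_median_ms)
        return np.where(size == 4, mid, med).astype(float)
    return np.full(len(trials_df), rt_model.median_ms[task], dtype=float)


def _other_side(side: str) -> str:
    return {"blue": "yellow", "yellow": "blue", "left": "right", "right": "left"}[side]


def _simulate_task_responses(
    df: pd.DataFrame,
    task: str,
    session: ParticipantSession,
    params: GroupParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(response, correct) arrays for one participant on one task frame."""
    n = len(df)
    if task == NUMBER_TASK:
        correct = sample_choices(
            df["n1"].to_numpy(), df["n2"].to_numpy(), session.true_w_number, rng
        )
        response = np.where(
            correct,
            df["majority_side"].to_numpy(),
            [_other_side(s) for s in df["majority_side"]],
        )
    elif task == TIME_TASK:
        correct = sample_choices(
            df["n1"].to_numpy(), df["n2"].to_numpy(), session.true_w_time, rng
        )
        longer_is_target = df["target_ms"].to_numpy() > df["reference_ms"].to_numpy()
        response = np.where(correct == longer_is_target, "target", "reference")
    elif task == SYMBOLIC_TASK:
        correct = sample_choices(
            df["n1"].to_numpy(), df["n2"].to_numpy(), params.w_symbolic, rng
        )
        response = np.where(
            correct,
            df["majority_side"].to_numpy(),
            [_other_side(s) for s in df["majority_side"]],
        )
    else:  # enumeration: report a count
        size = df["n1"].to_numpy()
        wrong = rng.random(n) < np.where(size >= 5, params.enumeration_error, 0.0)
        off = rng.choice([-1.0, 1.0], size=n)
        reported = np.where(wrong, np.clip(size + off, 1, None), size)
        correct = ~wrong
        response = reported.astype(int).astype(str)
    return response.astype(object), np.asarray(correct, dtype=bool)


def _tidy_task_frame(
    df: pd.DataFrame,
    task: str,
    session: ParticipantSession,
    response: np.ndarray,
    correct: np.ndarray,
    rt: np.ndarray,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": session.participant_id,
            "group": session.group,
            "task": task,
            "trial_index": df["trial_index"].to_numpy(int),
            "is_practice": df["is_practice"].to_numpy(bool),
            "n1": df["n1"].to_numpy(float),
            "n2": df["n2"].to_numpy(float),
            "bin": df["bin_label"].astype(object).where(df["bin_label"].notna(), np.nan),
            "bin_ratio": df["bin_ratio"].to_numpy(float),
            "distance_class": df["distance_class"]
            .astype(object)
            .where(df["distance_class"].notna(), np.nan),
            "reference_ms": df["reference_ms"].to_numpy(float),
            "target_ms": df["target_ms"].to_numpy(float),
            "response": response,
            "correct": correct,
            "rt_ms": rt,
        }
    )


def simulate_session(
    session: ParticipantSession,
    params: GroupParams,
    rng: np.random.Generator,
    trial_seed: int,
) -> pd.DataFrame:
    """Simulate all four tasks for one participant; returns a tidy frame."""
    frames = []
    for task, trial_list in tasks.all_task_trials(trial_seed).items():
        df = tasks.trials_to_frame(trial_list)
        response, correct = _simulate_task_responses(df, task, session, params, rng)
        rt = simulate_rt(_task_medians(df, task, params.rt_model), params.rt_model, rng)
        frames.append(_tidy_task_frame(df, task, session, response, correct, rt))
    return pd.concat(frames, ignore_index=True)


@dataclass
class GroupDataset:
    """A full simulated study: tidy responses plus a participant table."""

    responses: pd.DataFrame
    participants: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GroupDataset)
            and self.responses.equals(other.responses)
            and self.participants.equals(other.participants)
        )


def simulate_group_study(
    groups: tuple[GroupParams, ...] = DEFAULT_GROUPS,
    seed: int = DEFAULT_SEED,
) -> GroupDataset:
    """Simulate every participant in every group; deterministic per seed.

    As in a live administration, all participants receive the same trial
    tables (one design drawn from the study seed); participant-level
    draws come from independent child RNG streams, so changing one
    group's size never perturbs another participant's data.
    """
    master = np.random.SeedSequence(seed)
    design_stream = master.spawn(1)[0]
    design_seed = int(design_stream.generate_state(1)[0] % (2**31))
    task_frames = {
        task: tasks.trials_to_frame(tl)
        for task, tl in tasks.all_task_trials(design_seed).items()
    }

    response_frames, participant_rows = [], []
    pid = 0
    for params in groups:
        for _ in range(params.n_participants):
            rng = np.random.default_rng(master.spawn(1)[0])
            session = sample_participant(params, rng, participant_id=f"P{pid:03d}")
            for task, df in task_frames.items():
                response, correct = _simulate_task_responses(
                    df, task, session, params, rng
                )
                rt = simulate_rt(
                    _task_medians(df, task, params.rt_model), params.rt_model, rng
                )
                response_frames.append(
                    _tidy_task_frame(df, task, session, response, correct, rt)
                )
            participant_rows.append(
                {
                    "participant_id": session.participant_id,
                    "group": session.group,
                    "true_w_number": session.true_w_number,
                    "true_w_time": session.true_w_time,
                    "rpm": session.rpm,
                    "ran": session.ran,
                }
            )
            pid += 1
    return GroupDataset(
        responses=pd.concat(response_frames, ignore_index=True)[RESPONSE_COLUMNS],
        participants=pd.DataFrame(participant_rows),
    )
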