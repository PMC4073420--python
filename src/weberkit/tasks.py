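"""Trial-set generators for the four behavioural tasks.

Each generator is deterministic given a seed and returns a list of
:class:`TrialSpec`.  Counts and constraints follow the study designs:

* numerosity discrimination — 5 practice + 75 test trials, dot counts in
  5-16, ratio bins 1:2 / 3:4 / 5:6 / 7:8, majority colour and
  area-equating each balanced over halves of the test trials;
* duration discrimination — 4 practice + 60 test trials, a 3000 ms
  reference against targets in 1500-6000 ms, ratio bins 1:2 / 3:4 / 4:5 /
  5:6, 15 trials per bin;
* symbolic digit comparison — 32 trials, single digits 1-9, numerical
  distance 1 ("small") vs 4-5 ("large"), left/right counterbalanced;
* enumeration — 24 trials, set sizes 1-8 three times each, randomized;
  sizes 1-3 index subitizing, 5-8 counting/enumeration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

NUMBER_TASK = "number_discrimination"
TIME_TASK = "time_discrimination"
SYMBOLIC_TASK = "symbolic_comparison"
ENUMERATION_TASK = "enumeration"

#: Exact-ratio integer dot pairs with both counts in 5..16, per bin.
NUMBER_BIN_PAIRS: dict[str, list[tuple[int, int]]] = {
    "1:2": [(10, 5), (12, 6), (14, 7), (16, 8)],
    "3:4": [(8, 6), (12, 9), (16, 12)],
    "5:6": [(6, 5), (12, 10)],
    "7:8": [(8, 7), (16, 14)],
}

#: 75 test trials are not divisible by 4 bins; the hardest bin gets 18.
NUMBER_BIN_COUNTS: dict[str, int] = {"1:2": 19, "3:4": 19, "5:6": 19, "7:8": 18}

NUMBER_PRESENTATION_MS = 800
TIME_REFERENCE_MS = 3000
TIME_BIN_LABELS = ("1:2", "3:4", "4:5", "5:6")
TIME_TRIALS_PER_BIN = 15
DOT_RANGE = (5, 16)


def _bin_ratio(label: str) -> float:
    small, large = (int(p) for p in label.split(":"))
    return large / small


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial. Fields not applicable to a task are None."""

    task: str
    trial_index: int
    is_practice: bool
    n1: float  # larger magnitude (dots, ms, or digit); set size for enumeration
    n2: float | None
    bin_label: str | None = None
    bin_ratio: float | None = None
    majority_side: str | None = None  # blue/yellow or left/right
    area_equated: bool | None = None
    distance_class: str | None = None  # small / large (symbolic task)
    reference_ms: float | None = None
    target_ms: float | None = None
    presentation_ms: float | None = None


@dataclass(frozen=True)
class DotRenderSpec:
    """Per-dot radii (mm) realizing an area-equated two-colour array."""

    radii_majority: tuple[float, ...]
    radii_minority: tuple[float, ...]

    @property
    def area_majority(self) -> float:
        return float(sum(math.pi * r**2 for r in self.radii_majority))

    @property
    def area_minority(self) -> float:
        return float(sum(math.pi * r**2 for r in self.radii_minority))


def _balanced_halves(n: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean vector of length n with ceil/floor(n/2) True, shuffled."""
    n_true = n // 2 + (int(rng.integers(2)) if n % 2 else 0)
    flags = np.zeros(n, dtype=bool)
    flags[:n_true] = True
    rng.shuffle(flags)
    return flags


def numerosity_trials(seed: int = 0) -> list[TrialSpec]:
    """5 practice + 75 test trials of blue/yellow dot-array discrimination."""
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    pairs: list[tuple[int, int]] = []
    for label, count in NUMBER_BIN_COUNTS.items():
        cycle = itertools.cycle(NUMBER_BIN_PAIRS[label])
        for _ in range(count):
            labels.append(label)
            pairs.append(next(cycle))
    order = rng.permutation(len(pairs))
    blue_majority = _balanced_halves(len(pairs), rng)
    equated = _balanced_halves(len(pairs), rng)

    trials = [
        TrialSpec(
            task=NUMBER_TASK,
            trial_index=i,
            is_practice=True,
            n1=p[0],
            n2=p[1],
            bin_label=lab,
            bin_ratio=_bin_ratio(lab),
            majority_side="blue" if i % 2 == 0 else "yellow",
            area_equated=bool(i % 2),
            presentation_ms=NUMBER_PRESENTATION_MS,
        )
        for i, (lab, p) in enumerate(
            [("1:2", (12, 6)), ("3:4", (8, 6)), ("5:6", (12, 10)),
             ("7:8", (16, 14)), ("1:2", (10, 5))]
        )
    ]
    for i, k in enumerate(order):
        lab, p = labels[k], pairs[k]
        trials.append(
            TrialSpec(
                task=NUMBER_TASK,
                trial_index=i,
                is_practice=False,
                n1=p[0],
                n2=p[1],
                bin_label=lab,
                bin_ratio=_bin_ratio(lab),
                majority_side="blue" if blue_majority[i] else "yellow",
                area_equated=bool(equated[i]),
                presentation_ms=NUMBER_PRESENTATION_MS,
            )
        )
    return trials


def area_equate(
    n_majority: int,
    n_minority: int,
    base_radius_mm: float = 2.5,
    jitter: float = 0.3,
    rng: np.random.Generator | None = None,
) -> DotRenderSpec:
    """Radii for the two colours so that their total surface areas match.

    Each colour's dot radii are jittered uniformly by +-``jitter`` and then
    rescaled so that its total area equals ``n_mean * pi * base_radius^2``
    with ``n_mean = (n_majority + n_minority) / 2``; the two totals are thus
    equal by construction, and the more numerous colour necessarily has the
    smaller mean dot size.
    """
    if base_radius_mm <= 0:
        raise ValueError("base_radius_mm must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    target_area = 0.5 * (n_majority + n_minority) * math.pi * base_radius_mm**2

    def one_colour(n: int) -> tuple[float, ...]:
        r = base_radius_mm * (1.0 + rng.uniform(-jitter, jitter, size=n))
        r *= math.sqrt(target_area / float(np.sum(math.pi * r**2)))
        return tuple(float(v) for v in r)

    return DotRenderSpec(one_colour(n_majority), one_colour(n_minority))


def duration_trials(seed: int = 0) -> list[TrialSpec]:
    """4 practice + 60 test trials of reference-vs-target duration judgment."""
    rng = np.random.default_rng(seed)
    specs: list[tuple[str, float]] = []
    for b, label in enumerate(TIME_BIN_LABELS):
        r = _bin_ratio(label)
        longer = round(TIME_REFERENCE_MS * r)
        shorter = round(TIME_REFERENCE_MS / r)
        # 15 per bin cannot split evenly; alternate across bins which
        # direction (longer vs shorter target) receives the extra trial.
        n_long = 8 if b % 2 == 0 else 7
        specs += [(label, float(longer))] * n_long
        specs += [(label, float(shorter))] * (TIME_TRIALS_PER_BIN - n_long)
    order = rng.permutation(len(specs))

    def make(i: int, label: str, target: float, practice: bool) -> TrialSpec:
        return TrialSpec(
            task=TIME_TASK,
            trial_index=i,
            is_practice=practice,
            n1=max(target, TIME_REFERENCE_MS),
            n2=min(target, TIME_REFERENCE_MS),
            bin_label=label,
            bin_ratio=_bin_ratio(label),
            reference_ms=float(TIME_REFERENCE_MS),
            target_ms=target,
        )

    practice = [("1:2", 6000.0), ("3:4", 2250.0), ("4:5", 3750.0), ("5:6", 2500.0)]
    trials = [make(i, lab, t, True) for i, (lab, t) in enumerate(practice)]
    trials += [make(i, *specs[k], False) for i, k in enumerate(order)]
    return trials


def symbolic_trials(seed: int = 0) -> list[TrialSpec]:
    """32 digit-comparison trials: 8 pairs per distance class, each twice."""
    rng = np.random.default_rng(seed)
    small = [(d, d + 1) for d in range(1, 9)]  # all 8 distance-1 pairs
    large_all = [
        (a, b) for a, b in itertools.combinations(range(1, 10), 2) if b - a in (4, 5)
    ]
    large = [large_all[i] for i in sorted(rng.choice(len(large_all), 8, replace=False))]

    plan: list[tuple[int, int, str, str]] = []
    for cls, pairs in (("small", small), ("large", large)):
        for lo, hi in pairs:
            plan.append((hi, lo, cls, "left"))
            plan.append((hi, lo, cls, "right"))
    order = rng.permutation(len(plan))
    return [
        TrialSpec(
            task=SYMBOLIC_TASK,
            trial_index=i,
            is_practice=False,
            n1=float(plan[k][0]),
            n2=float(plan[k][1]),
            distance_class=plan[k][2],
            majority_side=plan[k][3],
        )
        for i, k in enumerate(order)
    ]


def enumeration_trials(seed: int = 0) -> list[TrialSpec]:
    """24 dot-counting trials: set sizes 1-8, three repetitions, randomized."""
    rng = np.random.default_rng(seed)
    sizes = np.repeat(np.arange(1, 9), 3)
    rng.shuffle(sizes)
    return [
        TrialSpec(
            task=ENUMERATION_TASK,
            trial_index=i,
            is_practice=False,
            n1=float(s),
            n2=None,
        )
        for i, s in enumerate(sizes)
    ]


SUBITIZING_SIZES = (1, 2, 3)
ENUMERATION_SIZES = (5, 6, 7, 8)


def all_task_trials(seed: int = 0) -> dict[str, list[TrialSpec]]:
    """One trial set per task, from independent child streams of ``seed``."""
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    return {
        NUMBER_TASK: numerosity_trials(seeds[0]),
        TIME_TASK: duration_trials(seeds[1]),
        SYMBOLIC_TASK: symbolic_trials(seeds[2]),
        ENUMERATION_TASK: enumeration_trials(seeds[3]),
    }


def trials_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    """Tidy table, one row per trial."""
    return pd.DataFrame([t.__dict__ for t in trials])
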