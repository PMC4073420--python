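"""Gaussian magnitude-representation model and Weber-fraction estimation.

Two magnitudes (dot counts, or durations in ms) are represented internally
as Gaussian random variables with means ``n1``, ``n2`` and standard
deviations ``w * n1``, ``w * n2`` — scalar variability with a single Weber
fraction ``w``.  Discrimination accuracy follows from the distribution of
the difference of the two representations:

    error(n1, n2, w) = 1/2 * erfc( (n1 - n2) / (sqrt(2) * w * sqrt(n1^2 + n2^2)) )

Accuracy depends on the two magnitudes only through their ratio, so a
participant's ``w`` is estimated by nonlinear least squares on the mean
accuracy per ratio bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special

#: Fits with r-squared below this are flagged as excluded.
R_SQUARED_EXCLUSION = 0.2

#: Box constraint on w during fitting; generous upper margin over the
#: largest group means seen in school-age cohorts (~0.9).
W_BOUNDS = (1e-4, 5.0)

#: Coarse log-spaced scan used to initialize the LM polish; the SSE in w
#: can be multimodal for very noisy sessions, so a basin search precedes
#: the local optimizer.
_SCAN_GRID = np.geomspace(W_BOUNDS[0], W_BOUNDS[1], 200)


class InvalidParameterError(ValueError):
    """A magnitude or Weber fraction outside its valid domain."""


class InsufficientDataError(ValueError):
    """Too few ratio bins to fit a Weber fraction."""


@dataclass(frozen=True)
class MagnitudePair:
    """An ordered pair of magnitudes, larger first.

    Units are arbitrary (dot counts or milliseconds); the model is
    scale-free so they never matter beyond validity checks.
    """

    n1: float
    n2: float

    def __post_init__(self) -> None:
        if not (self.n1 >= self.n2 > 0):
            raise InvalidParameterError(
                f"require n1 >= n2 > 0, got n1={self.n1}, n2={self.n2}"
            )

    @property
    def ratio(self) -> float:
        return self.n1 / self.n2


@dataclass(frozen=True)
class BinAccuracy:
    """Aggregate accuracy for one ratio bin."""

    ratio: float
    n_trials: int
    n_correct: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct <= self.n_trials):
            raise InvalidParameterError(
                f"require 0 <= n_correct <= n_trials, got {self.n_correct}/{self.n_trials}"
            )

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_trials


@dataclass(frozen=True)
class WeberEstimate:
    """A fitted Weber fraction with fit-quality bookkeeping.

    ``excluded`` is true iff the fit failed to converge or its r-squared
    fell below :data:`R_SQUARED_EXCLUSION` (strict inequality).
    ``degenerate_r2`` marks sessions whose bin accuracies were flat, where
    r-squared is defined as 0.
    """

    w: float
    r_squared: float
    converged: bool
    excluded: bool
    n_bins_used: int
    degenerate_r2: bool = False


def _validate_w(w: float) -> None:
    if not np.all(np.asarray(w) > 0):
        raise InvalidParameterError(f"Weber fraction must be > 0, got {w}")


def difference_distribution(pair: MagnitudePair, w: float) -> tuple[float, float]:
    """Mean and sd of the difference of the two internal Gaussians.

    Returns ``(n1 - n2, w * sqrt(n1**2 + n2**2))``.
    """
    _validate_w(w)
    return pair.n1 - pair.n2, w * math.hypot(pair.n1, pair.n2)


def predicted_error(pair: MagnitudePair, w: float) -> float:
    """Probability of choosing the smaller magnitude; in [0, 0.5]."""
    mean, sd = difference_distribution(pair, w)
    return 0.5 * special.erfc(mean / (math.sqrt(2.0) * sd))


def predicted_accuracy(pair: MagnitudePair, w: float) -> float:
    """1 minus the modeled error rate; in [0.5, 1]."""
    return 1.0 - predicted_error(pair, w)


def predicted_accuracy_for_ratio(ratio, w):
    """Predicted accuracy for any pair with the given ratio (> 1).

    The discriminability statistic (n1 - n2) / sqrt(n1^2 + n2^2) equals
    (r - 1) / sqrt(r^2 + 1), so accuracy is a function of the ratio alone.
    Vectorized over ``ratio`` and ``w``.
    """
    ratio = np.asarray(ratio, dtype=float)
    w = np.asarray(w, dtype=float)
    if not np.all(ratio > 1.0):
        raise InvalidParameterError(f"ratio must be > 1, got {ratio}")
    _validate_w(w)
    d = (ratio - 1.0) / np.sqrt(ratio**2 + 1.0)
    out = 1.0 - 0.5 * special.erfc(d / (np.sqrt(2.0) * w))
    return out if out.ndim else float(out)


def goodness_of_fit(
    bins: Sequence[BinAccuracy], w: float
) -> tuple[float, bool]:
    """r-squared of the model at ``w`` against the bin accuracies.

    ``SS_tot`` is taken about the mean bin accuracy, so r-squared may be
    negative.  Flat accuracies make ``SS_tot`` zero; then r-squared is
    defined as 0 and the degenerate flag is set.
    """
    acc = np.array([b.accuracy for b in bins])
    pred = predicted_accuracy_for_ratio(np.array([b.ratio for b in bins]), w)
    ss_res = float(np.sum((acc - pred) ** 2))
    ss_tot = float(np.sum((acc - acc.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0, True
    return 1.0 - ss_res / ss_tot, False


def _sse(bins_ratio: np.ndarray, bins_acc: np.ndarray, w: float) -> float:
    pred = predicted_accuracy_for_ratio(bins_ratio, w)
    return float(np.sum((bins_acc - pred) ** 2))


def fit_weber(
    bins: Iterable[BinAccuracy],
    r2_threshold: float = R_SQUARED_EXCLUSION,
) -> WeberEstimate:
    """Estimate w by Levenberg-Marquardt least squares on per-bin accuracy.

    The objective is the unweighted sum of squared deviations between each
    bin's mean accuracy and the model prediction at that bin's ratio.  A
    coarse log-spaced scan locates the SSE basin (the objective can be
    multimodal for very noisy sessions); the LM polish then runs in
    log(w), so positivity is structural, and the result is clipped into
    :data:`W_BOUNDS`.
    """
    bins = list(bins)
    bins = [b for b in bins if b.n_trials > 0]
    ratios = np.array([b.ratio for b in bins])
    if len(set(ratios.tolist())) < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct ratio bins with trials, got {len(bins)}"
        )
    acc = np.array([b.accuracy for b in bins])

    def residuals(theta: np.ndarray) -> np.ndarray:
        return acc - predicted_accuracy_for_ratio(ratios, np.exp(theta[0]))

    scan_pred = predicted_accuracy_for_ratio(ratios[None, :], _SCAN_GRID[:, None])
    scan_sse = np.sum((acc[None, :] - scan_pred) ** 2, axis=1)
    w_start = float(_SCAN_GRID[int(np.argmin(scan_sse))])

    sol = optimize.least_squares(
        residuals, x0=[math.log(w_start)], method="lm", xtol=1e-12, ftol=1e-12
    )
    w_polished = float(np.clip(math.exp(sol.x[0]), *W_BOUNDS))
    converged = bool(sol.success)
    # keep the polish only if it actually improved on the scan optimum
    if _sse(ratios, acc, w_polished) <= float(np.min(scan_sse)):
        best_w = w_polished
    else:
        best_w = w_start

    r2, degenerate = goodness_of_fit(bins, best_w)
    excluded = (not converged) or (r2 < r2_threshold)
    return WeberEstimate(
        w=best_w,
        r_squared=r2,
        converged=converged,
        excluded=excluded,
        n_bins_used=len(bins),
        degenerate_r2=degenerate,
    )


def grid_fit_weber(
    bins: Iterable[BinAccuracy],
    step: float = 1e-4,
    bounds: tuple[float, float] = W_BOUNDS,
) -> float:
    """Brute-force grid minimizer of the same SSE objective.

    Independent of :func:`fit_weber`'s optimizer; used as a cross-check.
    The grid spans the fitting box at the given step.
    """
    bins = [b for b in bins if b.n_trials > 0]
    ratios = np.array([b.ratio for b in bins])
    acc = np.array([b.accuracy for b in bins])
    grid = np.arange(round(bounds[0] / step), round(bounds[1] / step) + 1) * step
    pred = predicted_accuracy_for_ratio(ratios[None, :], grid[:, None])
    sse = np.sum((acc[None, :] - pred) ** 2, axis=1)
    return float(grid[int(np.argmin(sse))])
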