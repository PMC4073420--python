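"""Group comparisons with a heteroscedasticity-aware decision tree.

The pipeline runs Levene's test (mean-centred) on each outcome at
alpha = 0.05.  If variances pass, outcomes are compared by one-way
ANOVA/ANCOVA with Tukey-Kramer post-hocs; if not, by the Brown-Forsythe
variance-weighted F* with Satterthwaite degrees of freedom and
Games-Howell post-hocs.  Each ANCOVA is preceded by a homogeneity-of-
regression-slopes pretest (Group x covariate interaction); a violated
covariate is dropped and the model refit without it.  Rank-based
comparisons use Mann-Whitney U with midrank tie handling, a tie- and
continuity-corrected normal approximation, and exact enumeration for
small samples; the effect size is r = z / sqrt(N).

Brown-Forsythe F* (not provided by scipy/statsmodels/pingouin) for k
groups with sizes n_i, means m_i, variances s_i^2, grand mean m:

    F* = sum_i n_i (m_i - m)^2 / sum_i (1 - n_i/N) s_i^2
    df1 = k - 1
    1/df2 = sum_i c_i^2 / (n_i - 1),  c_i = (1 - n_i/N) s_i^2 / denom
"""

from __future__ import annotations

import itertools
import warnings
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05


@dataclass(frozen=True)
class CovariateEffect:
    name: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    correction: str = "none"  # or "brown_forsythe"
    covariates: tuple[CovariateEffect, ...] = ()


@dataclass(frozen=True)
class PosthocResult:
    method: str  # tukey_kramer / games_howell
    group_a: str
    group_b: str
    estimate: float  # mean(b) - mean(a)
    p: float


@dataclass(frozen=True)
class MWResult:
    U: float  # min(U1, U2), as conventionally printed
    z: float  # tie- and continuity-corrected normal approximation (<= 0)
    p: float
    r: float  # z / sqrt(N)
    rank_sum_x: float
    rank_sum_y: float
    exact: bool = False


@dataclass(frozen=True)
class SlopesPretest:
    F: float
    df1: float
    df2: float
    p: float
    homogeneous: bool


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2 or any(len(g) < 2 for g in out):
        raise ValueError("need >= 2 groups with >= 2 values each")
    return out


def levene_test(groups, center: str = "mean") -> tuple[float, float]:
    """Levene's homogeneity-of-variance test (classical, mean-centred).

    ``center='median'`` gives the robust Brown-Forsythe variant of the
    Levene statistic.
    """
    gs = _as_groups(groups)
    w, p = sps.levene(*gs, center=center)
    return float(w), float(p)


def _partial_eta_from_ss(ss_effect: float, ss_error: float) -> float:
    if ss_effect + ss_error == 0:
        return 0.0
    return ss_effect / (ss_effect + ss_error)


def oneway_anova(groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA with partial eta squared."""
    gs = _as_groups(groups)
    if all(np.var(g) == 0 for g in gs):
        raise ValueError("zero within-group variance in every group")
    f, p = sps.f_oneway(*gs)
    allv = np.concatenate(gs)
    ss_between = sum(len(g) * (g.mean() - allv.mean()) ** 2 for g in gs)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    df1, df2 = len(gs) - 1, len(allv) - len(gs)
    return AnovaResult(
        F=float(f), df1=float(df1), df2=float(df2), p=float(p),
        partial_eta_sq=_partial_eta_from_ss(ss_between, ss_within),
    )


def brown_forsythe(groups) -> AnovaResult:
    """Brown-Forsythe F* for unequal variances (Satterthwaite df2)."""
    gs = _as_groups(groups)
    n = np.array([len(g) for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    N = n.sum()
    grand = float(np.concatenate(gs).mean())
    num = float(np.sum(n * (m - grand) ** 2))
    terms = (1.0 - n / N) * v
    denom = float(terms.sum())
    if denom == 0:
        raise ValueError("zero within-group variance in every group")
    f_star = num / denom
    c = terms / denom
    df2 = 1.0 / float(np.sum(c**2 / (n - 1.0)))
    df1 = len(gs) - 1.0
    p = float(sps.f.sf(f_star, df1, df2))
    eta = f_star * df1 / (f_star * df1 + df2)
    return AnovaResult(
        F=float(f_star), df1=df1, df2=df2, p=p,
        partial_eta_sq=float(eta), correction="brown_forsythe",
    )


def _ancova_frame(dv, group, covariates: dict[str, np.ndarray]) -> pd.DataFrame:
    df = pd.DataFrame({"dv": np.asarray(dv, dtype=float), "group": np.asarray(group)})
    for name, vals in covariates.items():
        df[name] = np.asarray(vals, dtype=float)
    return df.dropna()


def ancova(dv, group, covariates: dict[str, np.ndarray] | None = None) -> AnovaResult:
    """Linear-model ANCOVA: group effect adjusted for numeric covariates.

    Type-II sums of squares; each term's partial eta squared uses the
    residual SS of the full model.  With no covariates this reduces to the
    one-way ANOVA.
    """
    covariates = covariates or {}
    df = _ancova_frame(dv, group, covariates)
    rhs = " + ".join(["C(group)", *covariates])
    fit = smf.ols(f"dv ~ {rhs}", data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design")
    table = sm.stats.anova_lm(fit, typ=2)
    ss_resid = float(table.loc["Residual", "sum_sq"])
    df_resid = float(table.loc["Residual", "df"])

    def effect(term: str) -> tuple[float, float, float, float]:
        row = table.loc[term]
        return (
            float(row["F"]), float(row["df"]), df_resid, float(row["PR(>F)"]),
        )

    f, df1, df2, p = effect("C(group)")
    cov_effects = []
    for name in covariates:
        cf, cdf1, cdf2, cp = effect(name)
        cov_effects.append(
            CovariateEffect(
                name=name, F=cf, df1=cdf1, df2=cdf2, p=cp,
                partial_eta_sq=_partial_eta_from_ss(
                    float(table.loc[name, "sum_sq"]), ss_resid
                ),
            )
        )
    return AnovaResult(
        F=f, df1=df1, df2=df2, p=p,
        partial_eta_sq=_partial_eta_from_ss(
            float(table.loc["C(group)", "sum_sq"]), ss_resid
        ),
        covariates=tuple(cov_effects),
    )


def slopes_pretest(dv, group, covariate, name: str = "cov", alpha: float = ALPHA) -> SlopesPretest:
    """Homogeneity-of-regression-slopes check: Group x covariate interaction."""
    df = _ancova_frame(dv, group, {name: covariate})
    fit = smf.ols(f"dv ~ C(group) * {name}", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc[f"C(group):{name}"]
    p = float(row["PR(>F)"])
    return SlopesPretest(
        F=float(row["F"]), df1=float(row["df"]),
        df2=float(table.loc["Residual", "df"]), p=p, homogeneous=p >= alpha,
    )


def _group_series(groups, labels) -> tuple[np.ndarray, np.ndarray]:
    vals = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    labs = np.concatenate([[str(l)] * len(g) for g, l in zip(groups, labels)])
    return vals, labs


def tukey_kramer(groups, labels=None) -> list[PosthocResult]:
    """Tukey HSD with the Kramer unequal-n harmonic correction."""
    gs = _as_groups(groups)
    labels = labels or [f"g{i}" for i in range(len(gs))]
    vals, labs = _group_series(gs, labels)
    res = pairwise_tukeyhsd(vals, labs, alpha=ALPHA)
    out = []
    for (a, b), diff, p in zip(
        itertools.combinations(res.groupsunique, 2), res.meandiffs, res.pvalues
    ):
        out.append(PosthocResult("tukey_kramer", str(a), str(b), float(diff), float(p)))
    return out


def games_howell(groups, labels=None) -> list[PosthocResult]:
    """Games-Howell pairwise comparisons (unpooled variances, Welch df)."""
    gs = _as_groups(groups)
    labels = labels or [f"g{i}" for i in range(len(gs))]
    vals, labs = _group_series(gs, labels)
    df = pd.DataFrame({"dv": vals, "group": labs})
    table = pg.pairwise_gameshowell(data=df, dv="dv", between="group")
    return [
        PosthocResult(
            "games_howell", str(row.A), str(row.B),
            float(row.mean_B - row.mean_A), float(row.pval),
        )
        for row in table.itertuples()
    ]


def _mw_counts(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: #{x_i > y_j} + 0.5 #{x_i == y_j} (brute pair count)."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def _mw_exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-tailed exact p by enumeration of all group assignments.

    Valid with ties (midranks are implicit in the pair-count definition of
    U).  Intended for n + m <= 12 where C(n+m, n) is tiny.
    """
    pooled = np.concatenate([x, y])
    n = len(x)
    nm = len(x) * len(y)
    dev_obs = abs(u_obs - nm / 2.0)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = _mw_counts(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - nm / 2.0) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney(x, y, exact_max_n: int = 12) -> MWResult:
    """Mann-Whitney U with printed-style U = min(U1, U2) and r = z/sqrt(N).

    z uses the tie-corrected variance and a 0.5 continuity correction
    toward zero, so it is always <= 0 (magnitude convention, as commonly
    printed); direction can be read from the rank sums.  When
    n + m <= ``exact_max_n`` the p-value comes from exact enumeration
    over all group assignments instead of the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n, m = len(x), len(y)
    N = n + m
    ranks = sps.rankdata(np.concatenate([x, y]))
    r_x = float(ranks[:n].sum())
    r_y = float(ranks[n:].sum())
    u1 = r_x - n * (n + 1) / 2.0
    u2 = n * m - u1
    u = min(u1, u2)

    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var_u == 0:
        z = 0.0
    else:
        z = min(u + 0.5 - n * m / 2.0, 0.0) / math.sqrt(var_u)
    if N <= exact_max_n:
        p = _mw_exact_p(x, y, u1)
        exact = True
    else:
        p = float(min(1.0, 2.0 * sps.norm.cdf(z)))
        exact = False
    return MWResult(
        U=float(u), z=float(z), p=float(p), r=float(z / math.sqrt(N)),
        rank_sum_x=r_x, rank_sum_y=r_y, exact=exact,
    )


@dataclass(frozen=True)
class MixedAnovaResult:
    between: AnovaResult
    within: AnovaResult
    interaction: AnovaResult
    n_used: int
    n_dropped: int


def mixed_anova_distance(condition_means: pd.DataFrame) -> MixedAnovaResult:
    """3 x 2 (group x distance) mixed ANOVA on per-participant RT means.

    Expects the output of ``preprocess.distance_split`` (columns
    participant_id, group, mean_rt_small, mean_rt_large).  Participants
    missing either condition are dropped.
    """
    df = condition_means.dropna(subset=["mean_rt_small", "mean_rt_large"])
    n_dropped = len(condition_means) - len(df)
    long = df.melt(
        id_vars=["participant_id", "group"],
        value_vars=["mean_rt_small", "mean_rt_large"],
        var_name="distance", value_name="rt",
    )
    long["distance"] = long["distance"].str.replace("mean_rt_", "", regex=False)
    table = pg.mixed_anova(
        data=long, dv="rt", within="distance", subject="participant_id", between="group"
    ).set_index("Source")

    def as_result(source: str) -> AnovaResult:
        row = table.loc[source]
        return AnovaResult(
            F=float(row["F"]), df1=float(row["DF1"]), df2=float(row["DF2"]),
            p=float(row["p_unc"]), partial_eta_sq=float(row["np2"]),
        )

    return MixedAnovaResult(
        between=as_result("group"),
        within=as_result("distance"),
        interaction=as_result("Interaction"),
        n_used=len(df), n_dropped=n_dropped,
    )


@dataclass
class OutcomeReport:
    """Decision-tree result for one outcome variable."""

    outcome: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    levene_W: float
    levene_p: float
    heteroscedastic: bool
    anova: AnovaResult
    posthoc: list[PosthocResult]
    slopes: dict[str, SlopesPretest] = field(default_factory=dict)
    covariates_used: list[str] = field(default_factory=list)
    covariates_dropped: list[str] = field(default_factory=list)


def compare_groups(
    data: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    covariates: list[str] | None = None,
    alpha: float = ALPHA,
    levene_center: str = "mean",
) -> OutcomeReport:
    """Run the full decision tree for one outcome column.

    Levene at ``alpha`` gates ANOVA/ANCOVA + Tukey-Kramer (homoscedastic)
    vs Brown-Forsythe + Games-Howell (heteroscedastic; covariates do not
    enter the variance-weighted test and are dropped with a note).  Each
    requested covariate is kept only if its slopes pretest is homogeneous.
    """
    covariates = covariates or []
    cols = [outcome, group_col, *covariates]
    df = data[cols].dropna()
    labels = sorted(df[group_col].unique())
    groups = [df.loc[df[group_col] == g, outcome].to_numpy(float) for g in labels]

    w, p_lev = levene_test(groups, center=levene_center)
    hetero = p_lev < alpha

    slopes: dict[str, SlopesPretest] = {}
    kept, dropped = [], []
    for cov in covariates:
        pretest = slopes_pretest(df[outcome], df[group_col], df[cov], name=cov, alpha=alpha)
        slopes[cov] = pretest
        (kept if pretest.homogeneous else dropped).append(cov)

    if hetero:
        result = brown_forsythe(groups)
        posthoc = games_howell(groups, labels)
        dropped, kept = kept + dropped, []
    elif kept:
        result = ancova(df[outcome], df[group_col], {c: df[c] for c in kept})
        posthoc = tukey_kramer(groups, labels)
    else:
        result = oneway_anova(groups)
        posthoc = tukey_kramer(groups, labels)

    return OutcomeReport(
        outcome=outcome,
        group_means={g: float(v.mean()) for g, v in zip(labels, groups)},
        group_sds={g: float(v.std(ddof=1)) for g, v in zip(labels, groups)},
        group_ns={g: int(len(v)) for g, v in zip(labels, groups)},
        levene_W=w, levene_p=p_lev, heteroscedastic=hetero,
        anova=result, posthoc=posthoc, slopes=slopes,
        covariates_used=kept, covariates_dropped=dropped,
    )


def analysis_policy(
    data: pd.DataFrame,
    outcomes: dict[str, list[str]],
    group_col: str = "group",
    alpha: float = ALPHA,
    levene_center: str = "mean",
) -> dict[str, OutcomeReport]:
    """Apply :func:`compare_groups` to every configured outcome.

    ``outcomes`` maps outcome column -> covariate columns (possibly empty).
    An outcome left with fewer than two complete cases in some group (e.g.
    after exclusions in a very small cohort) is skipped with a warning.
    """
    out: dict[str, OutcomeReport] = {}
    for outcome, covs in outcomes.items():
        try:
            out[outcome] = compare_groups(
                data, outcome, group_col=group_col, covariates=covs,
                alpha=alpha, levene_center=levene_center,
            )
        except ValueError as err:
            warnings.warn(f"skipping outcome {outcome!r}: {err}", stacklevel=2)
    return out
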