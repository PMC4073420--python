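"""Statistical decision tree: closed-form identities and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from weberkit import stats as st

GROUPS_FIXED = [
    np.array([3.1, 4.0, 2.8, 3.6, 3.3]),
    np.array([4.5, 5.2, 4.9, 5.8, 4.1]),
    np.array([2.0, 2.9, 2.5, 1.7, 2.4]),
]


def hand_oneway_f(groups):
    """Independent two-line ANOVA: SS decomposition by hand."""
    allv = np.concatenate(groups)
    ssb = sum(len(g) * (g.mean() - allv.mean()) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = len(groups) - 1, len(allv) - len(groups)
    f = (ssb / df1) / (ssw / df2)
    return f, float(sps.f.sf(f, df1, df2))


class TestLevene:
    def test_identical_deviation_sets(self):
        groups = [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
        w, p = st.levene_test(groups)
        assert w == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_two_step_hand_computation(self):
        w, p = st.levene_test(GROUPS_FIXED)
        deviations = [np.abs(g - g.mean()) for g in GROUPS_FIXED]
        w_hand, p_hand = hand_oneway_f(deviations)
        assert w == pytest.approx(w_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-12)

    def test_detects_gross_variance_inequality(self):
        rng = np.random.default_rng(9)
        rejections = 0
        for _ in range(200):
            g = [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(0, 10, 30)]
            rejections += st.levene_test(g)[1] < 0.01
        assert rejections / 200 > 0.99

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            st.levene_test([[1.0], [2.0, 3.0]])


class TestOneWayAnova:
    def test_identical_groups_zero_effect(self):
        g = [np.array([1.0, 2, 3, 4])] * 3
        res = st.oneway_anova(g)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.partial_eta_sq == pytest.approx(0.0, abs=1e-12)

    def test_f_equals_t_squared_for_two_balanced_groups(self, rng):
        a, b = rng.normal(size=20), rng.normal(1.0, 1, size=20)
        res = st.oneway_anova([a, b])
        t, p_t = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p_t, rel=1e-10)

    def test_partial_eta_identity(self):
        res = st.oneway_anova(GROUPS_FIXED)
        expect = res.F * res.df1 / (res.F * res.df1 + res.df2)
        assert res.partial_eta_sq == pytest.approx(expect, rel=1e-12)
        assert 0.0 <= res.partial_eta_sq <= 1.0


class TestBrownForsythe:
    def test_equal_n_reduces_to_classical_f(self, rng):
        # with equal group sizes the variance-weighted statistic equals the
        # classical F algebraically (1 - n/N is constant)
        g = [rng.normal(size=15) for _ in range(3)]
        bf, cl = st.brown_forsythe(g), st.oneway_anova(g)
        assert bf.F == pytest.approx(cl.F, rel=1e-12)
        assert bf.correction == "brown_forsythe"
        assert bf.df2 <= cl.df2 + 1e-9

    def test_unequal_n_homoscedastic_close_to_classical(self):
        rng = np.random.default_rng(17)
        ratios = []
        for _ in range(100):
            g = [rng.normal(size=n) for n in (30, 50, 40)]
            ratios.append(st.brown_forsythe(g).F / st.oneway_anova(g).F)
        assert np.median(np.abs(np.array(ratios) - 1)) < 0.05

    def test_fractional_df_under_heteroscedasticity(self, rng):
        g = [rng.normal(0, 1, 10), rng.normal(0, 5, 40), rng.normal(0, 2, 20)]
        res = st.brown_forsythe(g)
        assert res.df2 != int(res.df2)


def _typ2_group_f_by_lstsq(dv, group_codes, cov):
    """Brute-force type-II F for the group factor via projections."""
    n = len(dv)
    dummies = pd.get_dummies(group_codes, drop_first=True).to_numpy(float)
    X_full = np.column_stack([np.ones(n), dummies, cov])
    X_red = np.column_stack([np.ones(n), cov])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, dv, rcond=None)
        return float(((dv - X @ beta) ** 2).sum())

    rss_full, rss_red = rss(X_full), rss(X_red)
    df1 = dummies.shape[1]
    df2 = n - X_full.shape[1]
    f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    return f, df1, df2


class TestAncova:
    def test_matches_normal_equations_oracle(self, rng):
        dv = rng.normal(size=30)
        group = np.repeat(["a", "b", "c"], 10)
        cov = rng.normal(size=30) + (group == "b")
        res = st.ancova(dv, group, {"cov": cov})
        f, df1, df2 = _typ2_group_f_by_lstsq(dv, group, cov)
        assert res.F == pytest.approx(f, rel=1e-9)
        assert (res.df1, res.df2) == (df1, df2)

    def test_orthogonal_zero_effect_covariate_changes_only_df(self, rng):
        dv = rng.normal(size=30)
        group = np.repeat(["a", "b", "c"], 10)
        # residualize a random covariate against intercept, dummies and dv
        raw = rng.normal(size=30)
        X = np.column_stack(
            [np.ones(30), pd.get_dummies(group).to_numpy(float), dv]
        )
        beta, *_ = np.linalg.lstsq(X, raw, rcond=None)
        cov = raw - X @ beta
        with_cov = st.ancova(dv, group, {"cov": cov})
        without = st.oneway_anova([dv[group == g] for g in "abc"])
        # SS are untouched, so the F's differ exactly by the df_error ratio
        assert with_cov.F == pytest.approx(without.F * 26 / 27, rel=1e-9)
        assert with_cov.covariates[0].F == pytest.approx(0.0, abs=1e-16)

    def test_dv_equal_covariate_absorbs_group_effect(self, rng):
        group = np.repeat(["a", "b", "c"], 15)
        cov = rng.normal(size=45) + 2 * (group == "c")
        dv = cov + rng.normal(scale=1e-3, size=45)
        res = st.ancova(dv, group, {"cov": cov})
        assert res.covariates[0].partial_eta_sq > 0.999
        assert res.p > 0.1

    def test_rank_deficient_design_raises(self):
        group = np.repeat(["a", "b"], 5)
        cov = (group == "a").astype(float)  # collinear with the dummies
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            st.ancova(np.arange(10.0), group, {"cov": cov})


class TestSlopesPretest:
    def test_equal_slopes_homogeneous(self, rng):
        group = np.repeat(["a", "b", "c"], 20)
        cov = rng.normal(size=60)
        dv = 2.0 * cov + rng.normal(size=60)
        assert st.slopes_pretest(dv, group, cov).homogeneous

    def test_planted_slope_differences_detected(self, rng):
        group = np.repeat(["a", "b", "c"], 30)
        cov = rng.normal(size=90)
        slopes = np.select([group == "a", group == "b"], [0.0, 1.0], 2.0)
        dv = slopes * cov + rng.normal(scale=0.3, size=90)
        res = st.slopes_pretest(dv, group, cov)
        assert not res.homogeneous

    def test_interaction_f_matches_nested_model_oracle(self, rng):
        group = np.repeat(["a", "b", "c"], 12)
        cov = rng.normal(size=36)
        dv = rng.normal(size=36) + cov * (group == "b")
        res = st.slopes_pretest(dv, group, cov)
        dummies = pd.get_dummies(group, drop_first=True).to_numpy(float)
        X_red = np.column_stack([np.ones(36), dummies, cov])
        X_full = np.column_stack([X_red, dummies * cov[:, None]])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, dv, rcond=None)
            return float(((dv - X @ beta) ** 2).sum())

        f = ((rss(X_red) - rss(X_full)) / 2) / (rss(X_full) / (36 - X_full.shape[1]))
        assert res.F == pytest.approx(f, rel=1e-9)


class TestPosthocs:
    def test_tukey_kramer_matches_studentized_range_oracle_equal_n(self, rng):
        groups = [rng.normal(m, 1, 12) for m in (0.0, 0.6, 1.5)]
        res = st.tukey_kramer(groups, labels=["a", "b", "c"])
        ms_error = np.mean([g.var(ddof=1) for g in groups])
        df = 3 * 12 - 3
        for r in res:
            i, j = ord(r.group_a) - 97, ord(r.group_b) - 97
            q = abs(groups[j].mean() - groups[i].mean()) / math.sqrt(ms_error / 12)
            p = float(sps.studentized_range.sf(q, 3, df))
            assert r.p == pytest.approx(p, abs=1e-6)

    def test_huge_separation_p_near_zero(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(10, 1, 15)
        for method in (st.tukey_kramer, st.games_howell):
            assert method([a, b])[0].p < 1e-6

    def test_games_howell_close_to_tukey_when_assumptions_hold(self):
        rng = np.random.default_rng(31)
        diffs = []
        for _ in range(100):
            g = [rng.normal(m, 1, 60) for m in (0.0, 0.3, 0.6)]
            gh = {(r.group_a, r.group_b): r.p for r in st.games_howell(g)}
            tk = {(r.group_a, r.group_b): r.p for r in st.tukey_kramer(g)}
            diffs += [abs(gh[k] - tk[k]) for k in gh]
        # Welch df -> pooled df as n grows; the two procedures agree closely
        # on average, with occasional ~0.05 deviations where the p-value
        # curve is steep
        assert np.mean(diffs) < 0.02
        assert np.max(diffs) < 0.08

    def test_games_howell_matches_welch_studentized_range_oracle(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1.0, 3, 25)
        r = st.games_howell([a, b], labels=["a", "b"])[0]
        va, vb = a.var(ddof=1) / 10, b.var(ddof=1) / 25
        se = math.sqrt((va + vb) / 2)
        df = (va + vb) ** 2 / (va**2 / 9 + vb**2 / 24)
        q = abs(b.mean() - a.mean()) / se
        assert r.p == pytest.approx(float(sps.studentized_range.sf(q, 2, df)), abs=1e-6)

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            st.games_howell([[1.0], [1.0, 2.0]])


class TestMannWhitney:
    def test_complete_separation(self):
        res = st.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0.0
        assert res.exact

    def test_u_within_range_and_r_identity(self, rng):
        x, y = rng.normal(size=19), rng.normal(0.8, 1, size=32)
        res = st.mann_whitney(x, y)
        assert 0 <= res.U <= 19 * 32 / 2
        assert res.r == pytest.approx(res.z / math.sqrt(51), rel=1e-12)
        assert res.z <= 0

    def test_effect_size_convention_reproduces_printed_value(self):
        # a z of -3.63 over N = 51 participants corresponds to r ~ -0.51
        assert -3.63 / math.sqrt(51) == pytest.approx(-0.508, abs=5e-3)

    def test_exact_enumeration_matches_scipy_exact(self, rng):
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(0.5, 1, size=4)
            res = st.mann_whitney(x, y)
            p_scipy = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert res.exact
            assert res.p == pytest.approx(float(p_scipy), abs=1e-12)

    def test_normal_approximation_close_to_exact_at_boundary(self, rng):
        worst = 0.0
        for _ in range(20):
            x, y = rng.normal(size=6), rng.normal(0.5, 1, size=6)
            exact = st.mann_whitney(x, y).p
            approx = st.mann_whitney(x, y, exact_max_n=0).p
            worst = max(worst, abs(exact - approx))
        assert worst < 0.05  # approximation quality at n+m=12

    def test_ties_handled_by_midranks(self):
        res = st.mann_whitney([1, 2, 2, 3], [2, 3, 3, 4])
        assert res.exact
        assert 0 < res.p <= 1

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            st.mann_whitney([], [1.0])


def hand_mixed_anova(wide):
    """SS decomposition for a balanced 2-condition mixed design, by hand."""
    a = wide[["y1", "y2"]].to_numpy(float)
    groups = wide["g"].to_numpy()
    labels = sorted(set(groups))
    n_total, k = len(wide), len(labels)
    grand = a.mean()
    subj_means = a.mean(axis=1)
    cond_means = a.mean(axis=0)
    ss_between_subj = 2 * ((subj_means - grand) ** 2).sum()
    ss_group = sum(
        2 * (groups == g).sum() * (a[groups == g].mean() - grand) ** 2 for g in labels
    )
    ss_subj_within = ss_between_subj - ss_group
    ss_cond = n_total * ((cond_means - grand) ** 2).sum()
    cell = np.array([[a[groups == g, j].mean() for j in (0, 1)] for g in labels])
    gmeans = np.array([a[groups == g].mean() for g in labels])
    ss_inter = sum(
        (groups == g).sum()
        * ((cell[i] - gmeans[i] - cond_means + grand) ** 2).sum()
        for i, g in enumerate(labels)
    )
    ss_total = ((a - grand) ** 2).sum()
    ss_err_within = ss_total - ss_between_subj - ss_cond - ss_inter
    df_g, df_sw = k - 1, n_total - k
    f_group = (ss_group / df_g) / (ss_subj_within / df_sw)
    f_cond = (ss_cond / 1) / (ss_err_within / df_sw)
    f_inter = (ss_inter / df_g) / (ss_err_within / df_sw)
    return f_group, f_cond, f_inter


class TestMixedAnova:
    @staticmethod
    def frame(wide):
        return pd.DataFrame(
            {
                "participant_id": wide.index.astype(str),
                "group": wide["g"].to_numpy(),
                "mean_rt_small": wide["y1"].to_numpy(),
                "mean_rt_large": wide["y2"].to_numpy(),
            }
        )

    def test_constant_within_effect_no_interaction(self, rng):
        g = np.repeat(["DD", "TA4", "TA2"], 10)
        base = rng.normal(1000, 100, 30)
        # near-constant within-participant effect (exact constancy makes the
        # within-residual SS zero and the F ratio undefined)
        wide = pd.DataFrame(
            {"g": g, "y1": base + 170.0 + rng.normal(0, 5, 30), "y2": base}
        )
        res = st.mixed_anova_distance(self.frame(wide))
        assert res.interaction.p > 0.05
        assert res.within.p < 1e-12

    def test_matches_hand_ss_decomposition(self, rng):
        g = np.repeat(["a", "b", "c"], 4)
        wide = pd.DataFrame(
            {"g": g, "y1": rng.normal(size=12), "y2": rng.normal(size=12)}
        )
        res = st.mixed_anova_distance(self.frame(wide))
        f_group, f_cond, f_inter = hand_mixed_anova(wide)
        assert res.between.F == pytest.approx(f_group, rel=1e-9)
        assert res.within.F == pytest.approx(f_cond, rel=1e-9)
        assert res.interaction.F == pytest.approx(f_inter, rel=1e-9)

    def test_missing_condition_drops_participant(self, rng):
        g = np.repeat(["a", "b", "c"], 5)
        wide = pd.DataFrame(
            {"g": g, "y1": rng.normal(size=15), "y2": rng.normal(size=15)}
        )
        frame = self.frame(wide)
        frame.loc[0, "mean_rt_small"] = np.nan
        res = st.mixed_anova_distance(frame)
        assert res.n_used == 14 and res.n_dropped == 1

    def test_null_type_one_error_near_alpha(self):
        rng = np.random.default_rng(77)
        rej = np.zeros(3)
        n_sim = 300
        for _ in range(n_sim):
            g = np.repeat(["a", "b", "c"], 8)
            wide = pd.DataFrame(
                {"g": g, "y1": rng.normal(size=24), "y2": rng.normal(size=24)}
            )
            res = st.mixed_anova_distance(self.frame(wide))
            rej += [res.between.p < 0.05, res.within.p < 0.05, res.interaction.p < 0.05]
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert np.all(np.abs(rej / n_sim - 0.05) < 3 * se)


class TestPolicy:
    @staticmethod
    def summary_frame(rng, dd_sd=1.0):
        rows = []
        for g, n, mean, sd in (
            ("DD", 19, 1.0, dd_sd), ("TA4", 32, 0.0, 1.0), ("TA2", 31, 0.5, 1.0)
        ):
            for _ in range(n):
                rows.append(
                    {
                        "group": g,
                        "outcome": rng.normal(mean, sd),
                        "rpm": rng.normal(20, 5),
                    }
                )
        return pd.DataFrame(rows)

    def test_homoscedastic_selects_anova_and_tukey(self):
        rng = np.random.default_rng(101)
        chosen = []
        for _ in range(20):
            rep = st.compare_groups(self.summary_frame(rng), "outcome")
            chosen.append((rep.heteroscedastic, rep.posthoc[0].method))
        assert sum(not h for h, _ in chosen) >= 18
        assert all(m == "tukey_kramer" for h, m in chosen if not h)

    def test_heteroscedastic_selects_brown_forsythe_and_games_howell(self):
        rng = np.random.default_rng(202)
        hits = 0
        for _ in range(20):
            rep = st.compare_groups(self.summary_frame(rng, dd_sd=8.0), "outcome")
            if rep.heteroscedastic:
                assert rep.anova.correction == "brown_forsythe"
                assert rep.posthoc[0].method == "games_howell"
                hits += 1
        assert hits >= 18

    def test_violated_slopes_drop_covariate(self, rng):
        df = self.summary_frame(rng)
        # plant a strong Group x rpm interaction
        df.loc[df.group == "DD", "outcome"] += 3.0 * df.loc[df.group == "DD", "rpm"]
        df["outcome"] -= df["outcome"].mean()
        rep = st.compare_groups(df, "outcome", covariates=["rpm"])
        if not rep.heteroscedastic:
            assert "rpm" in rep.covariates_dropped

    def test_report_per_outcome(self, rng):
        df = self.summary_frame(rng)
        df["second"] = rng.normal(size=len(df))
        out = st.analysis_policy(df, {"outcome": ["rpm"], "second": []})
        assert set(out) == {"outcome", "second"}
        rep = out["outcome"]
        assert set(rep.group_ns.values()) == {19, 32, 31}
        assert len(rep.posthoc) == 3
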