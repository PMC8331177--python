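"""Group-level statistics: mixed ANOVA, LSD, t, chi-square, Bayes factors."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from ddcurve.inference import (
    DesignError,
    GroupSummary,
    chi_square_2x2,
    fisher_lsd,
    jzs_bf_from_t,
    jzs_bf_ttest,
    mixed_anova,
    pooled_t,
)


def make_mixed_table(n_per_group=(5, 9), seed=7, effects=None):
    """Toy group x condition x magnitude long table from a seeded generator."""
    effects = effects or {}
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in zip(("patient", "control"), n_per_group):
        for i in range(n):
            sid = f"{g}{i}"
            base = rng.normal(0.4, 0.15)
            for c in ("Standard", "EFT"):
                for m in ("small", "large"):
                    y = base + rng.normal(0, 0.05)
                    y += effects.get("condition", 0.0) * (c == "EFT")
                    y += effects.get("group_magnitude", 0.0) * (
                        (m == "large") and (g == "control")
                    )
                    rows.append(
                        dict(participant_id=sid, group=g, condition=c,
                             magnitude=m, y=y)
                    )
    return pd.DataFrame(rows)


def cell_means_anova_oracle(df):
    """Classical balanced mixed-ANOVA SS by explicit mean decomposition."""
    piv = df.pivot_table(index=["group", "participant_id"],
                         columns=["condition", "magnitude"], values="y")
    grand = piv.to_numpy().mean()
    g_mean = piv.groupby("group").mean().mean(axis=1)          # per group
    subj_mean = piv.mean(axis=1)                                # per subject
    c_mean = piv.T.groupby("condition").mean().T.mean()         # per condition
    m_mean = piv.T.groupby("magnitude").mean().T.mean()         # per magnitude
    gc = piv.T.groupby("condition").mean().T.groupby("group").mean()
    gm = piv.T.groupby("magnitude").mean().T.groupby("group").mean()
    cm = piv.mean(axis=0)                                       # (c, m) cells
    cm = cm.groupby(["condition", "magnitude"]).mean()
    gcm = piv.groupby("group").mean()
    n_per_group = piv.groupby("group").size()
    n = int(n_per_group.iloc[0])
    assert (n_per_group == n).all(), "oracle assumes balanced groups"

    ss = {}
    ss["group"] = 4 * n * sum((g_mean[g] - grand) ** 2 for g in g_mean.index)
    ss["s(g)"] = 4 * sum(
        (subj_mean[g, s] - g_mean[g]) ** 2 for g, s in subj_mean.index
    )
    ss["condition"] = 2 * n * 2 * sum((c_mean[c] - grand) ** 2 for c in c_mean.index)
    ss["magnitude"] = 2 * n * 2 * sum((m_mean[m] - grand) ** 2 for m in m_mean.index)
    ss["group * condition"] = 2 * n * sum(
        (gc.loc[g, c] - g_mean[g] - c_mean[c] + grand) ** 2
        for g in gc.index for c in gc.columns
    )
    ss["group * magnitude"] = 2 * n * sum(
        (gm.loc[g, m] - g_mean[g] - m_mean[m] + grand) ** 2
        for g in gm.index for m in gm.columns
    )
    ss["condition * magnitude"] = 2 * n * sum(
        (cm[c, m] - c_mean[c] - m_mean[m] + grand) ** 2 for c, m in cm.index
    )
    ss["group * condition * magnitude"] = n * sum(
        (
            gcm.loc[g, (c, m)] - gc.loc[g, c] - gm.loc[g, m] - cm[c, m]
            + g_mean[g] + c_mean[c] + m_mean[m] - grand
        ) ** 2
        for g in gcm.index for c, m in gcm.columns
    )
    # error terms
    subj_c = piv.T.groupby("condition").mean().T   # subject x condition means
    ss["err_c"] = 2 * sum(
        (subj_c.loc[(g, s), c] - subj_mean[g, s] - gc.loc[g, c] + g_mean[g]) ** 2
        for g, s in subj_c.index for c in subj_c.columns
    )
    subj_m = piv.T.groupby("magnitude").mean().T
    ss["err_m"] = 2 * sum(
        (subj_m.loc[(g, s), m] - subj_mean[g, s] - gm.loc[g, m] + g_mean[g]) ** 2
        for g, s in subj_m.index for m in subj_m.columns
    )
    resid = 0.0
    for (g, s), row in piv.iterrows():
        for (c, m), y in row.items():
            fitted = (
                subj_mean[g, s]
                + (subj_c.loc[(g, s), c] - subj_mean[g, s])
                + (subj_m.loc[(g, s), m] - subj_mean[g, s])
                + (gcm.loc[g, (c, m)] - gc.loc[g, c] - gm.loc[g, m] + g_mean[g])
            )
            resid += (y - fitted) ** 2
    ss["err_cm"] = resid
    return ss


class TestMixedAnova:
    def test_matches_cell_means_oracle_on_balanced_design(self):
        df = make_mixed_table(n_per_group=(6, 6), seed=11,
                              effects={"condition": 0.2, "group_magnitude": 0.1})
        tab = mixed_anova(df, "y", "group", ["condition", "magnitude"]).set_index("effect")
        oracle = cell_means_anova_oracle(df)
        for effect in ("group", "condition", "magnitude", "group * condition",
                       "group * magnitude", "condition * magnitude",
                       "group * condition * magnitude"):
            assert tab.loc[effect, "ss_effect"] == pytest.approx(
                oracle[effect], rel=1e-8
            ), effect
        assert tab.loc["group", "ss_error"] == pytest.approx(oracle["s(g)"], rel=1e-8)
        assert tab.loc["condition", "ss_error"] == pytest.approx(oracle["err_c"], rel=1e-8)
        assert tab.loc["magnitude", "ss_error"] == pytest.approx(oracle["err_m"], rel=1e-8)
        assert tab.loc["condition * magnitude", "ss_error"] == pytest.approx(
            oracle["err_cm"], rel=1e-8
        )

    def test_ss_decomposition_identity_on_balanced_design(self):
        df = make_mixed_table(n_per_group=(4, 4), seed=3)
        tab = mixed_anova(df, "y", "group", ["condition", "magnitude"])
        total = ((df["y"] - df["y"].mean()) ** 2).sum()
        # error SS are shared between a within effect and its group interaction
        unique_err = tab.drop_duplicates("ss_error")["ss_error"].sum()
        assert tab["ss_effect"].sum() + unique_err == pytest.approx(total, rel=1e-8)

    def test_unbalanced_groups_give_expected_dfs(self):
        df = make_mixed_table(n_per_group=(12, 41), seed=5)
        tab = mixed_anova(df, "y", "group", ["condition", "magnitude"])
        assert (tab["df_effect"] == 1).all()
        assert (tab["df_error"] == 51).all()

    def test_agrees_with_pingouin_two_way_collapse(self):
        """Collapsing magnitude, the group/condition rows match pingouin."""
        pg = pytest.importorskip("pingouin")
        df = make_mixed_table(n_per_group=(5, 9), seed=7,
                              effects={"condition": 0.2, "group_magnitude": 0.1})
        tab = mixed_anova(df, "y", "group", ["condition", "magnitude"]).set_index("effect")
        coll = df.groupby(["participant_id", "group", "condition"],
                          as_index=False)["y"].mean()
        ref = pg.mixed_anova(data=coll, dv="y", within="condition",
                             between="group", subject="participant_id")
        ref = ref.set_index("Source")
        assert tab.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert tab.loc["group * condition", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6
        )
        assert tab.loc["group * condition", "partial_eta_sq"] == pytest.approx(
            ref.loc["Interaction", "np2"], rel=1e-6
        )

    def test_no_within_variance_gives_zero_within_ss(self):
        df = make_mixed_table(n_per_group=(4, 5), seed=2)
        flat = df.groupby("participant_id")["y"].transform("mean")
        df = df.assign(y=flat)
        tab = mixed_anova(df, "y", "group", ["condition", "magnitude"]).set_index("effect")
        for effect in ("condition", "magnitude", "condition * magnitude"):
            assert tab.loc[effect, "ss_effect"] == pytest.approx(0.0, abs=1e-12)
            assert tab.loc[effect, "F"] == 0.0

    def test_partial_eta_sq_identity(self):
        df = make_mixed_table(n_per_group=(5, 8), seed=9,
                              effects={"condition": 0.15})
        tab = mixed_anova(df, "y", "group", ["condition", "magnitude"])
        recomputed = (tab["F"] * tab["df_effect"]) / (
            tab["F"] * tab["df_effect"] + tab["df_error"]
        )
        assert np.allclose(tab["partial_eta_sq"], recomputed)

    def test_missing_cell_names_participant(self):
        df = make_mixed_table(n_per_group=(4, 4), seed=1)
        df = df.drop(df[(df.participant_id == "patient0")
                        & (df.condition == "EFT")
                        & (df.magnitude == "small")].index)
        with pytest.raises(DesignError, match="patient0"):
            mixed_anova(df, "y", "group", ["condition", "magnitude"])


class TestFisherLsd:
    def test_identical_cells_degenerate(self):
        df = make_mixed_table()
        res = fisher_lsd(df, "y", "group", ["condition", "magnitude"],
                         {"group": "control", "magnitude": "large"},
                         {"group": "control", "magnitude": "large"})
        assert (res.t, res.p) == (0.0, 1.0)

    def test_within_comparison_matches_hand_computed_pooled_t(self):
        """LSD t for a within contrast = group mean diff over pooled SE."""
        df = make_mixed_table(n_per_group=(5, 9), seed=13,
                              effects={"group_magnitude": 0.2})
        res = fisher_lsd(df, "y", "group", ["condition", "magnitude"],
                         {"group": "control", "magnitude": "large"},
                         {"group": "control", "magnitude": "small"})
        # hand computation from per-subject large-minus-small scores
        wide = df.pivot_table(index=["participant_id", "group"],
                              columns="magnitude", values="y")
        z = (wide["large"] - wide["small"])
        by_group = z.groupby(level="group")
        pooled = sum(((v - v.mean()) ** 2).sum() for _, v in by_group) / (len(z) - 2)
        expected_t = z.xs("control", level="group").mean() / math.sqrt(
            pooled / by_group.size()["control"]
        )
        assert res.t == pytest.approx(expected_t, rel=1e-10)
        assert res.df == len(z) - 2

    def test_between_comparison_detects_planted_difference(self):
        df = make_mixed_table(n_per_group=(10, 10), seed=17,
                              effects={"group_magnitude": 0.4})
        res = fisher_lsd(df, "y", "group", ["condition", "magnitude"],
                         {"group": "patient", "magnitude": "large"},
                         {"group": "control", "magnitude": "large"})
        assert res.p < 0.05
        assert res.t < 0


class TestPooledT:
    def test_age_matching_example(self):
        res = pooled_t(GroupSummary(12, 57.41, 8.20), GroupSummary(41, 61.09, 6.58))
        assert abs(res.t) == pytest.approx(1.61, abs=0.01)
        assert res.df == 51

    def test_education_matching_example(self):
        res = pooled_t(GroupSummary(12, 13.41, 3.67), GroupSummary(41, 13.19, 2.82))
        assert abs(res.t) == pytest.approx(0.22, abs=0.01)
        assert res.p == pytest.approx(0.82, abs=0.01)

    def test_equal_summaries_null(self):
        res = pooled_t(GroupSummary(10, 1.0, 0.5), GroupSummary(10, 1.0, 0.5))
        assert (res.t, res.p) == (0.0, pytest.approx(1.0))

    def test_degenerate_zero_variance(self):
        res = pooled_t(GroupSummary(5, 2.0, 0.0), GroupSummary(5, 2.0, 0.0))
        assert (res.t, res.p) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_t_squared_equals_one_way_f(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 41)
        res = pooled_t(
            GroupSummary(len(a), a.mean(), a.std(ddof=1)),
            GroupSummary(len(b), b.mean(), b.std(ddof=1)),
        )
        f = stats.f_oneway(a, b)
        assert res.t ** 2 == pytest.approx(f.statistic, rel=1e-10)
        assert res.p == pytest.approx(f.pvalue, rel=1e-8)


class TestChiSquare:
    def test_gender_balance_example(self):
        chi2, p = chi_square_2x2([[8, 4], [35, 6]])
        assert chi2 == pytest.approx(2.12, abs=0.01)
        assert p == pytest.approx(0.14, abs=0.01)

    def test_proportional_rows_are_independent(self):
        chi2, _ = chi_square_2x2([[10, 20], [5, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_hand_computation(self):
        chi2, _ = chi_square_2x2([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 6]])


def bf_nct_oracle(t, n1, n2, r):
    """Independent quadrature: noncentral-t marginal over the Cauchy prior."""
    neff, nu = n1 * n2 / (n1 + n2), n1 + n2 - 2
    num = integrate.quad(
        lambda d: stats.nct.pdf(t, nu, d * math.sqrt(neff))
        * stats.cauchy.pdf(d, scale=r),
        -np.inf, np.inf, limit=400,
    )[0]
    return num / stats.t.pdf(t, nu)


class TestJzsBayesFactor:
    @pytest.mark.parametrize("t", [-3.2, -1.5, 0.0, 0.8, 2.5, 5.0])
    def test_matches_independent_quadrature(self, t):
        mine = jzs_bf_from_t(t, 12, 41)
        oracle = bf_nct_oracle(t, 12, 41, math.sqrt(2) / 2)
        assert mine == pytest.approx(oracle, rel=1e-6)

    def test_summary_statistic_bayes_factors(self):
        """BF10 from the matching-summary inputs, checked by dual quadrature."""
        eft = jzs_bf_ttest(GroupSummary(12, 0.17, 0.21), GroupSummary(41, 0.26, 0.17))
        mag = jzs_bf_ttest(GroupSummary(12, 0.01, 0.10), GroupSummary(41, 0.14, 0.13))
        assert eft.bf10 == pytest.approx(0.7876, abs=5e-4)
        assert mag.bf10 == pytest.approx(14.693, abs=5e-3)
        assert eft.prior_scale == pytest.approx(math.sqrt(2) / 2)

    def test_null_favoring_at_zero_evidence(self):
        assert jzs_bf_from_t(0.0, 20, 20) < 1.0

    def test_bf_at_null_shrinks_with_sample_size(self):
        bfs = [jzs_bf_from_t(0.0, n, n) for n in (10, 100, 1000)]
        assert bfs[0] > bfs[1] > bfs[2] > 0.0

    def test_invalid_prior_scale(self):
        with pytest.raises(ValueError):
            jzs_bf_from_t(1.0, 10, 10, prior_scale=0.0)
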