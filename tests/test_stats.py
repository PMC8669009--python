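"""Aggregation and the statistical harness: MWU, OLS association, gamma GLM, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from speechmarkers.stats import (
    aggregate_subject,
    association_matrix,
    compare_groups,
    fdr_bh,
    gamma_adjusted_model,
    mann_whitney_exact_p,
    mann_whitney_z,
    pairwise_measure_association,
    shapiro_wilk,
)


class TestAggregate:
    def test_hand_mean(self):
        out = aggregate_subject(
            [{"coherence": 0.6}, {"coherence": 0.8}], measures=("coherence",)
        )
        assert out["coherence"] == pytest.approx(0.7)
        assert out["n_used_coherence"] == 2

    def test_single_excerpt_identity(self):
        out = aggregate_subject([{"on_topic": 0.42}], measures=("on_topic",))
        assert out["on_topic"] == pytest.approx(0.42)

    def test_missing_excluded_not_zeroed(self):
        out = aggregate_subject(
            [{"coherence": 0.5}, {"coherence": float("nan")}],
            measures=("coherence",),
        )
        assert out["coherence"] == pytest.approx(0.5)
        assert out["n_used_coherence"] == 1

    def test_all_missing_stays_missing(self):
        out = aggregate_subject(
            [{"tangentiality": float("nan")}], measures=("tangentiality",)
        )
        assert np.isnan(out["tangentiality"])

    def test_zero_excerpts_rejected(self):
        with pytest.raises(ValueError):
            aggregate_subject([])


class TestShapiroWilk:
    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([3.0] * 10)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = [shapiro_wilk(rng.normal(size=50))[1] for _ in range(400)]
        # calibration: rejection rate near nominal under normal data
        assert 0.01 <= np.mean(np.array(ps) < 0.05) <= 0.10

    def test_power_against_lognormal(self):
        rng = np.random.default_rng(1)
        rejected = sum(
            shapiro_wilk(np.exp(rng.normal(size=50)))[1] < 0.05
            for _ in range(500)
        )
        assert rejected / 500 > 0.8


class TestMannWhitney:
    def test_fully_separated_closed_form(self):
        res = mann_whitney_z([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.z == pytest.approx(-1.9640, abs=1e-3)
        assert res.p == pytest.approx(0.0495, abs=1e-3)
        # exact enumeration over all 20 arrangements (mid-p convention)
        assert mann_whitney_exact_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.05)
        assert mann_whitney_exact_p(
            [1, 2, 3], [4, 5, 6], convention="inclusive"
        ) == pytest.approx(0.10)

    def test_identical_samples_z_zero(self):
        res = mann_whitney_z([1, 2, 3], [1, 2, 3])
        assert res.z == 0.0 and res.p == 1.0

    def test_sign_convention(self):
        assert mann_whitney_z([10, 11, 12], [1, 2, 3]).z > 0
        assert mann_whitney_z([1, 2, 3], [10, 11, 12]).z < 0

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(size=9)
            b = rng.normal(0.5, size=7)
            res = mann_whitney_z(a, b)
            ref = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            )
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_tie_correction_matches_scipy(self):
        a = [1, 2, 2, 3, 3, 3]
        b = [2, 3, 3, 4, 4, 5]
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
        assert mann_whitney_z(a, b).p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_agreement_with_exact_enumeration(self):
        rng = np.random.default_rng(7)
        for i in range(30):
            n = (6, 7, 8)[i % 3]
            a = rng.normal(size=n)
            b = rng.normal(rng.uniform(-1, 1), size=n)
            assert mann_whitney_z(a, b).p == pytest.approx(
                mann_whitney_exact_p(a, b), abs=0.02
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_z([], [1.0])


class TestAssociation:
    @staticmethod
    def _profiles(n=54, seed=0):
        rng = np.random.default_rng(seed)
        group = np.repeat(["CON", "CHR-P", "FEP"], n // 3)
        x = rng.normal(size=n)
        return pd.DataFrame({"group": group, "x": x}), rng

    def test_exact_linear_dependence_gives_huge_t(self):
        df, _ = self._profiles()
        shifts = df["group"].map({"CON": 0.0, "CHR-P": 2.0, "FEP": -1.0})
        df["y"] = df["x"] + shifts
        t, p, n = pairwise_measure_association(df, "x", "y")
        assert abs(t) > 1e6 and n == 54

    def test_textbook_fit_matches_normal_equations(self):
        # 8-point dataset, single group pair; oracle: hand normal equations
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        y = np.array([2.1, 2.9, 4.2, 4.8, 6.1, 6.9, 8.2, 8.8])
        g = ["CON", "CON", "CON", "CON", "FEP", "FEP", "FEP", "FEP"]
        df = pd.DataFrame({"x": x, "y": y, "group": g})
        t, _, _ = pairwise_measure_association(df, "x", "y", min_n=8)
        X = np.column_stack([np.ones(8), x, (np.array(g) == "FEP").astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (8 - 3)
        cov = s2 * np.linalg.inv(X.T @ X)
        t_oracle = beta[1] / np.sqrt(cov[1, 1])
        assert t == pytest.approx(t_oracle, abs=1e-8)

    def test_type_one_error_rate(self):
        """Independent measures: |T| > 1% critical value in ~1% of reps."""
        rng = np.random.default_rng(42)
        n = 54
        group = np.repeat(["CON", "CHR-P", "FEP"], 18)
        crit = sps.t.ppf(0.995, df=n - 4)
        hits = 0
        reps = 500
        for _ in range(reps):
            df = pd.DataFrame(
                {"group": group, "x": rng.normal(size=n), "y": rng.normal(size=n)}
            )
            t, _, _ = pairwise_measure_association(df, "x", "y")
            hits += abs(t) > crit
        assert hits / reps == pytest.approx(0.01, abs=0.01)

    def test_matrix_shape_and_edges(self):
        df, rng = self._profiles(seed=3)
        df["y"] = df["x"] * 0.9 + rng.normal(scale=0.1, size=len(df))
        df["z"] = rng.normal(size=len(df))
        tm, pm, edges = association_matrix(df, measures=("x", "y", "z"))
        assert tm.shape == (3, 3) and np.isnan(tm.loc["x", "x"])
        assert {"x", "y"} == set(
            edges.loc[0, ["measure_i", "measure_j"]]
        )  # strong pair detected

    def test_too_few_complete_cases(self):
        df = pd.DataFrame(
            {"group": ["CON"] * 5, "x": range(5), "y": range(5)}
        )
        t, p, n = pairwise_measure_association(df, "x", "y")
        assert np.isnan(t) and n == 5


class TestGammaModel:
    def test_null_effect_centred_at_one(self):
        # lambda-hat = exp(beta-hat) carries a small Jensen bias above 1
        # under the null (~exp(var(beta)/2) ~ 1.01 at these sizes), so the
        # band allows for that plus Monte Carlo error
        rng = np.random.default_rng(5)
        lams = []
        group = np.array(["a"] * 25 + ["b"] * 25)
        for _ in range(300):
            y = rng.gamma(5.0, 0.4, size=50)
            lams.append(
                gamma_adjusted_model(y, group, None, group_a="a", group_b="b").lam
            )
        assert np.mean(lams) == pytest.approx(1.0, abs=0.05)

    def test_covariate_explains_group_difference(self):
        """Adjusting for a confounder that carries the whole group effect
        attenuates the group statistic (constructed confounding)."""
        rng = np.random.default_rng(6)
        n = 40
        group = np.array(["a"] * n + ["b"] * n)
        cov = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        y = np.exp(0.5 * cov) * rng.gamma(8.0, 1 / 8.0, size=2 * n)
        unadj = gamma_adjusted_model(y, group, None, group_a="a", group_b="b")
        adj = gamma_adjusted_model(y, group, cov, group_a="a", group_b="b")
        assert abs(adj.t) < abs(unadj.t)

    def test_shift_recorded_for_nonpositive_measures(self):
        y = np.array([-0.2, 0.1, 0.4, 0.3, -0.1, 0.2, 0.5, 0.6])
        group = np.array(["a"] * 4 + ["b"] * 4)
        res = gamma_adjusted_model(y, group, None, group_a="a", group_b="b")
        assert res.shift > 0.2
        assert res.lam > 0

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            gamma_adjusted_model(
                [1.0, 2.0], ["x", "y"], None, group_a="a", group_b="b"
            )


class TestFdrBH:
    def test_hand_ladder(self):
        adj = fdr_bh([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.3]), [0.3])

    def test_all_ones_capped(self):
        np.testing.assert_allclose(fdr_bh([1.0, 1.0]), [1.0, 1.0])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-6, 1, size=40)
        ours = fdr_bh(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_explicit_larger_family(self):
        # 2 of 96 comparisons supplied: adjustment uses the declared family
        adj = fdr_bh([0.001, 0.5], m=96)
        assert adj[0] == pytest.approx(0.096)
        assert adj[1] == 1.0

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(1e-4, 1, size=25)
        adj = fdr_bh(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.0, 0.5])


class TestCompareGroups:
    def test_table_shape_and_not_computable_marking(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "group": ["CON"] * 8 + ["FEP"] * 8 + ["CHR-P"],
                "coherence": rng.normal(size=17),
            }
        )
        out = compare_groups(df, measures=("coherence",))
        assert len(out) == 3
        fep_con = out[(out.group_a == "FEP") & (out.group_b == "CON")].iloc[0]
        assert np.isfinite(fep_con.z)
        chr_con = out[(out.group_a == "CHR-P")].iloc[0]
        assert np.isnan(chr_con.z)  # single CHR-P subject: not computable

    def test_pipeline_associativity(self):
        """Aggregating then testing equals testing hand-aggregated values."""
        rng = np.random.default_rng(11)
        rows = []
        for g, n in (("CON", 6), ("FEP", 6)):
            for i in range(n):
                for _ in range(3):
                    rows.append(
                        {"subject_id": f"{g}{i}", "group": g,
                         "coherence": rng.normal()}
                    )
        df = pd.DataFrame(rows)
        subj = df.groupby(["subject_id", "group"], as_index=False).mean()
        res_pipeline = compare_groups(
            subj, measures=("coherence",), pairs=(("FEP", "CON"),)
        ).iloc[0]
        by_hand_a = [
            np.mean([r["coherence"] for r in rows if r["subject_id"] == f"FEP{i}"])
            for i in range(6)
        ]
        by_hand_b = [
            np.mean([r["coherence"] for r in rows if r["subject_id"] == f"CON{i}"])
            for i in range(6)
        ]
        res_hand = mann_whitney_z(by_hand_a, by_hand_b)
        assert res_pipeline.z == pytest.approx(res_hand.z, abs=1e-12)
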