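"""Edge-wise GLMs, permutation inference, FDR, and effect sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import geoconn as g
from geoconn.group_stats import build_design_matrix


class TestEdgeGLM:
    def test_identical_groups_give_zero_f(self):
        y = np.array([1.0, 2, 3, 1, 2, 3])
        labels = ["a"] * 3 + ["b"] * 3
        fit = g.fit_edge_glm(y, labels)
        assert fit.omnibus_F == pytest.approx(0.0, abs=1e-20)
        assert fit.partial_eta_sq == pytest.approx(0.0, abs=1e-20)

    def test_separated_groups_match_hand_computed_f(self, rng):
        """Two groups 0 vs 1 with tiny noise: F from explicit sums of squares."""
        y = np.concatenate([np.zeros(4), np.ones(4)]) + rng.normal(0, 1e-3, 8)
        labels = ["a"] * 4 + ["b"] * 4
        fit = g.fit_edge_glm(y, labels)
        # hand computation: between/within sums of squares
        ya, yb = y[:4], y[4:]
        ss_b = 4 * (ya.mean() - y.mean()) ** 2 + 4 * (yb.mean() - y.mean()) ** 2
        ss_w = ((ya - ya.mean()) ** 2).sum() + ((yb - yb.mean()) ** 2).sum()
        f_hand = (ss_b / 1) / (ss_w / 6)
        assert fit.omnibus_F == pytest.approx(f_hand, rel=1e-8)
        assert fit.p_value < 0.001
        assert fit.df == (1, 6)

    def test_matches_statsmodels_ols(self, rng):
        """Independent oracle: coefficients, RSS and partial F from a
        statsmodels OLS fit on the same design."""
        import statsmodels.api as sm

        n = 60
        labels = rng.choice(["a", "b", "c"], size=n)
        cov = pd.DataFrame({"age": rng.uniform(12, 48, n), "sex": rng.integers(0, 2, n)})
        y = rng.standard_normal(n) + (labels == "b") * 0.5
        fit = g.fit_edge_glm(y, labels, cov)
        x, names, k = build_design_matrix(pd.Series(labels), cov)
        sm_fit = sm.OLS(y, x).fit()
        np.testing.assert_allclose(
            list(fit.coefficients.values()), sm_fit.params, atol=1e-10
        )
        assert fit.rss == pytest.approx(sm_fit.ssr)
        f_test = sm_fit.f_test(np.eye(x.shape[1])[1 : 1 + k])
        assert fit.omnibus_F == pytest.approx(float(f_test.fvalue))
        assert fit.p_value == pytest.approx(float(f_test.pvalue))

    def test_degrees_of_freedom_reference_design(self, default_cohort, default_edges):
        """4 case-control group levels + age + sex on n=195 gives F(3, 189)."""
        _, cohort = default_cohort
        design = g.build_design(cohort.records, "case_control")
        labels = [design.labels[ev.subject_id] for ev in default_edges]
        cov = pd.DataFrame(
            {
                "age": [r.age_scan_months for r in cohort.records],
                "sex": [1.0 if r.sex == "M" else 0.0 for r in cohort.records],
            }
        )
        y = np.array([ev.values[0] for ev in default_edges])
        fit = g.fit_edge_glm(y, labels, cov)
        assert fit.df == (3, 189)

    def test_null_omnibus_p_uniform(self, rng):
        """With no planted effect, omnibus p-values across many synthetic
        edges are approximately uniform."""
        n = 80
        labels = np.repeat(["a", "b", "c", "d"], n // 4)
        ps = []
        for _ in range(2000):
            y = rng.standard_normal(n)
            ps.append(g.fit_edge_glm(y, labels).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_rank_deficient_design_rejected(self):
        y = np.arange(6, dtype=float)
        cov = pd.DataFrame({"c1": [1.0] * 6})  # collinear with intercept
        with pytest.raises(g.DesignError):
            g.fit_edge_glm(y, ["a", "a", "a", "b", "b", "b"], cov)


class TestFdrBH:
    def test_step_up_hand_example(self):
        """Thresholds i*q/m = 0.0167, 0.0333, 0.05 discover the first two."""
        reject, adj = g.fdr_bh([0.001, 0.02, 0.9], q=0.05)
        assert list(reject) == [True, True, False]
        np.testing.assert_allclose(adj, [0.003, 0.03, 0.9])

    def test_all_ones_no_discovery(self):
        reject, _ = g.fdr_bh([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()

    def test_single_p_reduces_to_raw_threshold(self):
        reject, adj = g.fdr_bh([0.04], q=0.05)
        assert reject[0] and adj[0] == pytest.approx(0.04)

    def test_discoveries_monotone_in_q(self, rng):
        p = rng.uniform(size=50)
        r1, _ = g.fdr_bh(p, q=0.01)
        r2, _ = g.fdr_bh(p, q=0.10)
        assert r1.sum() <= r2.sum()

    def test_empty_rejected(self):
        with pytest.raises(g.ValidationError):
            g.fdr_bh([])


class TestPermutationPairwise:
    def test_determinism(self, rng):
        y = rng.standard_normal(30)
        labels = ["a"] * 15 + ["b"] * 15
        p1 = g.permutation_pairwise(y, labels, "a", "b", n_perm=300, seed=7).perm_p
        p2 = g.permutation_pairwise(y, labels, "a", "b", n_perm=300, seed=7).perm_p
        assert p1 == p2

    def test_separated_groups_attain_minimum_p(self):
        y = np.concatenate([np.zeros(10), np.ones(10) + 5])
        labels = ["a"] * 10 + ["b"] * 10
        pc = g.permutation_pairwise(y, labels, "a", "b", n_perm=500, seed=0)
        assert pc.perm_p == pytest.approx(1 / 501)

    def test_parametric_f_matches_permutation_p_two_groups(self, rng):
        """For two groups without covariates, omnibus F = t^2 and the
        parametric p agrees with the permutation p at large n_perm."""
        y = rng.standard_normal(60) + np.repeat([0.0, 0.6], 30)
        labels = ["a"] * 30 + ["b"] * 30
        fit = g.fit_edge_glm(y, labels)
        t, _ = stats.ttest_ind(y[:30], y[30:])
        assert fit.omnibus_F == pytest.approx(t**2, rel=1e-10)
        pc = g.permutation_pairwise(y, labels, "a", "b", n_perm=20000, seed=1)
        assert pc.perm_p == pytest.approx(fit.p_value, abs=0.01)

    def test_tiny_group_rejected(self):
        y = np.arange(5, dtype=float)
        with pytest.raises(g.EstimabilityError):
            g.permutation_pairwise(y, ["a", "b", "b", "b", "b"], "a", "b", n_perm=100)

    def test_planted_edge_has_smallest_omnibus_p(self):
        """Subtype-model recovery: the edge carrying a GeoPref-specific
        deficit yields the smallest omnibus p among all edges in a majority
        of replicate cohorts."""
        import dataclasses

        base = g.CohortConfig(
            component_labels=("DMN", "OTC", "PVC", "DAN"),
            edge_effects=[
                g.EdgeEffect(("DMN", "OTC"), grp, 0.25)
                for grp in ["TD", "TD ASDSib", "LD/DD", "nonGeo ASD", "ASD-noET"]
            ]
            + [g.EdgeEffect(("DMN", "OTC"), "GeoPref ASD", 0.03)],
            behavior_coupling=[],
        )
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            cohort = g.generate_cohort(dataclasses.replace(base, seed=4000 + rep))
            evs = g.compute_edge_vectors(cohort.timeseries)
            design = g.build_design(cohort.records, "subtype")
            ids = [ev.subject_id for ev in evs if ev.subject_id in design.labels]
            ev_by_id = {ev.subject_id: ev for ev in evs}
            labels = [design.labels[i] for i in ids]
            ps = []
            for e_idx in range(len(evs[0].labels)):
                y = np.array([ev_by_id[i].values[e_idx] for i in ids])
                ps.append(g.fit_edge_glm(y, labels).p_value)
            target = evs[0].labels.index(("OTC", "DMN"))
            wins += int(np.argmin(ps) == target)
        assert wins > n_rep / 2


class TestEffectSizesAndBalance:
    def test_cohens_d_hand_example(self):
        assert g.cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_cohens_d_antisymmetric_and_zero(self, rng):
        x, y = rng.standard_normal(10), rng.standard_normal(12)
        assert g.cohens_d(x, y) == pytest.approx(-g.cohens_d(y, x))
        assert g.cohens_d(x, x) == 0.0

    def test_cohens_d_degenerate(self):
        with pytest.raises(g.DegenerateDataError):
            g.cohens_d([1.0, 1.0], [1.0, 1.0])

    def test_chi2_reference_sex_table(self):
        """Male/female counts of the six-group design give chi2(5) ~ 9.88."""
        table = [[27, 4], [11, 5], [49, 13], [10, 5], [8, 8], [37, 18]]
        chi2, df, p = g.contingency_chi2(table)
        assert chi2 == pytest.approx(9.88, abs=0.01)
        assert df == 5
        assert 0.05 < p < 0.10

    def test_chi2_homogeneous_tables_zero(self):
        assert g.contingency_chi2([[10, 10], [10, 10]])[0] == pytest.approx(0.0)
        chi2, df, _ = g.contingency_chi2([[20, 10], [40, 20], [60, 30]])
        assert chi2 == pytest.approx(0.0, abs=1e-12) and df == 2

    def test_chi2_zero_margin_rejected(self):
        with pytest.raises(g.DegenerateDataError):
            g.contingency_chi2([[0, 0], [5, 5]])

    def test_anova_equals_squared_t_for_two_groups(self, rng):
        x = rng.standard_normal(20)
        labels = np.repeat(["a", "b"], 10)
        f, (df1, df2), p = g.oneway_anova(x, labels)
        t, pt = stats.ttest_ind(x[:10], x[10:])
        assert f == pytest.approx(t**2) and p == pytest.approx(pt)
        assert (df1, df2) == (1, 18)

    def test_anova_constant_data_rejected(self):
        with pytest.raises(g.DegenerateDataError):
            g.oneway_anova([1.0] * 10, ["a"] * 5 + ["b"] * 5)
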