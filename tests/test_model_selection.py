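"""AIC, Delta-AIC support bands, and cross-validated MAPE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import geoconn as g
from geoconn.model_selection import (
    SUPPORT_CONSIDERABLY_LESS,
    SUPPORT_EQUIVALENT,
    SUPPORT_ESSENTIALLY_NONE,
    SUPPORT_INTERMEDIATE,
    _make_folds,
)


class TestGaussianAIC:
    def test_hand_evaluated_value(self):
        # n=10, rss=10, k=2: 10*(ln(2*pi) + 0 + 1) + 2*3
        assert g.gaussian_aic(rss=10, n=10, n_params=2) == pytest.approx(
            34.37877, abs=1e-4
        )

    def test_matches_r_style_lm_aic(self, rng):
        """Oracle: statsmodels OLS loglikelihood-based AIC plus the sigma^2
        parameter convention reproduces the same number."""
        import statsmodels.api as sm

        n = 40
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = x @ [1.0, 0.5] + rng.standard_normal(n)
        fit = sm.OLS(y, x).fit()
        # -2*llf + 2*(k+1): statsmodels llf is the Gaussian ML loglikelihood
        oracle = -2 * fit.llf + 2 * (x.shape[1] + 1)
        assert g.gaussian_aic(rss=fit.ssr, n=n, n_params=2) == pytest.approx(oracle)

    def test_identical_fits_tie(self):
        a = g.gaussian_aic(rss=3.3, n=20, n_params=4)
        assert g.delta_aic([a, a])[0].tolist() == [0.0, 0.0]

    def test_nonpositive_rss_rejected(self):
        with pytest.raises(g.DegenerateDataError):
            g.gaussian_aic(rss=0.0, n=10, n_params=2)


class TestDeltaAIC:
    @pytest.mark.parametrize(
        "aics, expected_delta",
        [
            ((-51.32, -47.60), 3.72),   # subtype vs case-control, DMN-OTC
            ((-87.72, -74.63), 13.09),  # subtype vs transdiagnostic, DMN-PVC
            ((-89.54, -87.72), 1.82),   # case-control vs subtype, DMN-PVC
        ],
    )
    def test_printed_aic_pairs(self, aics, expected_delta):
        deltas, _ = g.delta_aic(aics)
        assert deltas[0] == 0.0
        assert deltas[1] == pytest.approx(expected_delta, abs=0.005)

    def test_support_bands(self):
        deltas, labels = g.delta_aic([0.0, 1.5, 3.0, 5.0, 9.0])
        assert labels == [
            SUPPORT_EQUIVALENT,
            SUPPORT_EQUIVALENT,
            SUPPORT_INTERMEDIATE,
            SUPPORT_CONSIDERABLY_LESS,
            SUPPORT_ESSENTIALLY_NONE,
        ]

    @settings(max_examples=100, derandomize=True)
    @given(
        aics=st.lists(st.floats(-100, 100), min_size=2, max_size=6),
        shift=st.floats(-1000, 1000, allow_nan=False),
    )
    def test_invariant_to_additive_constant(self, aics, shift):
        d1, l1 = g.delta_aic(aics)
        d2, l2 = g.delta_aic([a + shift for a in aics])
        np.testing.assert_allclose(d1, d2, atol=1e-9)
        assert l1 == l2

    def test_nonfinite_rejected(self):
        with pytest.raises(g.ValidationError):
            g.delta_aic([1.0, np.inf])


class TestKfoldMape:
    def test_perfect_predictions_zero(self, rng):
        x = np.column_stack([np.ones(20), np.arange(20.0)])
        y = x @ [1.0, 2.0]
        _, mean_mape, _ = g.kfold_mape(y, x, k=5, seed=0)
        assert mean_mape == pytest.approx(0.0, abs=1e-8)

    def test_hand_evaluated_single_fold(self):
        """Actuals (1, 2), predictions (1, 1): mean(0%, 50%) = 25."""
        y = np.array([1.0, 1.0, 2.0, 1.0])
        x = np.ones((4, 1))  # intercept-only model predicts the train mean
        fold = np.array([0, 0, 1, 1])  # train on (1,1) -> predict 1 for (2,1)
        per_fold, _, n_zero = g.kfold_mape(y, x, fold_assignment=fold)
        assert per_fold[1] == pytest.approx(25.0)
        assert n_zero == 0

    def test_determinism_and_balanced_folds(self, rng):
        y = rng.standard_normal(53)
        x = np.column_stack([np.ones(53), rng.standard_normal(53)])
        f1 = g.kfold_mape(y, x, k=5, seed=9)
        f2 = g.kfold_mape(y, x, k=5, seed=9)
        assert f1 == f2
        folds = _make_folds(53, 5, seed=9)
        sizes = np.bincount(folds)
        assert sizes.max() - sizes.min() <= 1

    def test_too_few_subjects_rejected(self, rng):
        y = rng.standard_normal(8)
        x = np.ones((8, 1))
        with pytest.raises(g.EstimabilityError):
            g.kfold_mape(y, x, k=5)


@pytest.fixture(scope="module")
def comparison(default_cohort, default_edges):
    _, cohort = default_cohort
    idx = default_edges[0].labels.index(("OTC", "DMN"))
    series = pd.Series({ev.subject_id: ev.values[idx] for ev in default_edges})
    return g.compare_models(series, cohort.records, k=5, seed=0)


class TestCompareModels:

    def test_identical_subject_set_across_schemes(self, comparison):
        """AICs are only comparable on identical data: all schemes are fit on
        the 164 subjects with eye tracking."""
        assert comparison.n_subjects == 164
        ns = {len(f.mape_folds) for f in comparison.fits.values()}
        assert ns == {5}

    def test_exactly_one_zero_delta(self, comparison):
        zeros = [s for s, f in comparison.fits.items() if f.delta_aic == 0.0]
        assert len(zeros) == 1 and zeros[0] == comparison.preferred_by_aic

    def test_fold_assignment_shared(self, comparison, default_cohort, default_edges):
        """CV fairness: rerunning with the same seed reuses bit-identical
        folds for every scheme."""
        _, cohort = default_cohort
        idx = default_edges[0].labels.index(("OTC", "DMN"))
        series = pd.Series({ev.subject_id: ev.values[idx] for ev in default_edges})
        again = g.compare_models(series, cohort.records, k=5, seed=0)
        np.testing.assert_array_equal(
            comparison.fold_assignment, again.fold_assignment
        )
        for s in comparison.fits:
            assert comparison.fits[s].mape_folds == again.fits[s].mape_folds

    def test_subtype_model_wins_on_strong_geopref_deficit(self):
        """A cohort with a pronounced GeoPref-specific DMN-OTC deficit is fit
        best by the stratified subtype model."""
        cfg = g.CohortConfig(
            component_labels=("DMN", "OTC", "PVC", "DAN"),
            edge_effects=[
                g.EdgeEffect(("DMN", "OTC"), grp, 0.30)
                for grp in ["TD", "TD ASDSib", "LD/DD", "nonGeo ASD", "ASD-noET"]
            ]
            + [g.EdgeEffect(("DMN", "OTC"), "GeoPref ASD", 0.00)],
            behavior_coupling=[],
            seed=17,
        )
        cohort = g.generate_cohort(cfg)
        evs = g.compute_edge_vectors(cohort.timeseries)
        idx = evs[0].labels.index(("OTC", "DMN"))
        series = pd.Series({ev.subject_id: ev.values[idx] for ev in evs})
        rep = g.compare_models(series, cohort.records, k=5, seed=0)
        assert rep.preferred_by_aic == "subtype"

    def test_single_scheme_trivially_preferred(self, default_cohort, default_edges):
        _, cohort = default_cohort
        series = pd.Series({ev.subject_id: ev.values[0] for ev in default_edges})
        rep = g.compare_models(series, cohort.records, schemes=("case_control",))
        assert rep.fits["case_control"].delta_aic == 0.0
        assert rep.preferred_by_aic == "case_control"

    def test_mape_reduction_is_percentage_points(self, comparison):
        f = comparison.fits
        assert comparison.mape_reduction("subtype", "case_control") == pytest.approx(
            f["case_control"].mape_mean - f["subtype"].mape_mean
        )
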