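"""Synthetic cohort generator: structure, determinism, and oracle calibration."""

import dataclasses
from collections import Counter

import numpy as np
import pytest

import geoconn as g
from geoconn.cohort import _build_precision


class TestStructure:
    def test_default_cohort_matches_reference_design(self, default_cohort):
        _, cohort = default_cohort
        counts = Counter(r.group for r in cohort.records)
        assert sum(counts.values()) == 195
        assert counts["GeoPref ASD"] == 16
        assert counts["nonGeo ASD"] == 62
        assert counts["ASD-noET"] == 31
        assert counts["TD"] == 55
        assert len(cohort.timeseries) == 195
        assert len(cohort.motion) == 195
        assert all(ts.values.shape == (150, 4) for ts in cohort.timeseries)
        assert all(m.params.shape == (150, 6) for m in cohort.motion)

    def test_subtype_labels_consistent_with_cutoff(self, default_cohort):
        _, cohort = default_cohort
        for r in cohort.records:
            if r.group == "GeoPref ASD":
                assert r.pct_geo >= 69
            elif r.group == "nonGeo ASD":
                assert r.pct_geo < 69

    def test_missingness_pattern(self, default_cohort):
        """pct_geo missing iff no eye tracking; ADOS only in ASD groups."""
        _, cohort = default_cohort
        for r in cohort.records:
            assert (r.pct_geo is None) == (r.group == "ASD-noET")
            assert (r.ados_sa is not None) == r.is_asd
            if r.pct_geo is not None:
                assert 0 <= r.pct_geo <= 100

    def test_seed_determinism_bit_identical(self):
        cfg = g.CohortConfig(component_labels=("DMN", "OTC", "PVC", "DAN"), seed=5)
        c1 = g.generate_cohort(cfg)
        c2 = g.generate_cohort(dataclasses.replace(cfg))
        for a, b in zip(c1.timeseries, c2.timeseries):
            np.testing.assert_array_equal(a.values, b.values)
        for a, b in zip(c1.records, c2.records):
            assert a == b

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"group_sizes": {"TD": 0}},
            {"ar_coefficient": 1.0},
            {"edge_effects": [g.EdgeEffect(("DMN", "XX"), "TD", 0.3)]},
            {"edge_effects": [g.EdgeEffect(("DMN", "OTC"), "TD", 1.2)]},
            {"geo_cutoff_pct": 120.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        cfg = g.CohortConfig(component_labels=("DMN", "OTC", "PVC", "DAN"), **kwargs)
        with pytest.raises(g.ConfigurationError):
            g.generate_cohort(cfg)


class TestTrueEdgeOracle:
    def test_no_effects_gives_identity_precision_all_zero(self):
        cfg = g.CohortConfig(
            component_labels=("DMN", "OTC", "PVC"), edge_effects=[],
            behavior_coupling=[],
        )
        assert all(v == 0.0 for v in g.true_edge_values(cfg).values())

    def test_chain_precision_conditional_independence(self):
        """Partial correlation of an unplanted pair is exactly zero even when
        both members couple to a shared third component (chain structure)."""
        cfg = g.CohortConfig(
            group_sizes={"TD": 10},
            component_labels=("A", "B", "C"),
            edge_effects=[
                g.EdgeEffect(("A", "B"), "TD", -0.4),
                g.EdgeEffect(("B", "C"), "TD", -0.4),
            ],
            behavior_coupling=[],
        )
        tv = g.true_edge_values(cfg)
        assert tv[(("C", "A"), "TD")] == pytest.approx(0.0, abs=1e-15)
        assert tv[(("B", "A"), "TD")] == pytest.approx(-0.4)
        # hand check: with unit diagonal, partial corr = -theta_ij exactly
        theta = _build_precision(3, {(1, 0): -0.4, (2, 1): -0.4})
        d = np.sqrt(np.diag(theta))
        np.testing.assert_allclose(-theta[1, 0] / (d[1] * d[0]), -0.4)

    def test_planted_value_round_trips(self):
        cfg = g.CohortConfig(
            group_sizes={"TD": 5},
            component_labels=("DMN", "OTC", "PVC", "DAN"),
            edge_effects=[g.EdgeEffect(("DMN", "OTC"), "TD", 0.30)],
            behavior_coupling=[],
        )
        assert g.true_edge_values(cfg)[(("OTC", "DMN"), "TD")] == pytest.approx(0.30)

    def test_precision_shrunk_when_overloaded_but_positive_definite(self):
        theta = _build_precision(3, {(1, 0): -0.9, (2, 0): -0.9, (2, 1): -0.9})
        assert np.linalg.eigvalsh(theta).min() > 0


class TestCalibration:
    def test_mean_estimated_edge_matches_oracle(self):
        """Over 100 replicate cohorts, nearly-unregularized estimates at large
        T recover the generating partial correlation within 3 MC SEs."""
        cfg = g.CohortConfig(
            group_sizes={"TD": 6},
            component_labels=("DMN", "OTC", "PVC", "DAN"),
            n_timepoints=800,
            edge_effects=[g.EdgeEffect(("DMN", "OTC"), "TD", 0.30)],
            behavior_coupling=[],
            subject_edge_sd=0.0,
        )
        target = g.true_edge_values(cfg)[(("OTC", "DMN"), "TD")]
        conn = g.ConnectivityConfig(rho=1e-8, normalize_covariance=False, fisher=False)
        means = []
        for rep in range(100):
            cohort = g.generate_cohort(dataclasses.replace(cfg, seed=1000 + rep))
            evs = g.compute_edge_vectors(cohort.timeseries, conn)
            idx = evs[0].labels.index(("OTC", "DMN"))
            means.append(np.mean([ev.values[idx] for ev in evs]))
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - target) < 3 * se

    def test_behavior_coupling_converges_to_target(self):
        """With a large coupled group and low-noise edge estimates, the
        estimated-edge/ADOS correlation approaches the planted target."""
        cfg = g.CohortConfig(
            group_sizes={"GeoPref ASD": 300},
            component_labels=("DMN", "OTC", "PVC", "DAN"),
            n_timepoints=2000,
            edge_effects=[g.EdgeEffect(("DMN", "OTC"), "GeoPref ASD", 0.10)],
            behavior_coupling=[
                g.BehaviorCoupling(("DMN", "OTC"), "GeoPref ASD", -0.78, 3.5)
            ],
            seed=21,
        )
        cohort = g.generate_cohort(cfg)
        conn = g.ConnectivityConfig(rho=1e-6, normalize_covariance=False, fisher=False)
        evs = g.compute_edge_vectors(cohort.timeseries, conn)
        idx = evs[0].labels.index(("OTC", "DMN"))
        e = np.array([ev.values[idx] for ev in evs])
        b = np.array([r.ados_sa for r in cohort.records])
        r = np.corrcoef(e, b)[0, 1]
        assert r == pytest.approx(-0.78, abs=0.08)

    def test_motion_level_controls_mean_fd(self):
        cfg = g.CohortConfig(
            group_sizes={"TD": 40},
            component_labels=("DMN", "OTC"),
            motion_level={"TD": 0.10},
            motion_sd={"TD": 0.0},
            edge_effects=[],
            behavior_coupling=[],
            seed=3,
        )
        cohort = g.generate_cohort(cfg)
        fds = [g.framewise_displacement(m).mean_fd for m in cohort.motion]
        assert np.mean(fds) == pytest.approx(0.10, rel=0.15)
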