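"""Genetic values, population covariance, and the regional outlier test."""

import numpy as np
import pandas as pd
import pytest

from polyshift import (
    compute_genetic_values,
    estimate_population_covariance,
    regional_outlier_test,
)
from polyshift.containers import ControlPool, ControlSets, TraitSnpSet
from polyshift.genetic_values import SingularCovarianceError
from polyshift.matched_null import MODE_MAF_BVALUE
from _oracles import loop_genetic_values
from conftest import make_panel, make_trait_snps


def _pool(ids):
    return ControlPool(
        pd.DataFrame({"snp_id": ids, "matched_trait_snp": ids}), len(ids)
    )


def _sets(trait_ids, ids, flags, seed=0):
    return ControlSets(list(trait_ids), np.asarray(ids, dtype=object),
                       np.asarray(flags, dtype=bool), MODE_MAF_BVALUE, seed)


class TestGeneticValues:
    def test_zero_weights_give_zero_values(self):
        panel = make_panel({"P1": [0.2, 0.8], "P2": [0.4, 0.6]},
                           {"P1": "a", "P2": "b"})
        ts = make_trait_snps(["s0", "s1"], [0.0, 0.0])
        z = compute_genetic_values(ts, panel)
        assert (z == 0.0).all()

    def test_hand_arithmetic(self):
        panel = make_panel({"P1": [0.25], "P2": [0.75]}, {"P1": "a", "P2": "b"})
        ts = make_trait_snps(["s0"], [2.0])
        z = compute_genetic_values(ts, panel)
        assert z["P1"] == pytest.approx(0.5) and z["P2"] == pytest.approx(1.5)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_per_snp_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        panel = make_panel(
            {p: rng.uniform(0, 1, n).tolist() for p in ("P1", "P2", "P3")},
            {"P1": "a", "P2": "b", "P3": "b"},
        )
        ts = make_trait_snps([f"s{i}" for i in range(n)],
                             rng.exponential(0.3, n).tolist(),
                             increasing="G" if seed else "A")
        got = compute_genetic_values(ts, panel)
        want = loop_genetic_values(ts, panel)
        for pop in panel.populations:
            assert got[pop] == pytest.approx(want[pop], abs=1e-12)

    def test_empty_set_is_na(self):
        panel = make_panel({"P1": [0.5], "P2": [0.5]}, {"P1": "a", "P2": "b"})
        z = compute_genetic_values(make_trait_snps([], []), panel)
        assert z.isna().all()


class TestPopulationCovariance:
    def test_identical_frequencies_give_zero_matrix(self):
        panel = make_panel({"P1": [0.3, 0.6], "P2": [0.3, 0.6]},
                           {"P1": "a", "P2": "b"})
        F = estimate_population_covariance(_pool(["s0", "s1"]), panel, min_snps=1)
        assert np.allclose(F.to_numpy(), 0.0)

    def test_single_snp_hand_value(self):
        panel = make_panel({"P1": [0.2], "P2": [0.4]}, {"P1": "a", "P2": "b"})
        F = estimate_population_covariance(_pool(["s0"]), panel, min_snps=1)
        v = 0.01 / 0.21  # (0.1)^2 / (0.3 * 0.7)
        expect = np.array([[v, -v], [-v, v]])
        assert np.allclose(F.to_numpy(), expect, atol=1e-12)

    def test_fixed_snps_dropped_and_small_pools_warn(self):
        panel = make_panel({"P1": [0.0, 0.2], "P2": [0.0, 0.4]},
                           {"P1": "a", "P2": "b"})
        with pytest.warns(UserWarning, match="unstable"):
            F = estimate_population_covariance(_pool(["s0", "s1"]), panel)
        v = 0.01 / 0.21
        assert np.allclose(F.to_numpy(), [[v, -v], [-v, v]], atol=1e-12)

    def test_recovers_centered_generating_covariance(self, small_model, small_cohort):
        panel = small_cohort["panel"]
        F = estimate_population_covariance(
            _pool(panel.snp_ids.tolist()), panel
        ).to_numpy()
        m = len(small_model.population_labels)
        P = np.eye(m) - np.ones((m, m)) / m
        target = P @ small_model.F_true @ P
        assert np.linalg.norm(F - target) < 0.15 * np.linalg.norm(small_model.F_true)


class TestRegionalOutlier:
    def test_no_deviation_gives_zero_z_and_p_one(self):
        panel = make_panel(
            {p: [0.3, 0.6, 0.5, 0.2] for p in ("P1", "P2", "P3", "P4")},
            {"P1": "r1", "P2": "r1", "P3": "r2", "P4": "r2"},
        )
        ts = make_trait_snps(["s0", "s1"], [0.5, 0.2])
        F = estimate_population_covariance(_pool(["s2", "s3"]), panel, min_snps=1)
        sets = _sets(["s0", "s1"], [["s2", "s3"]] * 10, [[True, True]] * 10)
        res = regional_outlier_test(ts, panel, F, "r1", sets)
        assert res.regional_z == 0.0
        assert res.p_empirical == 1.0
        assert (res.population_z == 0.0).all()

    def test_two_singleton_regions_are_antisymmetric(self):
        rng = np.random.default_rng(5)
        n = 60
        panel = make_panel(
            {"P1": rng.uniform(0.1, 0.9, n).tolist(),
             "P2": rng.uniform(0.1, 0.9, n).tolist()},
            {"P1": "r1", "P2": "r2"},
        )
        ts = make_trait_snps([f"s{i}" for i in range(10)],
                             rng.exponential(0.3, 10).tolist())
        F = estimate_population_covariance(
            _pool([f"s{i}" for i in range(10, n)]), panel, min_snps=1
        )
        z1 = regional_outlier_test(ts, panel, F, "r1").regional_z
        z2 = regional_outlier_test(ts, panel, F, "r2").regional_z
        assert z1 == pytest.approx(-z2, abs=1e-10)

    def test_scale_invariance_in_effect_sizes(self, small_cohort, small_trait_snps):
        panel = small_cohort["panel"]
        pool_ids = [s for s in panel.snp_ids[:400]
                    if s not in set(small_trait_snps.snp_ids)]
        F = estimate_population_covariance(_pool(pool_ids), panel)
        rng = np.random.default_rng(0)
        L = len(small_trait_snps)
        ids = rng.choice(np.array(pool_ids, dtype=object), size=(50, L))
        flags = rng.random((50, L)) < 0.5
        sets = _sets(small_trait_snps.snp_ids, ids, flags)
        base = regional_outlier_test(small_trait_snps, panel, F, "R1", sets)
        scaled_table = small_trait_snps.table.copy()
        scaled_table["beta_abs"] *= 7.3
        scaled = TraitSnpSet(scaled_table, small_trait_snps.trait,
                             small_trait_snps.threshold)
        res = regional_outlier_test(scaled, panel, F, "R1", sets)
        assert res.regional_z == pytest.approx(base.regional_z, rel=1e-10)
        assert res.p_empirical == base.p_empirical

    def test_reported_values_center_to_zero(self, small_cohort, small_trait_snps):
        panel = small_cohort["panel"]
        F = estimate_population_covariance(_pool(panel.snp_ids[:500].tolist()), panel)
        res = regional_outlier_test(small_trait_snps, panel, F, "R1")
        assert abs(res.Z_centered.mean()) < 1e-10
        # population-count-weighted mean of regional values is zero
        sizes = pd.Series(
            {r: len(m) for r, m in panel.region_members().items()}
        )
        weighted = (res.regional_values * sizes).sum() / sizes.sum()
        assert abs(weighted) < 1e-10

    def test_singular_covariance_with_real_deviation_errors(self):
        # controls carry no drift signal (F_hat = 0) but trait SNPs deviate
        panel = make_panel(
            {"P1": [0.8, 0.3, 0.3], "P2": [0.2, 0.3, 0.3], "P3": [0.2, 0.3, 0.3],
             "P4": [0.2, 0.3, 0.3]},
            {"P1": "r1", "P2": "r2", "P3": "r2", "P4": "r2"},
        )
        ts = make_trait_snps(["s0"], [1.0])
        F = estimate_population_covariance(_pool(["s1", "s2"]), panel, min_snps=1)
        with pytest.raises(SingularCovarianceError):
            regional_outlier_test(ts, panel, F, "r1")

    def test_empty_trait_set_is_na(self):
        panel = make_panel({"P1": [0.5], "P2": [0.5]}, {"P1": "r1", "P2": "r2"})
        F = pd.DataFrame(np.eye(2) * 0.01, index=["P1", "P2"], columns=["P1", "P2"])
        res = regional_outlier_test(make_trait_snps([], []), panel, F, "r1")
        assert res.is_na and np.isnan(res.regional_z)

    def test_null_spread_matches_analytic_standardization(self, small_cohort,
                                                          small_trait_snps):
        # control-set z values should be approximately standard normal
        from polyshift import assign_bins, build_match_index, sample_control_sets
        from polyshift import sample_control_pool

        panel, ann = small_cohort["panel"], small_cohort["ann"]
        binned = assign_bins(panel, ann.bvalue_series(), ("R1P1", "R2P1"), "R1P1")
        index = build_match_index(binned, small_trait_snps,
                                  mode=MODE_MAF_BVALUE, on_empty="lenient")
        pool = sample_control_pool(index, 500, 1500, seed=9)
        F = estimate_population_covariance(pool, panel)
        sets = sample_control_sets(index, 400, seed=10)
        kept = small_trait_snps.table[
            small_trait_snps.table["snp_id"].isin(index.trait_snp_ids)
        ]
        ts = TraitSnpSet(kept.reset_index(drop=True), "trait1", 1e-6)
        res = regional_outlier_test(ts, panel, F, "R1", sets)
        assert 0.8 <= res.null_z_sd <= 1.25
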