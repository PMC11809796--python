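"""MAF/B-value binning, candidate matching, and control resampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from polyshift import (
    IntervalSet,
    assign_bins,
    build_match_index,
    sample_control_pool,
    sample_control_sets,
)
from polyshift.matched_null import (
    MODE_MAF,
    MODE_MAF_BVALUE,
    MatchingError,
    _bin_index,
)
from _oracles import brute_force_candidates
from conftest import make_panel, make_trait_snps


class TestBinAssignment:
    def test_high_frequency_maps_through_minor_allele(self):
        panel = make_panel({"T": [0.97], "R": [0.97]}, {"T": "a", "R": "b"})
        binned = assign_bins(panel, None, ("T", "R"), "T")
        assert binned.bins.loc["s0", "maf_bin_focal"] == 1  # MAF 0.03

    def test_pair_mean_maf_bin(self):
        panel = make_panel({"T": [0.10], "R": [0.20]}, {"T": "a", "R": "b"})
        binned = assign_bins(panel, None, ("T", "R"), "T")
        assert binned.bins.loc["s0", "maf_bin_pairwise"] == 7  # mean MAF 0.15

    def test_bvalue_1000_in_top_bin(self):
        panel = make_panel({"T": [0.5], "R": [0.5]}, {"T": "a", "R": "b"})
        bv = pd.Series([1000], index=panel.snp_ids)
        binned = assign_bins(panel, bv, ("T", "R"), "T")
        assert binned.bins.loc["s0", "b_bin"] == 9

    def test_maf_exactly_half_in_top_bin(self):
        panel = make_panel({"T": [0.5], "R": [0.5]}, {"T": "a", "R": "b"})
        binned = assign_bins(panel, None, ("T", "R"), "T")
        assert binned.bins.loc["s0", "maf_bin_focal"] == 24

    def test_missing_bvalue_flagged(self):
        panel = make_panel({"T": [0.3, 0.4], "R": [0.3, 0.4]}, {"T": "a", "R": "b"})
        bv = pd.Series([500], index=panel.snp_ids[:1])
        binned = assign_bins(panel, bv, ("T", "R"), "T")
        assert binned.bins.loc["s0", "b_bin"] == 5
        assert binned.bins.loc["s1", "b_bin"] == -1

    def test_interval_and_series_bvalues_agree(self, small_cohort, tmp_path):
        from polyshift.simulate import write_bvalues_bed

        panel, ann = small_cohort["panel"], small_cohort["ann"]
        write_bvalues_bed(panel, ann, tmp_path / "b.bed")
        bed = IntervalSet.from_bed(tmp_path / "b.bed", valued=True)
        via_bed = assign_bins(panel, bed, ("R1P1", "R2P1"), "R1P1")
        via_series = assign_bins(panel, ann.bvalue_series(), ("R1P1", "R2P1"), "R1P1")
        pd.testing.assert_frame_equal(via_bed.bins, via_series.bins)

    def test_unknown_population_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown population"):
            assign_bins(small_cohort["panel"], None, ("R1P1", "nope"), "R1P1")

    @given(st.floats(0.0, 1.0, allow_nan=False))
    def test_bin_index_consistent_with_floor(self, maf_like):
        v = min(maf_like, 1.0 - maf_like)
        idx = _bin_index(np.array([v]), 0.02, 25)[0]
        assert idx == min(int(v / 0.02), 24)
        assert 0 <= idx <= 24


class TestMatchIndex:
    def _random_binned(self, seed, n=300):
        rng = np.random.default_rng(seed)
        panel = make_panel(
            {"T": rng.uniform(0.02, 0.98, n).tolist(),
             "R": rng.uniform(0.02, 0.98, n).tolist()},
            {"T": "a", "R": "b"},
        )
        bv = pd.Series(rng.integers(0, 1001, n), index=panel.snp_ids)
        bv = bv.mask(pd.Series(rng.random(n) < 0.1, index=panel.snp_ids))
        return panel, assign_bins(panel, bv, ("T", "R"), "T")

    @pytest.mark.parametrize("mode", [MODE_MAF, MODE_MAF_BVALUE])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_quadratic_oracle(self, mode, seed):
        panel, binned = self._random_binned(seed)
        trait_ids = [f"s{i}" for i in range(0, 30)]
        ts = make_trait_snps(trait_ids, [0.1] * 30)
        index = build_match_index(binned, ts, mode=mode, on_empty="lenient")
        oracle = brute_force_candidates(binned.bins, trait_ids, mode)
        for tid in trait_ids:
            got = set(index.candidates.get(tid, []))
            assert got == oracle[tid]
        for tid in index.excluded_trait_snps:
            assert oracle[tid] == set()

    def test_trait_snps_never_their_own_controls(self, small_cohort, small_trait_snps):
        binned = assign_bins(
            small_cohort["panel"], small_cohort["ann"].bvalue_series(),
            ("R1P1", "R2P1"), "R1P1",
        )
        index = build_match_index(binned, small_trait_snps, mode=MODE_MAF)
        trait_set = set(small_trait_snps.snp_ids)
        for cands in index.candidates.values():
            assert trait_set.isdisjoint(cands)

    def test_strict_mode_errors_on_unmatchable_snp(self):
        # isolated bins: each SNP alone in its mean-MAF bin
        panel = make_panel(
            {"T": [0.05, 0.15, 0.25], "R": [0.05, 0.15, 0.25]},
            {"T": "a", "R": "b"},
        )
        binned = assign_bins(panel, None, ("T", "R"), "T")
        ts = make_trait_snps(["s0"], [0.1])
        with pytest.raises(MatchingError, match="s0"):
            build_match_index(binned, ts, mode=MODE_MAF, on_empty="strict")
        with pytest.warns(UserWarning, match="excluding 1"):
            idx = build_match_index(binned, ts, mode=MODE_MAF, on_empty="lenient")
        assert idx.trait_snp_ids == []


class TestControlSets:
    def _index(self, n_candidates=3):
        freqs = [0.30] * (1 + n_candidates)
        panel = make_panel({"T": freqs, "R": freqs}, {"T": "a", "R": "b"})
        binned = assign_bins(panel, None, ("T", "R"), "T")
        ts = make_trait_snps(["s0"], [0.1])
        return build_match_index(binned, ts, mode=MODE_MAF)

    def test_deterministic_given_seed(self):
        index = self._index()
        a = sample_control_sets(index, 50, seed=7)
        b = sample_control_sets(index, 50, seed=7)
        assert np.array_equal(a.ids, b.ids)
        assert np.array_equal(a.use_allele1, b.use_allele1)

    def test_singleton_candidates_force_identical_sets(self):
        index = self._index(n_candidates=1)
        sets = sample_control_sets(index, 20, seed=1)
        assert (sets.ids == sets.ids[0, 0]).all()

    def test_draw_frequencies_are_uniform(self):
        index = self._index(n_candidates=3)
        sets = sample_control_sets(index, 30_000, seed=3)
        counts = pd.Series(sets.ids[:, 0]).value_counts(normalize=True)
        sigma = np.sqrt((1 / 3) * (2 / 3) / 30_000)
        assert np.abs(counts - 1 / 3).max() < 3 * sigma
        # orientation flags are a fair coin from the same stream
        assert abs(sets.use_allele1.mean() - 0.5) < 3 * np.sqrt(0.25 / 30_000)

    def test_bin_equality_holds_for_every_draw(self, small_cohort, small_trait_snps):
        binned = assign_bins(
            small_cohort["panel"], small_cohort["ann"].bvalue_series(),
            ("R1P1", "R2P1"), "R1P1",
        )
        index = build_match_index(
            binned, small_trait_snps, mode=MODE_MAF_BVALUE, on_empty="lenient"
        )
        sets = sample_control_sets(index, 25, seed=5)
        bins = binned.bins
        for l, tid in enumerate(sets.trait_snp_ids):
            want = bins.loc[tid, ["maf_bin_focal", "b_bin"]]
            for cid in np.unique(sets.ids[:, l]):
                got = bins.loc[cid, ["maf_bin_focal", "b_bin"]]
                assert (got == want).all()

    def test_rejects_nonpositive_set_count(self):
        with pytest.raises(ValueError):
            sample_control_sets(self._index(), 0, seed=1)

    def test_round_trip_serialization(self, tmp_path):
        sets = sample_control_sets(self._index(), 10, seed=2)
        sets.write(tmp_path / "cs.tsv", tmp_path / "cs.json")
        from polyshift.containers import ControlSets

        back = ControlSets.read(tmp_path / "cs.tsv", tmp_path / "cs.json")
        assert np.array_equal(back.ids, sets.ids)
        assert np.array_equal(back.use_allele1, sets.use_allele1)
        assert back.mode == sets.mode and back.seed == sets.seed


class TestControlPool:
    def test_per_snp_cap_bounds_pool_size(self, small_cohort, small_trait_snps):
        binned = assign_bins(
            small_cohort["panel"], small_cohort["ann"].bvalue_series(),
            ("R1P1", "R2P1"), "R1P1",
        )
        index = build_match_index(binned, small_trait_snps, mode=MODE_MAF,
                                  on_empty="lenient")
        pool = sample_control_pool(index, per_snp_cap=1, target_total=10_000, seed=1)
        assert len(pool) <= len(index.trait_snp_ids)

    def test_exhaustion_warns_and_returns_everything(self):
        freqs = [0.30] * 4
        panel = make_panel({"T": freqs, "R": freqs}, {"T": "a", "R": "b"})
        binned = assign_bins(panel, None, ("T", "R"), "T")
        ts = make_trait_snps(["s0"], [0.1])
        index = build_match_index(binned, ts, mode=MODE_MAF)
        with pytest.warns(UserWarning, match="10%"):
            pool = sample_control_pool(index, 2_000, 100_000, seed=1)
        assert sorted(pool.snp_ids) == ["s1", "s2", "s3"]

    def test_membership_and_deduplication(self, small_cohort, small_trait_snps):
        binned = assign_bins(
            small_cohort["panel"], small_cohort["ann"].bvalue_series(),
            ("R1P1", "R2P1"), "R1P1",
        )
        index = build_match_index(binned, small_trait_snps,
                                  mode=MODE_MAF_BVALUE, on_empty="lenient")
        pool = sample_control_pool(index, 50, 500, seed=4)
        ids = pool.snp_ids
        assert len(ids) == len(set(ids))
        allowed = set().union(*(set(c) for c in index.candidates.values()))
        assert set(ids) <= allowed
        # every pool member is bin-matched to the trait SNP it is recorded under
        bins = binned.bins
        for _, row in pool.table.iterrows():
            want = bins.loc[row["matched_trait_snp"], ["maf_bin_focal", "b_bin"]]
            got = bins.loc[row["snp_id"], ["maf_bin_focal", "b_bin"]]
            assert (got == want).all()
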