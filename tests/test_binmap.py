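"""Window rule, block formation, bin partition, and heterozygosity."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import ionoqtl as iq
from ionoqtl import binmap as bg
from ionoqtl.codes import HET, LM, MISSING, TQ


def _table(chrom, pos, calls, depth=None, ril_ids=None):
    """Build a SnpTable from plain arrays (one or more RILs)."""
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 1:
        calls = calls[:, None]
    n, k = calls.shape
    if depth is None:
        depth = np.where(calls == MISSING, 0, 5).astype(np.int16)
    sites = pd.DataFrame({
        "chrom": np.asarray(chrom), "pos": np.asarray(pos),
        "p1_allele": "A", "p2_allele": "G",
        "p1_depth": 30, "p2_depth": 30, "p1_hom": True, "p2_hom": True,
    })
    return bg.SnpTable(sites=sites, calls=calls, depth=depth,
                       ril_ids=ril_ids or [f"R{i}" for i in range(k)])


class TestFilterSnps:
    def test_adjacent_snps_both_removed(self):
        t = _table([1, 1, 1], [100, 103, 5000], [LM, LM, LM])
        out, report = iq.filter_snps(t)
        assert list(out.sites["pos"]) == [5000]
        assert report["adjacent"] == 2

    def test_identical_parent_alleles_removed(self):
        t = _table([1, 1], [100, 5000], [LM, LM])
        t.sites.loc[0, "p2_allele"] = "A"
        out, report = iq.filter_snps(t)
        assert list(out.sites["pos"]) == [5000]
        assert report["parent_not_informative"] == 1

    def test_heterozygous_parent_removed(self):
        t = _table([1, 1], [100, 5000], [LM, LM])
        t.sites.loc[0, "p1_hom"] = False
        out, _ = iq.filter_snps(t)
        assert list(out.sites["pos"]) == [5000]

    def test_shallow_parent_removed(self):
        t = _table([1, 1], [100, 5000], [LM, LM])
        t.sites.loc[0, "p1_depth"] = 3
        out, report = iq.filter_snps(t)
        assert report["parent_low_depth"] == 1
        assert list(out.sites["pos"]) == [5000]

    def test_indel_adjacency_removed(self):
        t = _table([1, 1], [100, 5000], [LM, LM])
        indels = pd.DataFrame({"chrom": [1], "pos": [98]})
        out, _ = iq.filter_snps(t, indel_positions=indels)
        assert list(out.sites["pos"]) == [5000]

    def test_clean_table_passes_through(self):
        t = _table([1, 1, 1], [100, 200, 300], [[LM], [TQ], [LM]])
        out, report = iq.filter_snps(t)
        assert out.n_sites == 3
        assert report["retained"] == 3

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            _table([1, 1], [200, 100], [LM, LM])


class TestWindowRule:
    def test_exhaustive_composition_labelling(self):
        """Every (c_TQ, c_LM) with c_TQ + c_LM <= 15 maps to exactly the
        documented label: parental majority > 11, two-sided HET >= 4 each,
        else missing."""
        W = 15
        for c_tq in range(W + 1):
            for c_lm in range(W + 1 - c_tq):
                calls = np.asarray(
                    [TQ] * c_tq + [LM] * c_lm + [HET] * (W - c_tq - c_lm),
                    dtype=np.int8)
                t = _table([1] * W, np.arange(1, W + 1) * 100, calls)
                wc = iq.call_windows(t, 0)
                labels, anchors = wc[1]
                assert len(labels) == 1
                if c_tq > 11:
                    expected = TQ
                elif c_lm > 11:
                    expected = LM
                elif c_tq >= 4 and c_lm >= 4:
                    expected = HET
                else:
                    expected = MISSING
                assert labels[0] == expected, (c_tq, c_lm)
                assert anchors[0] == 800  # median of 15 positions

    @pytest.mark.parametrize("c_tq,c_lm,expected", [
        (12, 3, TQ),     # parental majority
        (0, 15, LM),     # unanimous window
        (8, 7, HET),     # intermediate, two-sided evidence
        (14, 1, TQ),
        (3, 3, MISSING),
    ])
    def test_documented_examples(self, c_tq, c_lm, expected):
        W = 15
        calls = np.asarray(
            [TQ] * c_tq + [LM] * c_lm + [HET] * (W - c_tq - c_lm),
            dtype=np.int8)
        t = _table([1] * W, np.arange(1, W + 1) * 100, calls)
        labels, _ = iq.call_windows(t, 0)[1]
        assert labels[0] == expected

    def test_windows_slide_over_observed_calls_only(self):
        """MISSING sites do not enter windows; 20 observed of 40 sites
        yield 20 - 15 + 1 windows."""
        calls = np.asarray([TQ, MISSING] * 20, dtype=np.int8)
        t = _table([1] * 40, np.arange(1, 41) * 100, calls)
        labels, _ = iq.call_windows(t, 0)[1]
        assert len(labels) == 6
        assert (labels == TQ).all()

    def test_short_chromosome_warns_and_yields_nothing(self):
        t = _table([1] * 5, np.arange(1, 6) * 100,
                   np.asarray([TQ] * 5, dtype=np.int8))
        with pytest.warns(UserWarning, match="no windows"):
            labels, _ = iq.call_windows(t, 0)[1]
        assert len(labels) == 0

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            bg.WindowCallParams(window_snps=15, majority_threshold=15)


def _wc(labels, anchors=None):
    labels = np.asarray(labels, dtype=np.int8)
    if anchors is None:
        anchors = (np.arange(len(labels)) + 1) * 1000
    return {1: (labels, np.asarray(anchors, dtype=np.int64))}


class TestBlocks:
    def test_single_transition_breakpoint_at_midpoint(self):
        blocks = iq.call_blocks(_wc([TQ] * 40 + [LM] * 40))
        bounds, labels = blocks[1]
        assert list(labels) == [TQ, LM]
        assert bounds[0] == (40_000 + 41_000) // 2

    def test_uniform_labels_single_block(self):
        bounds, labels = iq.call_blocks(_wc([TQ] * 50))[1]
        assert len(bounds) == 0
        assert list(labels) == [TQ]

    def test_transition_het_zone_absorbed(self):
        """The ~8-window HET footprint of a crossover is a transition, not
        a heterozygous segment; the breakpoint lands at its midpoint."""
        bounds, labels = iq.call_blocks(
            _wc([TQ] * 30 + [HET] * 8 + [LM] * 30))[1]
        assert list(labels) == [TQ, LM]
        assert bounds[0] == (30_000 + 39_000) // 2

    def test_long_het_run_kept_as_block(self):
        bounds, labels = iq.call_blocks(
            _wc([TQ] * 30 + [HET] * 20 + [LM] * 30))[1]
        assert list(labels) == [TQ, HET, LM]
        assert len(bounds) == 2

    def test_het_between_agreeing_flanks_kept(self):
        """A short HET run inside one parental background marks a real
        (double-crossover) segment and keeps its breakpoints."""
        bounds, labels = iq.call_blocks(
            _wc([TQ] * 30 + [HET] * 5 + [TQ] * 30))[1]
        assert list(labels) == [TQ, HET, TQ]
        assert len(bounds) == 2

    def test_missing_run_absorbed_when_flanks_agree(self):
        bounds, labels = iq.call_blocks(
            _wc([TQ] * 20 + [MISSING] * 10 + [TQ] * 20))[1]
        assert list(labels) == [TQ]

    def test_missing_run_kept_when_flanks_differ(self):
        bounds, labels = iq.call_blocks(
            _wc([TQ] * 20 + [MISSING] * 10 + [LM] * 20))[1]
        assert list(labels) == [TQ, MISSING, LM]

    def test_empty_chromosome_yields_missing_block(self):
        bounds, labels = iq.call_blocks(
            {1: (np.empty(0, dtype=np.int8),
                 np.empty(0, dtype=np.int64))})[1]
        assert list(labels) == [MISSING]


class TestBinMap:
    def test_union_of_breakpoints_gives_three_bins(self):
        blocks = [
            {1: (np.asarray([1_000_000]), np.asarray([TQ, LM],
                                                     dtype=np.int8))},
            {1: (np.asarray([1_500_000]), np.asarray([LM, TQ],
                                                     dtype=np.int8))},
        ]
        bm = iq.build_bin_map(blocks, {1: (0, 3_000_000)}, ["a", "b"],
                              min_bin_bp=1, exempt_chroms=())
        assert bm.n_bins == 3
        assert bm.geno[:, 0].tolist() == [TQ, LM, LM]
        assert bm.geno[:, 1].tolist() == [LM, LM, TQ]

    def test_partition_property(self, small_bins, small_snps):
        """Bins tile exactly the SNP-covered span of each chromosome."""
        for chrom in small_snps.chroms:
            sub = small_bins.bins[small_bins.bins["chrom"] == chrom]
            lo, hi = small_snps.chrom_span(chrom)
            assert sub["start_bp"].iloc[0] == lo
            assert sub["end_bp"].iloc[-1] == hi
            assert (sub["start_bp"].iloc[1:].to_numpy()
                    == sub["end_bp"].iloc[:-1].to_numpy()).all()

    def test_short_bins_merged_unless_exempt(self):
        blocks = [
            {1: (np.asarray([1_000_000, 1_005_000]),
                 np.asarray([TQ, LM, TQ], dtype=np.int8))},
            {1: (np.asarray([], dtype=np.int64),
                 np.asarray([TQ], dtype=np.int8))},
        ]
        spans = {1: (0, 3_000_000)}
        bm = iq.build_bin_map(blocks, spans, ["a", "b"], min_bin_bp=20_000,
                              exempt_chroms=())
        assert (bm.lengths_bp >= 20_000).all()
        bm_ex = iq.build_bin_map(blocks, spans, ["a", "b"],
                                 min_bin_bp=20_000, exempt_chroms=(1,))
        assert (bm_ex.lengths_bp < 20_000).any()

    def test_calling_is_ril_permutation_equivariant(self, small_snps):
        perm = np.arange(len(small_snps.ril_ids))[::-1]
        shuffled = bg.SnpTable(
            sites=small_snps.sites.copy(),
            calls=small_snps.calls[:, perm],
            depth=small_snps.depth[:, perm],
            ril_ids=[small_snps.ril_ids[i] for i in perm])
        a = iq.genotype_rils(small_snps, exempt_chroms=())
        b = iq.genotype_rils(shuffled, exempt_chroms=())
        assert a.bins[["chrom", "start_bp", "end_bp"]].equals(
            b.bins[["chrom", "start_bp", "end_bp"]])
        assert np.array_equal(a.geno[:, perm], b.geno)

    def test_bin_genotypes_match_truth_at_high_depth(self):
        # rice-like recombination density (~5 cM/Mb)
        cfg = iq.SimConfig(n_ril=100, n_chrom=1, chrom_len_bp=10_000_000,
                           chrom_len_cM=50.0, n_snp_per_chrom=2000,
                           mean_depth=50.0, genotyping_error=0.0, seed=5)
        truth = iq.simulate_ril_genomes(cfg)
        snps, _ = iq.filter_snps(iq.simulate_snp_observations(truth))
        bm = iq.genotype_rils(snps, exempt_chroms=())
        mids = ((bm.bins["start_bp"] + bm.bins["end_bp"]) / 2).to_numpy()
        tg = truth.genotype_at(1, mids).T
        called = bm.geno != MISSING
        assert (bm.geno[called] == tg[called]).mean() >= 0.999


class TestHeterozygosity:
    def _bm(self, geno):
        geno = np.asarray(geno, dtype=np.int8)
        n = geno.shape[0]
        edges = np.arange(n + 1) * 100_000
        bins = pd.DataFrame({"chrom": 1, "start_bp": edges[:-1],
                             "end_bp": edges[1:], "n_merged": 1})
        return iq.BinMatrix(bins=bins, geno=geno,
                            ril_ids=[f"R{i}" for i in
                                     range(geno.shape[1])])

    def test_no_het_gives_zero(self):
        _, pop = iq.heterozygosity(self._bm([[LM, TQ]] * 4))
        assert pop == 0.0

    def test_fully_het_ril_gives_one(self):
        per, _ = iq.heterozygosity(self._bm([[HET, LM]] * 4))
        assert per.iloc[0] == 1.0
        assert per.iloc[1] == 0.0

    def test_all_missing_ril_flagged_nan(self):
        with pytest.warns(UserWarning, match="no called bins"):
            per, _ = iq.heterozygosity(self._bm([[MISSING, LM]] * 4))
        assert np.isnan(per.iloc[0])

    def test_bp_weighting(self):
        bm = self._bm([[HET], [LM]])
        bm.bins.loc[0, "end_bp"] = 300_000   # HET bin 3x longer
        bm.bins.loc[1, "start_bp"] = 300_000
        bm.bins.loc[1, "end_bp"] = 400_000
        per, _ = iq.heterozygosity(bm)
        assert per.iloc[0] == pytest.approx(0.75)

    def test_f20_simulation_nearly_homozygous(self, small_bins):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pop = iq.heterozygosity(small_bins)
        assert pop < 0.02
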