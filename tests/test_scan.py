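"""Genotype probabilities, HK/imputation scans, permutations, peaks."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import ionoqtl as iq
from ionoqtl.codes import LM, MISSING, TQ
from ionoqtl.linkage import inverse_map_distance, ril_observed

from conftest import random_bin_matrix


def _probs_for(bm):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lmap = iq.build_linkage_map(bm)
        return iq.genotype_probs(bm, lmap), lmap


def brute_force_lod(x: np.ndarray, y: np.ndarray) -> float:
    """Independent oracle: direct least squares at a single marker."""
    X1 = np.column_stack([np.ones_like(x), x])
    rss1 = np.linalg.lstsq(X1, y, rcond=None)[1]
    rss1 = float(rss1[0]) if len(rss1) else float(
        ((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2).sum())
    rss0 = float(((y - y.mean()) ** 2).sum())
    return (len(y) / 2.0) * np.log10(rss0 / rss1)


class TestGenoProbs:
    def test_observed_marker_is_delta(self, small_probs, small_bins,
                                      small_map):
        """P(TQ) is exactly 0/1 at an observed parental bin marker."""
        for lg, g in small_probs.groups.items():
            sub = small_map.table[small_map.table["lg"] == lg]
            for mp, b in zip(sub["cm"], sub["bin_id"]):
                j = int(np.argmin(np.abs(g.pos - mp)))
                geno = small_bins.geno[b]
                for r in range(len(small_probs.ril_ids)):
                    if geno[r] == TQ:
                        assert g.p_tq[r, j] >= 1.0 - 1e-9
                    elif geno[r] == LM:
                        assert g.p_tq[r, j] <= 1e-9
            break  # one group suffices

    def test_all_missing_ril_is_uniform(self):
        rng = np.random.default_rng(0)
        bm = random_bin_matrix(rng, n_ril=10, n_bins=8, n_chrom=1)
        bm.geno[:, 3] = MISSING
        probs, _ = _probs_for(bm)
        assert np.allclose(probs.groups[1].p_tq[3], 0.5)

    def test_midpoint_between_lm_markers_matches_closed_form(self):
        """Two LM markers 2 cM apart: the midpoint posterior follows the
        two-state chain closed form R1 R2 / (R1 R2 + (1-R1)(1-R2))."""
        geno = np.asarray([[LM] * 22, [LM] * 22], dtype=np.int8)
        # engineer R corresponding to ~2 cM with 22 informative RILs
        bins = pd.DataFrame({"chrom": 1,
                             "start_bp": [0, 1_000_000],
                             "end_bp": [1_000_000, 2_000_000],
                             "n_merged": 1})
        bm = iq.BinMatrix(bins=bins, geno=geno, ril_ids=[f"R{i}"
                                                         for i in range(22)])
        # manual map with 2 cM spacing
        table = pd.DataFrame({
            "lg": [1, 1], "bin_id": [0, 1], "chrom": [1, 1],
            "start_bp": [0, 1_000_000], "end_bp": [1_000_000, 2_000_000],
            "cm": [0.0, 2.0], "r_obs": [np.nan, 0.02],
            "r_meiotic": [np.nan, 0.01], "n_informative": [0, 22]})
        lmap = iq.LinkageMap(table=table, map_function="kosambi")
        probs = iq.genotype_probs(bm, lmap, step_cM=1.0)
        g = probs.groups[1]
        j = int(np.argmin(np.abs(g.pos - 1.0)))
        R = ril_observed(inverse_map_distance(1.0, "kosambi"))
        expected = R * R / (R * R + (1 - R) * (1 - R))
        assert g.p_tq[0, j] == pytest.approx(expected, abs=1e-12)
        assert expected < 0.01

    def test_empty_map_rejected(self, small_bins):
        empty = iq.LinkageMap(table=pd.DataFrame(
            columns=["lg", "bin_id", "chrom", "start_bp", "end_bp", "cm",
                     "r_obs", "r_meiotic", "n_informative"]),
            map_function="kosambi")
        with pytest.raises(ValueError):
            iq.genotype_probs(small_bins, empty)


class TestHkScan:
    def test_matches_single_marker_regression_oracle(self):
        """HK LOD at marker positions equals brute-force least squares."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            bm = random_bin_matrix(rng, n_ril=40, n_bins=12)
            probs, lmap = _probs_for(bm)
            y = rng.standard_normal(40)
            curve = iq.hk_scan(probs, y, name="t")
            X, meta = probs.x_matrix()
            for lg, sub in lmap.table.groupby("lg"):
                g = probs.groups[lg]
                for mp, b in zip(sub["cm"], sub["bin_id"]):
                    j = int(np.argmin(np.abs(g.pos - mp)))
                    x = 2.0 * g.p_tq[:, j] - 1.0
                    expected = brute_force_lod(x, y)
                    got = curve.table.loc[
                        (curve.table["lg"] == lg)
                        & (np.abs(curve.table["pos_cM"] - g.pos[j]) < 1e-9),
                        "lod"].iloc[0]
                    assert got == pytest.approx(expected, abs=1e-8)

    def test_lod_nonnegative(self, small_probs, small_pheno):
        curve = iq.hk_scan(small_probs, small_pheno["02GF"]["Cu"])
        assert (curve.table["lod"] >= 0).all()

    def test_planted_qtl_lod_near_theory(self, small_probs, small_pheno,
                                         small_truth):
        """Expected peak LOD approximates -(n/2) log10(1 - PVE)."""
        curve = iq.hk_scan(small_probs, small_pheno["02GF"]["Cu"])
        pve = small_truth.realized_pve
        theo = pve[(pve["element"] == "Cu")
                   & (pve["env"] == "02GF")]["realized_pve"].iloc[0]
        expected = float(iq.lod_from_pve(theo, curve.n_used))
        assert curve.max_lod() > 0.4 * expected

    def test_missing_trait_values_dropped(self, small_probs, small_pheno):
        y = small_pheno["02GF"]["Cu"].copy()
        y.iloc[:5] = np.nan
        curve = iq.hk_scan(small_probs, y)
        assert curve.n_used == len(y) - 5

    def test_constant_trait_rejected(self, small_probs):
        with pytest.raises(ValueError):
            iq.hk_scan(small_probs, np.ones(len(small_probs.ril_ids)))


class TestImputationScan:
    def test_matches_hk_at_markers_under_full_observation(self):
        rng = np.random.default_rng(2)
        bm = random_bin_matrix(rng, n_ril=30, n_bins=10)
        probs, lmap = _probs_for(bm)
        y = rng.standard_normal(30)
        hk = iq.hk_scan(probs, y, name="t")
        imp = iq.imputation_scan(probs, y, n_imputations=8, seed=0,
                                 name="t")
        _, meta = probs.x_matrix()
        at_marker = meta["is_marker"].to_numpy()
        assert np.allclose(hk.table["lod"].to_numpy()[at_marker],
                           imp.table["lod"].to_numpy()[at_marker],
                           atol=1e-8)

    def test_deterministic_given_seed(self, small_probs, small_pheno):
        y = small_pheno["02GF"]["Cu"]
        a = iq.imputation_scan(small_probs, y, n_imputations=4, seed=7)
        b = iq.imputation_scan(small_probs, y, n_imputations=4, seed=7)
        assert np.array_equal(a.table["lod"], b.table["lod"])

    def test_agrees_with_hk_on_sparse_panel(self, small_probs,
                                            small_pheno):
        """Method agreement: imputation within 0.5 LOD of HK at the peak."""
        y = small_pheno["02GF"]["Cu"]
        hk = iq.hk_scan(small_probs, y)
        imp = iq.imputation_scan(small_probs, y, n_imputations=64, seed=1)
        assert abs(hk.max_lod() - imp.max_lod()) < 0.5


class TestPermutation:
    def test_alpha_one_gives_minimum(self, small_probs, small_pheno):
        y = small_pheno["02GF"]["Cu"]
        res = iq.permute_threshold(small_probs, y, n_perm=100, alpha=1.0,
                                   seed=0)
        assert res.threshold == pytest.approx(res.max_lods.min())

    def test_deterministic_given_seed(self, small_probs, small_pheno):
        y = small_pheno["02GF"]["Cu"]
        a = iq.permute_threshold(small_probs, y, n_perm=120, seed=3)
        b = iq.permute_threshold(small_probs, y, n_perm=120, seed=3)
        assert a.threshold == b.threshold

    def test_quantile_stable_in_n_perm(self, small_probs, small_pheno):
        y = small_pheno["02GF"]["Cu"]
        t1 = iq.permute_threshold(small_probs, y, n_perm=400, seed=5)
        t2 = iq.permute_threshold(small_probs, y, n_perm=800, seed=6)
        assert abs(t1.threshold - t2.threshold) < 0.5

    def test_small_n_perm_warns(self, small_probs, small_pheno):
        with pytest.warns(UserWarning, match="unstable"):
            iq.permute_threshold(small_probs, small_pheno["02GF"]["Cu"],
                                 n_perm=50, seed=0)


class TestPeaks:
    def _curve(self, lod, trait="Cu", n=250):
        table = pd.DataFrame({"lg": 1,
                              "pos_cM": np.arange(len(lod), dtype=float),
                              "lod": np.asarray(lod, dtype=float)})
        return iq.LodCurve(trait=trait, table=table, n_used=n)

    def test_flat_curve_below_threshold_empty(self):
        assert iq.find_peaks(self._curve([1.0] * 30), 3.0) == []

    def test_two_close_maxima_merged(self):
        lod = np.zeros(30)
        lod[10] = 5.0
        lod[14] = 4.5
        peaks = iq.find_peaks(self._curve(lod), 3.0, min_sep_cM=10.0)
        assert len(peaks) == 1
        assert peaks[0].peak_cM == 10.0

    def test_distant_maxima_kept(self):
        lod = np.zeros(40)
        lod[5] = 5.0
        lod[30] = 4.5
        peaks = iq.find_peaks(self._curve(lod), 3.0, min_sep_cM=10.0)
        assert len(peaks) == 2

    def test_support_interval_is_1p5_drop(self):
        lod = np.asarray([0, 1, 3, 4, 5, 4, 3, 1, 0], dtype=float)
        peaks = iq.find_peaks(self._curve(lod), 3.0)
        pk = peaks[0]
        assert (pk.ci_lo_cM, pk.ci_hi_cM) == (3.0, 5.0)

    def test_pve_closed_form(self):
        """LOD = 3 at n = 250 explains 5.38% of variance."""
        assert float(iq.pve_from_lod(3.0, 250)) == pytest.approx(
            5.38, abs=0.01)

    def test_pve_lod_round_trip(self):
        for pve in (1.0, 5.0, 20.0, 50.0):
            back = iq.pve_from_lod(iq.lod_from_pve(pve, 250), 250)
            assert back == pytest.approx(pve, abs=1e-12)

    def test_additive_effect_sign_and_size(self, small_probs, small_pheno,
                                           small_map):
        """TQ allele planted to raise Cu by +0.6 SD; fitted slope agrees."""
        y = small_pheno["02GF"]["Cu"]
        curve = iq.hk_scan(small_probs, y)
        peaks = iq.find_peaks(curve, 3.0, probs=small_probs, trait=y,
                              linkage_map=small_map)
        best = max(peaks, key=lambda p: p.lod)
        assert best.lg == 2
        assert 0.3 < best.additive_effect < 0.9


class TestLsMeans:
    def test_balanced_equals_per_ril_mean(self):
        rng = np.random.default_rng(3)
        rils = [f"R{i}" for i in range(20)]
        tables = {e: pd.DataFrame(rng.standard_normal((20, 2)),
                                  index=rils, columns=["Cu", "Zn"])
                  for e in ("E1", "E2", "E3")}
        lsm = iq.ls_means(tables)
        manual = (sum(tables.values()) / 3).reindex(lsm.index)
        assert np.allclose(lsm.to_numpy(), manual.to_numpy(), atol=1e-10)

    def test_single_environment_is_identity(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame(rng.standard_normal((10, 1)),
                         index=[f"R{i}" for i in range(10)],
                         columns=["Cu"])
        lsm = iq.ls_means({"E1": t})
        assert np.allclose(lsm["Cu"].to_numpy(), t["Cu"].to_numpy(),
                           atol=1e-10)

    def test_unbalanced_matches_statsmodels_oracle(self):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(5)
        rils = [f"R{i}" for i in range(12)]
        t1 = pd.DataFrame({"Cu": rng.standard_normal(12)}, index=rils)
        t2 = pd.DataFrame({"Cu": rng.standard_normal(8)}, index=rils[:8])
        lsm = iq.ls_means({"E1": t1, "E2": t2})
        long = pd.concat([t1.assign(env="E1"), t2.assign(env="E2")]
                         ).rename_axis("ril").reset_index()
        fit = smf.ols("Cu ~ C(ril) + C(env)", data=long).fit()
        grid = pd.DataFrame(
            [(r, e) for r in rils for e in ("E1", "E2")],
            columns=["ril", "env"])
        grid["pred"] = fit.predict(grid)
        oracle = grid.groupby("ril")["pred"].mean().reindex(lsm.index)
        assert np.allclose(lsm["Cu"].to_numpy(), oracle.to_numpy(),
                           atol=1e-8)

    def test_absent_ril_excluded(self):
        t1 = pd.DataFrame({"Cu": [1.0, 2.0]}, index=["a", "b"])
        t2 = pd.DataFrame({"Cu": [3.0]}, index=["a"])
        lsm = iq.ls_means({"E1": t1, "E2": t2})
        assert set(lsm.index) == {"a", "b"}
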