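"""Descriptive statistics and PCA composite-trait construction."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ionoqtl as iq
from ionoqtl.codes import ELEMENTS, ConfigError
from ionoqtl.pctraits import phenotype_stats


def _frame(rng, n=200, k=6, cols=None):
    cols = cols or ELEMENTS[:k]
    return pd.DataFrame(rng.standard_normal((n, len(cols))),
                        index=pd.Index([f"R{i}" for i in range(n)],
                                       name="ril_id"),
                        columns=cols)


class TestStats:
    def test_duplicated_element_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        df = _frame(rng, cols=["Cu", "Zn"])
        df["Zn"] = df["Cu"]
        rep = phenotype_stats(df.reset_index())
        assert rep.corr.loc["Cu", "Zn"] == pytest.approx(1.0)
        assert rep.sig_mask.loc["Cu", "Zn"]

    def test_symmetric_distribution_has_small_skewness(self):
        rng = np.random.default_rng(1)
        rep = phenotype_stats(_frame(rng, n=2000).reset_index())
        assert np.abs(rep.per_element["skewness"]).max() < 0.2

    def test_correlation_matrix_properties(self, small_pheno):
        long = pd.concat([t.assign(env=e)
                          for e, t in small_pheno.items()]).reset_index()
        rep = phenotype_stats(long)
        c = rep.corr.to_numpy()
        assert np.allclose(c, c.T, equal_nan=True)
        assert np.allclose(np.diag(c), 1.0)
        assert np.nanmax(np.abs(c)) <= 1.0 + 1e-12

    def test_anova_uses_replicates(self, small_pheno):
        long = pd.concat([t.assign(env=e)
                          for e, t in small_pheno.items()]).reset_index()
        rep = phenotype_stats(long)
        assert rep.per_element["anova_F"].notna().all()

    def test_constant_column_flagged_nan(self):
        rng = np.random.default_rng(2)
        df = _frame(rng, cols=["Cu", "Zn"])
        df["Zn"] = 1.0
        rep = phenotype_stats(df.reset_index())
        assert np.isnan(rep.corr.loc["Cu", "Zn"])

    def test_planted_ca_sr_structure_recovered(self, small_pheno):
        """The generator's Ca-Sr coupling shows up as a strong positive,
        significant correlation (chemical-analog pattern)."""
        long = pd.concat([t.assign(env=e)
                          for e, t in small_pheno.items()]).reset_index()
        rep = phenotype_stats(long)
        assert rep.corr.loc["Ca", "Sr"] > 0.3
        assert rep.sig_mask.loc["Ca", "Sr"]


class TestPcaWithin:
    def test_var_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        m = iq.pca_within(_frame(rng, k=16))
        assert m.var_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert m.n_pc == 16

    def test_reconstruction(self):
        rng = np.random.default_rng(4)
        df = _frame(rng, k=8)
        m = iq.pca_within(df)
        Z = ((df - m.center) / m.scale).to_numpy()
        back = m.scores.to_numpy() @ m.loadings.to_numpy().T
        assert np.abs(Z - back).max() < 1e-8

    def test_scores_uncorrelated(self):
        rng = np.random.default_rng(5)
        m = iq.pca_within(_frame(rng, k=8))
        cov = np.cov(m.scores.to_numpy().T)
        off = cov[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(cov)).max()

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(6)
        df = _frame(rng, k=8)
        a = iq.pca_within(df)
        b = iq.pca_within(df.copy())
        assert np.array_equal(a.loadings.to_numpy(),
                              b.loadings.to_numpy())
        for pc in a.loadings.columns:
            col = a.loadings[pc]
            assert col.iloc[int(np.argmax(np.abs(col)))] > 0

    def test_perfectly_correlated_pair_shares_loading(self):
        """A 2-block correlation matrix has eigenvector (1,1)/sqrt(2) on
        the block, so the pair's |loadings| are equal on that PC."""
        rng = np.random.default_rng(7)
        df = _frame(rng, n=500, cols=["Ca", "Sr", "Cu", "Zn"])
        df["Sr"] = df["Ca"]
        m = iq.pca_within(df)
        lead = m.loadings["PC1"]
        assert abs(lead["Ca"]) == pytest.approx(abs(lead["Sr"]), abs=1e-9)
        assert abs(lead["Ca"]) == pytest.approx(1 / np.sqrt(2), abs=0.05)

    def test_isotropic_data_equal_fractions(self):
        rng = np.random.default_rng(8)
        m = iq.pca_within(_frame(rng, n=4000, k=16))
        assert np.allclose(m.var_fraction, 1 / 16, atol=0.02)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA
        rng = np.random.default_rng(9)
        df = _frame(rng, n=300, k=10)
        m = iq.pca_within(df)
        Z = ((df - df.mean()) / df.std(ddof=1)).to_numpy()
        sk = PCA(n_components=10).fit(Z)
        assert np.allclose(m.var_fraction, sk.explained_variance_ratio_,
                           atol=1e-9)
        assert np.allclose(np.abs(m.loadings.to_numpy().T),
                           np.abs(sk.components_), atol=1e-8)

    def test_missing_rows_dropped_with_count(self):
        rng = np.random.default_rng(10)
        df = _frame(rng, n=50, k=4)
        df.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="dropped 1"):
            m = iq.pca_within(df)
        assert m.n_dropped == 1
        assert len(m.scores) == 49

    def test_constant_column_rejected(self):
        rng = np.random.default_rng(11)
        df = _frame(rng, k=3)
        df["Cu"] = 2.0
        with pytest.raises(ConfigError):
            iq.pca_within(df)


class TestPcaAcross:
    def test_duplicated_tables_match_within(self):
        rng = np.random.default_rng(12)
        df = _frame(rng, k=6)
        m_within = iq.pca_within(df)
        m_across = iq.pca_across({"E1": df, "E2": df.copy()}, "S")
        assert np.allclose(m_within.loadings.to_numpy(),
                           m_across.loadings.to_numpy(), atol=1e-9)

    def test_environment_shift_dominates_pc1(self):
        """Strong between-environment mean shifts with no within-env
        structure push PC1 variance above any within-env PC1."""
        rng = np.random.default_rng(13)
        base = _frame(rng, n=200, k=6)
        shifted = _frame(rng, n=200, k=6) + 5.0
        m = iq.pca_across({"E1": base, "E2": shifted}, "S")
        w1 = iq.pca_within(base).var_fraction[0]
        w2 = iq.pca_within(shifted).var_fraction[0]
        assert m.var_fraction[0] > max(w1, w2)

    def test_scores_regrouped_per_env_counts(self, small_pheno):
        m = iq.pca_across(small_pheno, "S")
        per_env = iq.scores_by_env(m, "S")
        for env, df in per_env.items():
            assert len(df) == len(small_pheno[env])
            assert list(df.columns)[0] == f"S_{env}_aPC1"

    def test_single_env_delegates_with_warning(self):
        rng = np.random.default_rng(14)
        with pytest.warns(UserWarning, match="size 1"):
            m = iq.pca_across({"E1": _frame(rng, k=4)}, "S")
        assert m.n_pc == 4

    def test_pleiotropic_block_drives_a_leading_pc(self, small_pheno):
        """The planted Cu/As locus plus correlated noise puts Cu and As
        together in the top loadings of one of the first PCs."""
        hits = 0
        for env, table in small_pheno.items():
            m = iq.pca_within(table, scope=env)
            for pc in (1, 2, 3, 4):
                top = [e for e, _ in iq.top_loading_elements(m, pc, 5)]
                if "Cu" in top and "As" in top:
                    hits += 1
                    break
        assert hits >= 1


class TestTopLoadings:
    def test_simple_ordering(self):
        rng = np.random.default_rng(15)
        m = iq.pca_within(_frame(rng, k=4))
        m.loadings["PC1"] = [0.9, -0.8, 0.1, 0.05]
        top = iq.top_loading_elements(m, 1, 2)
        assert [t[0] for t in top] == list(m.loadings.index[:2])
        assert top[0][1] == pytest.approx(0.9)

    def test_k16_is_permutation(self):
        rng = np.random.default_rng(16)
        m = iq.pca_within(_frame(rng, k=16))
        top = iq.top_loading_elements(m, 3, 16)
        assert sorted(t[0] for t in top) == sorted(ELEMENTS)

    def test_k_clipped(self):
        rng = np.random.default_rng(17)
        m = iq.pca_within(_frame(rng, k=4))
        assert len(iq.top_loading_elements(m, 1, 99)) == 4

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=-1, max_value=1,
                              allow_nan=False), min_size=4, max_size=4))
    def test_matches_sort_oracle(self, values):
        rng = np.random.default_rng(18)
        m = iq.pca_within(_frame(rng, k=4))
        m.loadings["PC2"] = values
        got = [t[0] for t in iq.top_loading_elements(m, 2, 4)]
        oracle = [e for _, _, e in
                  sorted(zip([-abs(v) for v in values],
                             range(4), m.loadings.index))]
        assert got == oracle

    def test_bad_pc_index_rejected(self):
        rng = np.random.default_rng(19)
        m = iq.pca_within(_frame(rng, k=4))
        with pytest.raises(ValueError):
            iq.top_loading_elements(m, 5)
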