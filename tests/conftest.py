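"""Shared fixtures: one small simulated panel reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import ionoqtl as iq


@pytest.fixture(scope="session")
def small_cfg() -> iq.SimConfig:
    return iq.SimConfig(
        n_ril=60, n_chrom=2, chrom_len_bp=8_000_000, chrom_len_cM=100.0,
        n_snp_per_chrom=800, mean_depth=2.0, genotyping_error=0.005,
        env_names=["02GF", "07GU"],
        qtl_spec=[iq.PlantedQtl(2, 55.0, {"Cu": 0.6, "As": 0.4})],
        element_corr_noise=iq.study_corr_noise(), seed=42)


@pytest.fixture(scope="session")
def small_truth(small_cfg) -> iq.TruthSet:
    return iq.simulate_ril_genomes(small_cfg)


@pytest.fixture(scope="session")
def small_obs(small_truth):
    return iq.simulate_snp_observations(small_truth)


@pytest.fixture(scope="session")
def small_snps(small_obs):
    snps, _ = iq.filter_snps(small_obs)
    return snps


@pytest.fixture(scope="session")
def small_bins(small_snps) -> iq.BinMatrix:
    return iq.genotype_rils(small_snps, exempt_chroms=())


@pytest.fixture(scope="session")
def small_map(small_bins) -> iq.LinkageMap:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return iq.build_linkage_map(small_bins)


@pytest.fixture(scope="session")
def small_probs(small_bins, small_map) -> iq.GenoProbs:
    return iq.genotype_probs(small_bins, small_map)


@pytest.fixture(scope="session")
def small_pheno(small_truth):
    tables, _report = iq.simulate_phenotypes(small_truth)
    return tables


def random_bin_matrix(rng: np.random.Generator, n_ril: int = 40,
                      n_bins: int = 12, n_chrom: int = 2) -> iq.BinMatrix:
    """A fully observed random bin matrix (no HET, no MISSING)."""
    per = n_bins // n_chrom
    frames, genos = [], []
    for c in range(1, n_chrom + 1):
        edges = np.linspace(0, 1_000_000 * per, per + 1, dtype=np.int64)
        frames.append(pd.DataFrame({
            "chrom": c, "start_bp": edges[:-1], "end_bp": edges[1:],
            "n_merged": 1}))
        g = rng.integers(0, 2, (per, n_ril)).astype(np.int8)
        genos.append(g)
    return iq.BinMatrix(
        bins=pd.concat(frames, ignore_index=True),
        geno=np.vstack(genos),
        ril_ids=[f"RIL{i:03d}" for i in range(n_ril)])
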