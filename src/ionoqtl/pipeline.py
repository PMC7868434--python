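"""End-to-end pipeline: VCF + phenotype tables -> QTLs and clusters.

Chains SNP filtering, bin-map construction, linkage-map building,
descriptive statistics and PCA, univariate scans for all three trait
families (elemental per environment plus LS-mean composites, PC scores per
environment, aPC scores per environment set), and co-localization. Every
artifact is written with a manifest of parameters and checksums; reruns
with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binmap as bg
from . import colocal as cl
from . import io as iom
from . import linkage as lk
from . import pctraits as pt
from . import scan as sc
from .codes import ConfigError

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    vcf: str | Path
    phenotypes: dict[str, str | Path]        # env label -> CSV path
    outdir: str | Path
    env_sets: dict[str, list[str]] = field(default_factory=dict)
    lsmean_sets: dict[str, list[str]] = field(default_factory=dict)
    window_snps: int = 15
    majority_threshold: int = 11
    het_min_each: int = 4
    min_bin_bp: int = 20_000
    exempt_chroms: tuple[int, ...] = (4,)
    map_function: str = "kosambi"
    step_cM: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    min_sep_cM: float = 10.0
    seed: int = 0
    annotation: str | Path | None = None

    def __post_init__(self) -> None:
        if len(set(self.phenotypes)) != len(self.phenotypes):
            raise ConfigError("environment labels must be unique")
        for name, envs in {**self.env_sets, **self.lsmean_sets}.items():
            missing = [e for e in envs if e not in self.phenotypes]
            if missing:
                # runtime degrades gracefully: sets with < 2 available
                # environments are skipped with a logged reason
                warnings.warn(
                    f"set {name!r} references unavailable environments "
                    f"{missing}; it will be skipped if < 2 remain")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = iom.load_config(path)
        return cls(
            vcf=raw["paths"]["vcf"],
            phenotypes=dict(raw["paths"]["phenotypes"]),
            outdir=raw["paths"]["outdir"],
            annotation=raw["paths"].get("annotation"),
            env_sets={k: list(v)
                      for k, v in raw.get("env_sets", {}).items()},
            lsmean_sets={k: list(v)
                         for k, v in raw.get("lsmean_sets", {}).items()},
            **raw.get("params", {}),
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"[stage={stage}] {cause}")
        self.stage = stage
        self.code = f"E_{stage.upper()}"


def _scan_trait(probs, trait, name, cfg, rng, lmap):
    """Threshold + scan + peaks for a single trait vector."""
    seed = int(rng.integers(2 ** 31 - 1))
    curve = sc.hk_scan(probs, trait, name=name)
    perm = sc.permute_threshold(probs, trait, n_perm=cfg.n_perm,
                                alpha=cfg.alpha, seed=seed)
    peaks = sc.find_peaks(curve, perm.threshold,
                          min_sep_cM=cfg.min_sep_cM, probs=probs,
                          trait=trait, linkage_map=lmap)
    return peaks


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a result bundle of DataFrames.

    Writes bins.csv, linkage_map.csv, heterozygosity.csv, per-scope stats
    and PCA tables, qtl.csv, clusters.csv/json, and manifest.json under
    ``config.outdir``. All randomness flows from ``config.seed``.
    """
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    def save(key: str, df: pd.DataFrame, **kw) -> None:
        p = out / f"{key}.csv"
        df.to_csv(p, float_format=_FLOAT_FMT, **kw)
        outputs[key] = p

    # --- genotyping ------------------------------------------------------
    try:
        snps, skipped = iom.read_vcf(cfg.vcf)
        iom.log(f"read {snps.n_sites} SNP records (skipped {skipped})")
        snps, filt_report = bg.filter_snps(snps)
        iom.log(f"filtered SNPs: {filt_report}")
        params = bg.WindowCallParams(
            window_snps=cfg.window_snps,
            majority_threshold=cfg.majority_threshold,
            het_min_each=cfg.het_min_each)
        bins = bg.genotype_rils(snps, params, min_bin_bp=cfg.min_bin_bp,
                                exempt_chroms=tuple(cfg.exempt_chroms))
        bins.to_csv(out / "bins.csv")
        outputs["bins"] = out / "bins.csv"
        het_ril, het_pop = bg.heterozygosity(bins)
        save("heterozygosity", het_ril.to_frame())
        iom.log(f"bin map: {bins.n_bins} bins; "
                f"population heterozygosity {100 * het_pop:.3f}%")
    except Exception as e:  # noqa: BLE001
        raise StageError("binmap", e) from e

    # --- linkage map -----------------------------------------------------
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lmap = lk.build_linkage_map(bins, cfg.map_function)
        lmap.to_csv(out / "linkage_map.csv")
        outputs["linkage_map"] = out / "linkage_map.csv"
        iom.log(f"linkage map: {lmap.n_groups} groups, "
                f"{lmap.total_length_cM:.2f} cM total")
    except Exception as e:  # noqa: BLE001
        raise StageError("linkmap", e) from e

    # --- phenotypes, stats, PCA -----------------------------------------
    try:
        pheno = iom.read_phenotypes(cfg.phenotypes)
        envs = sorted(pheno)
        long = pd.concat(
            [t.assign(env=e) for e, t in pheno.items()]).reset_index()
        stats_report = pt.phenotype_stats(long)
        save("element_stats", stats_report.per_element)
        save("element_corr", stats_report.corr)

        pca_within = {}
        for env in envs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pca_within[env] = pt.pca_within(pheno[env], scope=env)
            save(f"pca_{env}_loadings", pca_within[env].loadings)
        pca_across = {}
        for set_name, set_envs in cfg.env_sets.items():
            avail = [e for e in set_envs if e in pheno]
            if len(avail) < 2:
                iom.log(f"aPC set {set_name!r}: {len(avail)} available "
                        "environment(s) < 2; skipped")
                continue
            m = pt.pca_across({e: pheno[e] for e in avail}, set_name)
            pca_across[set_name] = m
            save(f"pca_{set_name}_loadings", m.loadings)
    except Exception as e:  # noqa: BLE001
        raise StageError("pctraits", e) from e

    # --- scans -----------------------------------------------------------
    try:
        probs = sc.genotype_probs(bins, lmap, step_cM=cfg.step_cM)
        records: list[cl.QtlRecord] = []
        elemental_raw: list[cl.QtlRecord] = []
        rec_n = 0

        def add(peaks, qtl_class, env, element=None, top5=None,
                bucket=None):
            nonlocal rec_n
            for pk in peaks:
                rec_n += 1
                rec = cl.QtlRecord(
                    id=f"q{rec_n:04d}", qtl_class=qtl_class,
                    trait=pk.trait, env=env, lg=pk.lg,
                    ci_lo_cM=pk.ci_lo_cM, ci_hi_cM=pk.ci_hi_cM,
                    lod=pk.lod, pve_pct=pk.pve_pct, peak_cM=pk.peak_cM,
                    phys_lo_kb=pk.phys_lo_kb, phys_hi_kb=pk.phys_hi_kb,
                    element=element, top5_elements=top5)
                (bucket if bucket is not None else records).append(rec)

        elements = list(next(iter(pheno.values())).columns)
        for env in envs:
            for el in elements:
                trait = pheno[env][el].rename(el)
                add(_scan_trait(probs, trait, el, cfg, rng, lmap),
                    "elemental", env, element=el, bucket=elemental_raw)
        for set_name, set_envs in cfg.lsmean_sets.items():
            avail = {e: pheno[e] for e in set_envs if e in pheno}
            if len(avail) < 2:
                iom.log(f"LS-mean set {set_name!r} has < 2 environments; "
                        "skipped")
                continue
            lsm = sc.ls_means(avail)
            for el in elements:
                add(_scan_trait(probs, lsm[el].rename(el), el, cfg, rng,
                                lmap),
                    "elemental", set_name, element=el, bucket=elemental_raw)
        for env in envs:
            model = pca_within[env]
            for k in range(model.n_pc):
                label = f"{env}_PC{k + 1}"
                trait = model.scores[f"PC{k + 1}"].rename(label)
                top5 = [e for e, _ in
                        pt.top_loading_elements(model, k + 1, 5)]
                add(_scan_trait(probs, trait, label, cfg, rng, lmap),
                    "PC", env, top5=top5)
        for set_name, model in pca_across.items():
            per_env = pt.scores_by_env(model, set_name)
            for env, sdf in per_env.items():
                for k in range(model.n_pc):
                    label = f"{set_name}_{env}_aPC{k + 1}"
                    trait = sdf[label].rename(label)
                    top5 = [e for e, _ in
                            pt.top_loading_elements(model, k + 1, 5)]
                    add(_scan_trait(probs, trait, label, cfg, rng, lmap),
                        "aPC", env, top5=top5)

        unique_elemental = cl.merge_unique(elemental_raw)
        records = unique_elemental + [r for r in records
                                      if r.qtl_class != "elemental"]
        save("qtl", cl.records_to_frame(records), index=False)
        save("qtl_all_elemental", cl.records_to_frame(elemental_raw),
             index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("scan", e) from e

    # --- co-localization -------------------------------------------------
    try:
        overlap = cl.overlap_classes(records) if records else None
        clusters = cl.find_clusters(records)
        pairs, agg = cl.concordance_top5(records)
        save("clusters", cl.clusters_to_frame(clusters), index=False)
        cl.clusters_to_json(clusters, out / "clusters.json")
        outputs["clusters_json"] = out / "clusters.json"
        save("concordance_pairs", pairs, index=False)
        if cfg.annotation is not None:
            genes = pd.read_csv(cfg.annotation)
            save("cluster_genes", cl.annotate_clusters(clusters, genes),
                 index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("colocal", e) from e

    params = {
        "window_snps": cfg.window_snps,
        "majority_threshold": cfg.majority_threshold,
        "het_min_each": cfg.het_min_each,
        "min_bin_bp": cfg.min_bin_bp,
        "exempt_chroms": list(cfg.exempt_chroms),
        "map_function": cfg.map_function,
        "step_cM": cfg.step_cM, "n_perm": cfg.n_perm,
        "alpha": cfg.alpha, "min_sep_cM": cfg.min_sep_cM,
        "seed": cfg.seed,
    }
    iom.write_manifest(out / "manifest.json", params, outputs)
    return {
        "bins": bins, "linkage_map": lmap, "records": records,
        "clusters": clusters, "overlap": overlap,
        "concordance": agg, "heterozygosity": het_pop,
        "outdir": out,
    }
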