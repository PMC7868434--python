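#!/usr/bin/env python
"""Descriptive ionome statistics and PCA within / across environments.

Computes per-element distribution statistics (skewness, kurtosis,
Shapiro-Wilk, fold range, across-line ANOVA), the element-pair Pearson
correlation map (masked at p < 0.01), PCA of the 16-element ionome within
each environment/tissue, and across-environment PCA for the F / U / FUGG /
GRS scopes. Writes tables under results/pctraits/.
"""

import argparse
import sys
import time
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd  # noqa: E402
import ionoqtl as iq  # noqa: E402
from ionoqtl.codes import STUDY_ENV_SETS  # noqa: E402
from ionoqtl.io import read_phenotypes  # noqa: E402

ap = argparse.ArgumentParser()
ap.add_argument("--fixture", type=Path, default=Path("results/fixture"))
ap.add_argument("--outdir", type=Path, default=Path("results/pctraits"))
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

t0 = time.time()
paths = {p.stem.removeprefix("pheno_"): p
         for p in sorted(args.fixture.glob("pheno_*.csv"))}
pheno = read_phenotypes(paths)
print(f"{len(pheno)} environment/tissue tables, "
      f"{len(next(iter(pheno.values())))} lines each")

long = pd.concat([t.assign(env=e) for e, t in pheno.items()]).reset_index()
stats = iq.phenotype_stats(long)
stats.per_element.to_csv(args.outdir / "element_stats.csv",
                         float_format="%.6g")
stats.corr.to_csv(args.outdir / "element_corr.csv", float_format="%.4f")
stats.corr.where(stats.sig_mask).to_csv(
    args.outdir / "element_corr_significant.csv", float_format="%.4f")
n_nonnormal = int((stats.per_element["shapiro_p"] < 0.05).sum())
print(f"non-normal elements (Shapiro p < 0.05): {n_nonnormal}/16")
print(f"Ca-Sr correlation: r = {stats.corr.loc['Ca', 'Sr']:.2f} "
      f"(significant: {bool(stats.sig_mask.loc['Ca', 'Sr'])})")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for env, table in pheno.items():
        m = iq.pca_within(table, scope=env)
        m.loadings.to_csv(args.outdir / f"pca_{env}_loadings.csv",
                          float_format="%.6g")
        m.scores.to_csv(args.outdir / f"pca_{env}_scores.csv",
                        float_format="%.6g")
        print(f"  {env}: PC1 {100 * m.var_fraction[0]:.1f}%, "
              f"PC1+PC2 {100 * m.var_fraction[:2].sum():.1f}% of variance")
    for set_name, envs in STUDY_ENV_SETS.items():
        avail = {e: pheno[e] for e in envs if e in pheno}
        if len(avail) < 2:
            continue
        m = iq.pca_across(avail, set_name)
        m.loadings.to_csv(args.outdir / f"pca_{set_name}_loadings.csv",
                          float_format="%.6g")
        m.scores.to_csv(args.outdir / f"pca_{set_name}_scores.csv",
                        float_format="%.6g")
        print(f"  across {set_name} ({len(avail)} envs): PC1 "
              f"{100 * m.var_fraction[0]:.1f}% of variance")
print(f"wrote PCA/statistics tables to {args.outdir} "
      f"in {time.time() - t0:.1f}s")
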