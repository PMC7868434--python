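"""File readers/writers: VCF 4.2, phenotype CSVs, manifests, config.

Genotype observations travel as plain VCF 4.2 with GT and DP per sample;
the first two samples are the parents (LM then TQ), followed by the RILs.
Missing calls are "./.". Reading uses cyvcf2; multi-allelic and indel
records are skipped with logged counts.
"""

from __future__ import annotations

import hashlib
import json
import sys
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .binmap import SnpTable
from .codes import HET, LM, MISSING, TQ

P1_NAME = "LM"
P2_NAME = "TQ"


def write_vcf(snps: SnpTable, path: str | Path,
              contig_lengths: dict[int, int] | None = None) -> None:
    """Write a SnpTable as VCF 4.2 (samples: LM, TQ, then RILs)."""
    s = snps.sites
    lines = ["##fileformat=VCFv4.2",
             "##source=ionoqtl",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">']
    chroms = sorted(s["chrom"].unique())
    for c in chroms:
        ln = (contig_lengths or {}).get(
            int(c), int(s.loc[s["chrom"] == c, "pos"].max()))
        lines.append(f"##contig=<ID={c},length={ln}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
              "INFO", "FORMAT", P1_NAME, P2_NAME, *snps.ril_ids]
    lines.append("\t".join(header))

    gt_str = {LM: "0/0", TQ: "1/1", HET: "0/1", MISSING: "./."}
    calls = snps.calls
    depth = snps.depth
    for i in range(snps.n_sites):
        row = s.iloc[i]
        fields = [str(int(row["chrom"])), str(int(row["pos"])), ".",
                  str(row["p1_allele"]), str(row["p2_allele"]), ".",
                  "PASS", ".", "GT:DP",
                  f"0/0:{int(row['p1_depth'])}",
                  f"1/1:{int(row['p2_depth'])}"]
        fields.extend(
            f"{gt_str[int(calls[i, j])]}:{int(depth[i, j])}"
            for j in range(len(snps.ril_ids)))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> tuple[SnpTable, dict[str, int]]:
    """Read biallelic SNP records into a SnpTable.

    The LM parent's allele maps RIL hom calls onto parental origins;
    multi-allelic records, indels, and records where a parent call is
    missing are skipped (counts reported). Heterozygous RIL calls map to
    HET; "./." to MISSING.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if P1_NAME not in samples or P2_NAME not in samples:
        raise ValueError(
            f"VCF must contain parent samples {P1_NAME!r} and {P2_NAME!r}")
    i1, i2 = samples.index(P1_NAME), samples.index(P2_NAME)
    ril_idx = [i for i in range(len(samples)) if i not in (i1, i2)]
    ril_ids = [samples[i] for i in ril_idx]

    skipped = {"multiallelic": 0, "indel": 0, "parent_missing": 0}
    site_rows = []
    calls_rows = []
    depth_rows = []
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if v.is_indel or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped["indel"] += 1
            continue
        gts = v.gt_types  # 0=hom ref, 1=het, 2=unknown/missing, 3=hom alt
        try:
            dp = np.asarray(v.format("DP")).reshape(-1)
        except (TypeError, ValueError):
            dp = np.zeros(len(samples), dtype=np.int32)
        dp = np.where(dp < 0, 0, dp)
        g1, g2 = int(gts[i1]), int(gts[i2])
        if g1 == 2 or g2 == 2:
            skipped["parent_missing"] += 1
            continue
        # parental origin: whichever allele the LM parent carries is LM
        if g1 == 0:
            code_of = {0: LM, 3: TQ}
        elif g1 == 3:
            code_of = {0: TQ, 3: LM}
        else:
            code_of = {}
        row_calls = np.full(len(ril_idx), MISSING, dtype=np.int8)
        for k, j in enumerate(ril_idx):
            g = int(gts[j])
            if g == 1:
                row_calls[k] = HET
            elif g in code_of:
                row_calls[k] = code_of[g]
        site_rows.append({
            "chrom": int(v.CHROM), "pos": int(v.POS),
            "p1_allele": v.REF if g1 == 0 else v.ALT[0],
            "p2_allele": v.ALT[0] if g1 == 0 else v.REF,
            "p1_depth": int(dp[i1]), "p2_depth": int(dp[i2]),
            "p1_hom": g1 in (0, 3), "p2_hom": g2 in (0, 3),
        })
        calls_rows.append(row_calls)
        depth_rows.append(dp[ril_idx].astype(np.int16))
    if not site_rows:
        raise ValueError(f"no usable SNP records in {path}")
    table = SnpTable(
        sites=pd.DataFrame(site_rows),
        calls=np.vstack(calls_rows),
        depth=np.vstack(depth_rows),
        ril_ids=ril_ids)
    return table, skipped


def read_phenotypes(paths: dict[str, str | Path]) -> dict[str, pd.DataFrame]:
    """Read per-environment phenotype CSVs (``ril_id`` index column)."""
    out = {}
    for env, p in paths.items():
        df = pd.read_csv(p).set_index("ril_id")
        out[env] = df
    return out


def load_config(path: str | Path) -> dict:
    """Load a pipeline configuration from a TOML file."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, params: dict,
                   outputs: dict[str, Path]) -> None:
    obj = {
        "parameters": params,
        "outputs": {k: {"path": str(Path(p).name),
                        "sha256": sha256_file(p)}
                    for k, p in sorted(outputs.items())},
    }
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def log(msg: str) -> None:
    print(f"[ionoqtl] {msg}", file=sys.stderr)
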