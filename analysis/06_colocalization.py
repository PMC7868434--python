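#!/usr/bin/env python
"""Co-localization of elemental, PC-, and aPC-QTLs; cluster report.

Reads the unified QTL table from the scan step, recomputes the class
overlap (Venn-style counts), detects three-class QTL clusters, and tests
top-5-loading concordance: whether each co-localized elemental QTL's
element appears among the five highest-|loading| elements of the
overlapping PC/aPC trait. Writes results/colocal/.
"""

import argparse
import json
import sys
import time
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd  # noqa: E402
import ionoqtl as iq  # noqa: E402
from ionoqtl.colocal import (clusters_to_frame, clusters_to_json,  # noqa: E402
                             frame_to_records)

ap = argparse.ArgumentParser()
ap.add_argument("--qtl", type=Path, default=Path("results/scans/qtl.csv"))
ap.add_argument("--outdir", type=Path, default=Path("results/colocal"))
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

t0 = time.time()
records = frame_to_records(pd.read_csv(args.qtl))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    overlap = iq.overlap_classes(records)
    clusters = iq.find_clusters(records)
    pairs, agg = iq.concordance_top5(records)

(args.outdir / "venn_counts.json").write_text(
    json.dumps(overlap.venn, indent=1, sort_keys=True))
clusters_to_frame(clusters).to_csv(args.outdir / "clusters.csv",
                                   index=False, float_format="%.6g")
clusters_to_json(clusters, args.outdir / "clusters.json")
pairs.to_csv(args.outdir / "concordance_pairs.csv", index=False)

n_el = overlap.venn["elemental_total"]
print(f"records: {n_el} elemental, {overlap.venn['PC_total']} PC, "
      f"{overlap.venn['aPC_total']} aPC")
print(f"elemental co-localizing with PC: {overlap.venn['elemental&PC']}; "
      f"with aPC: {overlap.venn['elemental&aPC']}; with both: "
      f"{overlap.venn['elemental&PC&aPC']}")
print(f"three-class QTL clusters: {len(clusters)}")
for c in clusters:
    els = sorted({r.element for r in c.members['elemental'] if r.element})
    print(f"  cluster {c.cluster_id}: LG{c.lg} "
          f"{c.ci_lo_cM:.1f}-{c.ci_hi_cM:.1f} cM, elements {els}, "
          f"top-5 concordant: {c.concordant}")
for cls in ("PC", "aPC"):
    frac = agg.get(cls)
    if frac == frac:  # not NaN
        print(f"top-5 concordance ({cls}): {100 * frac:.0f}% of records")
print(f"wrote co-localization report to {args.outdir} "
      f"in {time.time() - t0:.1f}s")
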