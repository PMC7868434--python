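#!/usr/bin/env python
"""Build the genetic map from the bin matrix.

Adjacent-bin recombinant fractions are corrected for selfing-RIL map
expansion (r = R / (2(1-R))) and converted to cM with the Kosambi map
function; linkage groups follow physical chromosome order. Writes
results/linkmap/linkage_map.csv and prints per-group lengths.
"""

import argparse
import sys
import time
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import ionoqtl as iq  # noqa: E402

ap = argparse.ArgumentParser()
ap.add_argument("--bins", type=Path, default=Path("results/binmap/bins.csv"))
ap.add_argument("--map-function", default="kosambi",
                choices=("kosambi", "haldane"))
ap.add_argument("--outdir", type=Path, default=Path("results/linkmap"))
args = ap.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

t0 = time.time()
bins = iq.BinMatrix.from_csv(args.bins)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    lmap = iq.build_linkage_map(bins, args.map_function)
lmap.to_csv(args.outdir / "linkage_map.csv")

for lg, sub in lmap.table.groupby("lg"):
    span = sub["cm"].iloc[-1] - sub["cm"].iloc[0]
    print(f"  LG{lg:>2}: {len(sub):>4} bins, {span:8.2f} cM")
print(f"total genetic distance: {lmap.total_length_cM:.2f} cM "
      f"({args.map_function}); mean inter-bin distance "
      f"{lmap.mean_interval_cM():.3f} cM")
print(f"wrote {args.outdir}/linkage_map.csv in {time.time() - t0:.1f}s")
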