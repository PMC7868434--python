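"""Genetic-map construction from the bin matrix.

Adjacent-bin recombinant fractions observed on a selfing RIL panel (R) are
corrected to per-meiosis fractions (r) via the selfing-RIL identity
R = 2r / (1 + 2r), converted to map distances with the Haldane or Kosambi
map function, and accumulated into per-chromosome linkage groups in
physical marker order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binmap import BinMatrix
from .codes import LM, TQ

_EPS = 1e-9
MAP_FUNCTIONS = ("haldane", "kosambi")


def estimate_rf(bin_matrix: BinMatrix, i: int, j: int
                ) -> tuple[float, int]:
    """Observed recombinant fraction between bins i and j.

    Counts RILs with parental (LM/TQ) calls at both bins; HET or MISSING
    makes a RIL uninformative. Returns (R_obs clamped to [0, 0.5-eps],
    n_informative); with zero informative RILs R_obs is NaN.
    """
    a = bin_matrix.geno[i]
    b = bin_matrix.geno[j]
    inf = np.isin(a, (LM, TQ)) & np.isin(b, (LM, TQ))
    n = int(inf.sum())
    if n == 0:
        return float("nan"), 0
    disc = int((a[inf] != b[inf]).sum())
    return float(np.clip(disc / n, 0.0, 0.5 - _EPS)), n


def ril_correct(R_obs: float | np.ndarray) -> float | np.ndarray:
    """Selfing-RIL correction: observed R -> per-meiosis r.

    Inverts R = 2r/(1+2r): r = R / (2 (1 - R)); clamped to [0, 0.5).
    """
    R = np.clip(np.asarray(R_obs, dtype=float), 0.0, None)
    if np.any(R >= 0.5):
        warnings.warn("R_obs >= 0.5 clamped before RIL correction")
        R = np.clip(R, 0.0, 0.5 - _EPS)
    r = R / (2.0 * (1.0 - R))
    out = np.clip(r, 0.0, 0.5 - _EPS)
    return float(out) if np.isscalar(R_obs) else out


def ril_observed(r: float | np.ndarray) -> float | np.ndarray:
    """Forward map r -> R = 2r/(1+2r) (inverse of :func:`ril_correct`)."""
    r = np.asarray(r, dtype=float)
    out = 2.0 * r / (1.0 + 2.0 * r)
    return float(out) if out.ndim == 0 else out


def map_distance(r: float | np.ndarray, function: str = "kosambi"
                 ) -> float | np.ndarray:
    """Per-meiosis recombination fraction -> map distance in cM."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr >= 0.5):
        raise ValueError("r >= 0.5 corresponds to infinite map distance")
    if function == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * r_arr)
    elif function == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * r_arr) / (1.0 - 2.0 * r_arr))
    else:
        raise ValueError(f"unknown map function {function!r}")
    return float(d) if np.isscalar(r) else d


def inverse_map_distance(d: float | np.ndarray, function: str = "kosambi"
                         ) -> float | np.ndarray:
    """Map distance in cM -> per-meiosis recombination fraction."""
    d_arr = np.asarray(d, dtype=float)
    if function == "haldane":
        r = 0.5 * (1.0 - np.exp(-d_arr / 50.0))
    elif function == "kosambi":
        r = 0.5 * np.tanh(d_arr / 50.0)
    else:
        raise ValueError(f"unknown map function {function!r}")
    return float(r) if np.isscalar(d) else r


@dataclass
class LinkageMap:
    """Ordered bins with cumulative cM positions per linkage group.

    ``table`` columns: lg, bin_id (row index into the BinMatrix), chrom,
    start_bp, end_bp, cm, r_obs, r_meiotic, n_informative (the last three
    describe the interval to the previous bin; NaN for group starts).
    """

    table: pd.DataFrame
    map_function: str

    @property
    def total_length_cM(self) -> float:
        return float(sum(sub["cm"].iloc[-1] - sub["cm"].iloc[0]
                         for _, sub in self.table.groupby("lg")))

    @property
    def n_groups(self) -> int:
        return int(self.table["lg"].nunique())

    def group(self, lg: int) -> pd.DataFrame:
        return self.table[self.table["lg"] == lg]

    def mean_interval_cM(self) -> float:
        gaps = [np.diff(sub["cm"].to_numpy())
                for _, sub in self.table.groupby("lg")]
        gaps = np.concatenate(gaps) if gaps else np.empty(0)
        return float(gaps.mean()) if len(gaps) else 0.0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, map_function: str = "kosambi") -> "LinkageMap":
        return cls(pd.read_csv(path), map_function)


def build_linkage_map(bin_matrix: BinMatrix, function: str = "kosambi"
                      ) -> LinkageMap:
    """Cumulative cM positions from adjacent corrected distances.

    Bins are in physical order; linkage group = chromosome. When an
    adjacent pair has no informative RIL, the later bin is co-located with
    its predecessor and distance accrues against the last bin that had an
    estimate. Chromosomes with a single bin form flagged single-point
    groups.
    """
    if function not in MAP_FUNCTIONS:
        raise ValueError(f"unknown map function {function!r}")
    rows = []
    bins = bin_matrix.bins
    for chrom, sub in bins.groupby("chrom"):
        idx = sub.index.to_numpy()
        if len(idx) < 2:
            warnings.warn(f"chromosome {chrom} has {len(idx)} bin(s); "
                          "single-point linkage group")
        cm = 0.0
        anchor = idx[0]  # last bin with an informative estimate
        for k, b in enumerate(idx):
            if k == 0:
                rows.append((chrom, b, chrom,
                             bins.at[b, "start_bp"], bins.at[b, "end_bp"],
                             0.0, np.nan, np.nan, 0))
                continue
            R, n = estimate_rf(bin_matrix, anchor, b)
            if n == 0:
                rows.append((chrom, b, chrom,
                             bins.at[b, "start_bp"], bins.at[b, "end_bp"],
                             cm, np.nan, np.nan, 0))
                continue
            r = ril_correct(R)
            cm += map_distance(r, function)
            anchor = b
            rows.append((chrom, b, chrom,
                         bins.at[b, "start_bp"], bins.at[b, "end_bp"],
                         cm, R, r, n))
    table = pd.DataFrame(rows, columns=[
        "lg", "bin_id", "chrom", "start_bp", "end_bp",
        "cm", "r_obs", "r_meiotic", "n_informative"])
    return LinkageMap(table=table, map_function=function)
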