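"""SNP filtering, sliding-window genotype calling, and recombination bins.

Low-coverage sequencing of a RIL panel observes only a sparse, noisy subset
of parent-divergent SNP sites per line. This module turns those calls into
a population-level recombination *bin map*: per line, genotypes are called
in sliding windows of W observed SNPs (majority rule), maximal runs of
identical window calls become genotype blocks separated by breakpoints, and
the union of all lines' breakpoints partitions each chromosome into bins —
intervals within which no line recombines — that serve as genetic markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import CHAR_TO_CODE, CODE_TO_CHAR, HET, LM, MISSING, TQ


# ---------------------------------------------------------------------------
# data containers


@dataclass
class SnpTable:
    """Per-site parental alleles plus per-RIL calls and depths.

    ``sites`` columns: chrom, pos (1-based bp), p1_allele, p2_allele,
    p1_depth, p2_depth, p1_hom, p2_hom. ``calls`` is (n_sites, n_ril) int8
    in {LM, TQ, HET, MISSING}; ``depth`` the matching read depths.
    """

    sites: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray
    ril_ids: list[str]

    def __post_init__(self) -> None:
        s = self.sites
        key = s[["chrom", "pos"]].to_numpy()
        if len(key) > 1:
            order = np.lexsort((key[:, 1], key[:, 0]))
            if not np.array_equal(order, np.arange(len(key))):
                raise ValueError("SNP sites must be sorted by (chrom, pos)")
            same = (np.diff(key[:, 0]) == 0) & (np.diff(key[:, 1]) == 0)
            if same.any():
                raise ValueError("duplicate SNP positions within a chromosome")
        if self.calls.shape != (len(s), len(self.ril_ids)):
            raise ValueError("calls shape does not match sites x RILs")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list[int]:
        return sorted(self.sites["chrom"].unique().tolist())

    def chrom_mask(self, chrom: int) -> np.ndarray:
        return (self.sites["chrom"] == chrom).to_numpy()

    def chrom_span(self, chrom: int) -> tuple[int, int]:
        pos = self.sites.loc[self.sites["chrom"] == chrom, "pos"]
        return int(pos.iloc[0]), int(pos.iloc[-1])


@dataclass
class WindowCallParams:
    """Sliding-window genotype-calling rule.

    A window of ``window_snps`` consecutive *observed* SNPs is labelled TQ
    (resp. LM) when that parent's call count exceeds ``majority_threshold``;
    otherwise HET when both counts reach ``het_min_each``; otherwise
    MISSING. ``min_het_run`` controls how short a HET run between opposite
    parental blocks may be before it is read as a crossover transition zone
    rather than a real heterozygous segment.
    """

    window_snps: int = 15
    step_snps: int = 1
    majority_threshold: int = 11
    het_min_each: int = 4
    min_het_run: int | None = None  # default: window_snps

    def __post_init__(self) -> None:
        if not 0 < self.majority_threshold < self.window_snps:
            raise ValueError("need 0 < majority_threshold < window_snps")
        if self.step_snps < 1:
            raise ValueError("step_snps must be >= 1")
        if self.min_het_run is None:
            self.min_het_run = self.window_snps


@dataclass
class BinMatrix:
    """Population-level recombination bins with per-RIL genotypes.

    ``bins``: chrom, start_bp, end_bp (half-open [start, end)), n_merged.
    ``geno``: (n_bins, n_ril) int8 codes.
    """

    bins: pd.DataFrame
    geno: np.ndarray
    ril_ids: list[str]

    def __post_init__(self) -> None:
        b = self.bins
        if (b["end_bp"] <= b["start_bp"]).any():
            raise ValueError("bins must have end_bp > start_bp")
        for c, sub in b.groupby("chrom"):
            if not (sub["start_bp"].iloc[1:].to_numpy()
                    == sub["end_bp"].iloc[:-1].to_numpy()).all():
                raise ValueError(f"bins do not tile chromosome {c}")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def lengths_bp(self) -> np.ndarray:
        return (self.bins["end_bp"] - self.bins["start_bp"]).to_numpy()

    def to_csv(self, path) -> None:
        chars = np.vectorize(CODE_TO_CHAR.get)(self.geno)
        df = self.bins[["chrom", "start_bp", "end_bp"]].copy()
        for j, r in enumerate(self.ril_ids):
            df[r] = chars[:, j]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BinMatrix":
        df = pd.read_csv(path)
        ril_ids = [c for c in df.columns
                   if c not in ("chrom", "start_bp", "end_bp")]
        chars = df[ril_ids].to_numpy()
        geno = np.vectorize(CHAR_TO_CODE.get)(chars).astype(np.int8)
        bins = df[["chrom", "start_bp", "end_bp"]].copy()
        bins["n_merged"] = 1
        return cls(bins=bins, geno=geno, ril_ids=ril_ids)


# ---------------------------------------------------------------------------
# SNP filtering


def filter_snps(raw: SnpTable, parent_min_depth: int = 10,
                ril_min_depth: int = 4, adjacency_bp: int = 5,
                indel_positions: pd.DataFrame | None = None
                ) -> tuple[SnpTable, dict[str, int]]:
    """Apply the pre-binning SNP filters.

    Retains sites where (i) both parents are homozygous for different
    alleles, (ii) both parental depths reach ``parent_min_depth``, (iii) no
    other SNP (of the raw input) or indel lies within ``adjacency_bp``, and
    (iv) summed RIL depth reaches ``ril_min_depth`` (the per-RIL depth rule
    applied at the discovery level, since per-line thresholds are
    unattainable at ~2x coverage). Returns the filtered table and per-rule
    removal counts.
    """
    s = raw.sites
    keep = np.ones(raw.n_sites, dtype=bool)
    report: dict[str, int] = {}

    bad_parent = ~(s["p1_hom"] & s["p2_hom"]
                   & (s["p1_allele"] != s["p2_allele"])).to_numpy()
    report["parent_not_informative"] = int((keep & bad_parent).sum())
    keep &= ~bad_parent

    shallow = ((s["p1_depth"] < parent_min_depth)
               | (s["p2_depth"] < parent_min_depth)).to_numpy()
    report["parent_low_depth"] = int((keep & shallow).sum())
    keep &= ~shallow

    chrom = s["chrom"].to_numpy()
    pos = s["pos"].to_numpy()
    near = np.zeros(raw.n_sites, dtype=bool)
    same_chrom = np.diff(chrom) == 0
    close = (np.diff(pos) <= adjacency_bp) & same_chrom
    near[:-1] |= close
    near[1:] |= close
    if indel_positions is not None and len(indel_positions):
        for c, sub in indel_positions.groupby("chrom"):
            m = chrom == c
            ip = np.sort(sub["pos"].to_numpy())
            d_left = pos[m] - ip[np.clip(
                np.searchsorted(ip, pos[m]) - 1, 0, len(ip) - 1)]
            d_right = ip[np.clip(
                np.searchsorted(ip, pos[m]), 0, len(ip) - 1)] - pos[m]
            near[m] |= (np.abs(d_left) <= adjacency_bp) \
                | (np.abs(d_right) <= adjacency_bp)
    report["adjacent"] = int((keep & near).sum())
    keep &= ~near

    low_ril = raw.depth.sum(axis=1) < ril_min_depth
    report["ril_low_depth"] = int((keep & low_ril).sum())
    keep &= ~low_ril

    report["retained"] = int(keep.sum())
    out = SnpTable(sites=s[keep].reset_index(drop=True),
                   calls=raw.calls[keep], depth=raw.depth[keep],
                   ril_ids=raw.ril_ids)
    return out, report


# ---------------------------------------------------------------------------
# window calling


def call_windows(snps: SnpTable, ril: int,
                 params: WindowCallParams | None = None
                 ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Sliding-window genotype calls for one RIL.

    Windows slide over the RIL's *observed* (non-missing) calls per
    chromosome with the configured width and step. Returns, per chromosome,
    ``(labels, anchors_bp)`` where each window is anchored at its median
    observed-SNP position. Chromosomes with fewer observed calls than one
    window yield no windows (with a warning).
    """
    p = params or WindowCallParams()
    W, T = p.window_snps, p.majority_threshold
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in snps.chroms:
        m = snps.chrom_mask(chrom)
        calls = snps.calls[m, ril]
        pos = snps.sites.loc[m, "pos"].to_numpy()
        obs = calls != MISSING
        oc = calls[obs]
        opos = pos[obs]
        n = len(oc)
        if n < W:
            warnings.warn(
                f"chromosome {chrom}: only {n} observed calls for RIL "
                f"{ril} (< window of {W}); no windows emitted")
            out[chrom] = (np.empty(0, dtype=np.int8),
                          np.empty(0, dtype=np.int64))
            continue
        ctq = np.cumsum(np.concatenate(([0], (oc == TQ).astype(np.int32))))
        clm = np.cumsum(np.concatenate(([0], (oc == LM).astype(np.int32))))
        starts = np.arange(0, n - W + 1, p.step_snps)
        n_tq = ctq[starts + W] - ctq[starts]
        n_lm = clm[starts + W] - clm[starts]
        labels = np.full(len(starts), MISSING, dtype=np.int8)
        labels[(n_tq >= p.het_min_each) & (n_lm >= p.het_min_each)] = HET
        labels[n_lm > T] = LM
        labels[n_tq > T] = TQ
        anchors = opos[starts + (W - 1) // 2]
        out[chrom] = (labels, anchors.astype(np.int64))
    return out


# ---------------------------------------------------------------------------
# block formation


@dataclass
class _Run:
    label: int
    first_anchor: int
    last_anchor: int


def _rle(labels: np.ndarray, anchors: np.ndarray) -> list[_Run]:
    runs: list[_Run] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append(_Run(int(labels[start]),
                             int(anchors[start]), int(anchors[i - 1])))
            start = i
    return runs


def _simplify_runs(runs: list[_Run], min_het_windows: int,
                   window_index: dict[int, int]) -> list[_Run]:
    """Resolve MISSING and transition-zone HET runs to a stable block list.

    MISSING runs are absorbed when both flanks agree (else kept). A HET run
    between *opposite* parental flanks shorter than ``min_het_windows`` is
    the window-rule's deterministic footprint of a single crossover and is
    dropped (the breakpoint then falls at the midpoint of the zone); HET
    runs between agreeing flanks, at chromosome ends, or long enough to be
    genuine segments are kept as blocks.
    """
    def run_len(r: _Run) -> int:
        return window_index[r.last_anchor] - window_index[r.first_anchor] + 1

    changed = True
    while changed:
        changed = False
        # merge equal-label neighbours
        merged: list[_Run] = []
        for r in runs:
            if merged and merged[-1].label == r.label:
                merged[-1].last_anchor = r.last_anchor
                changed = True
            else:
                merged.append(_Run(r.label, r.first_anchor, r.last_anchor))
        runs = merged
        # absorb interior MISSING runs with agreeing flanks
        for i in range(1, len(runs) - 1):
            if (runs[i].label == MISSING
                    and runs[i - 1].label == runs[i + 1].label
                    and runs[i - 1].label != MISSING):
                runs.pop(i)
                changed = True
                break
        if changed:
            continue
        # drop transition-zone HET runs between opposite parental flanks
        for i in range(1, len(runs) - 1):
            left, mid, right = runs[i - 1], runs[i], runs[i + 1]
            if (mid.label == HET
                    and {left.label, right.label} == {LM, TQ}
                    and run_len(mid) < min_het_windows):
                runs.pop(i)
                changed = True
                break
    return runs


def call_blocks(window_calls: dict[int, tuple[np.ndarray, np.ndarray]],
                params: WindowCallParams | None = None
                ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Collapse window calls into genotype blocks with breakpoints.

    Returns, per chromosome, ``(boundaries_bp, block_labels)`` with
    ``len(labels) == len(boundaries) + 1``; a boundary between two adjacent
    discordant blocks lies at the midpoint between the last window anchor
    of the left block and the first anchor of the right block. A chromosome
    with no windows yields ``([], [MISSING])``.
    """
    p = params or WindowCallParams()
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (labels, anchors) in window_calls.items():
        if len(labels) == 0:
            out[chrom] = (np.empty(0, dtype=np.int64),
                          np.asarray([MISSING], dtype=np.int8))
            continue
        widx = {int(a): i for i, a in enumerate(anchors)}
        runs = _rle(labels, anchors)
        runs = _simplify_runs(runs, p.min_het_run, widx)
        bounds = np.asarray(
            [(runs[i].last_anchor + runs[i + 1].first_anchor) // 2
             for i in range(len(runs) - 1)], dtype=np.int64)
        labs = np.asarray([r.label for r in runs], dtype=np.int8)
        out[chrom] = (bounds, labs)
    return out


# ---------------------------------------------------------------------------
# bin map


def _conflicts(col_a: np.ndarray, col_b: np.ndarray) -> int:
    ok = (col_a != MISSING) & (col_b != MISSING)
    return int((col_a[ok] != col_b[ok]).sum())


def build_bin_map(blocks_by_ril: list[dict[int, tuple[np.ndarray, np.ndarray]]],
                  chrom_spans: dict[int, tuple[int, int]],
                  ril_ids: list[str],
                  min_bin_bp: int = 20_000,
                  exempt_chroms: tuple[int, ...] = (4,)) -> BinMatrix:
    """Assemble the population recombination bin map.

    Bin boundaries are the union over RILs of block breakpoints; each bin's
    genotype per RIL is the label of that RIL's block covering it. Bins
    shorter than ``min_bin_bp`` (except on ``exempt_chroms``) are merged
    into the adjacent bin introducing fewer population-level genotype
    conflicts (ties merge left), preserving the partition.
    """
    if not blocks_by_ril:
        raise ValueError("no blocks supplied")
    n_ril = len(ril_ids)
    all_bins = []
    all_geno = []
    for chrom in sorted(chrom_spans):
        span_lo, span_hi = chrom_spans[chrom]
        cuts: list[int] = []
        for blocks in blocks_by_ril:
            b, _ = blocks.get(chrom, (np.empty(0, dtype=np.int64), None))
            cuts.extend(int(x) for x in b if span_lo < x < span_hi)
        edges = np.asarray(sorted({span_lo, span_hi, *cuts}), dtype=np.int64)
        starts, ends = edges[:-1], edges[1:]
        mids = (starts + ends) / 2.0
        geno = np.full((len(starts), n_ril), MISSING, dtype=np.int8)
        for r, blocks in enumerate(blocks_by_ril):
            if chrom not in blocks:
                continue
            bounds, labels = blocks[chrom]
            geno[:, r] = labels[np.searchsorted(bounds, mids)]
        # merge sub-threshold bins
        bins = [[int(s), int(e), 1] for s, e in zip(starts, ends)]
        cols = [geno[i].copy() for i in range(len(bins))]
        if chrom not in exempt_chroms:
            while True:
                lengths = [b[1] - b[0] for b in bins]
                if len(bins) <= 1:
                    break
                i = int(np.argmin(lengths))
                if lengths[i] >= min_bin_bp:
                    break
                left = i - 1 if i > 0 else None
                right = i + 1 if i < len(bins) - 1 else None
                if left is not None and right is not None:
                    cl = _conflicts(cols[i], cols[left])
                    cr = _conflicts(cols[i], cols[right])
                    tgt = left if cl <= cr else right
                elif left is not None:
                    tgt = left
                else:
                    tgt = right
                # absorbed bin adopts the neighbour's genotypes
                if tgt < i:
                    bins[tgt][1] = bins[i][1]
                else:
                    bins[tgt][0] = bins[i][0]
                bins[tgt][2] += bins[i][2]
                bins.pop(i)
                cols.pop(i)
        df = pd.DataFrame(bins, columns=["start_bp", "end_bp", "n_merged"])
        df.insert(0, "chrom", chrom)
        all_bins.append(df)
        all_geno.append(np.vstack(cols) if cols else
                        np.empty((0, n_ril), dtype=np.int8))
    bins = pd.concat(all_bins, ignore_index=True)
    geno = np.vstack(all_geno)
    return BinMatrix(bins=bins, geno=geno, ril_ids=ril_ids)


def genotype_rils(snps: SnpTable, params: WindowCallParams | None = None,
                  min_bin_bp: int = 20_000,
                  exempt_chroms: tuple[int, ...] = (4,)) -> BinMatrix:
    """Convenience: window-call every RIL and build the bin map."""
    p = params or WindowCallParams()
    blocks = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(len(snps.ril_ids)):
            blocks.append(call_blocks(call_windows(snps, r, p), p))
    spans = {c: snps.chrom_span(c) for c in snps.chroms}
    return build_bin_map(blocks, spans, snps.ril_ids,
                         min_bin_bp=min_bin_bp, exempt_chroms=exempt_chroms)


# ---------------------------------------------------------------------------
# heterozygosity


def heterozygosity(bin_matrix: BinMatrix) -> tuple[pd.Series, float]:
    """Per-RIL and population heterozygous genome fraction (bp-weighted).

    fraction = sum(length of HET bins) / sum(length of non-MISSING bins).
    RILs with no called bins get NaN (flagged by a warning).
    """
    lengths = bin_matrix.lengths_bp.astype(float)
    geno = bin_matrix.geno
    het_len = lengths @ (geno == HET)
    called_len = lengths @ (geno != MISSING)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(called_len > 0, het_len / called_len, np.nan)
    if np.isnan(frac).any():
        warnings.warn(f"{int(np.isnan(frac).sum())} RIL(s) have no called "
                      "bins; heterozygosity undefined for them")
    per_ril = pd.Series(frac, index=bin_matrix.ril_ids, name="het_fraction")
    return per_ril, float(np.nanmean(frac))
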