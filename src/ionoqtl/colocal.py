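"""QTL co-localization, unique-QTL merging, and three-class clusters.

QTLs detected from element concentrations (elemental), within-environment
PC scores (PC), and across-environment PC scores (aPC) are unified into one
record type. Two records co-localize when their support intervals (closed,
in cM, on the same linkage group) intersect. Repeated detections of the
same element merge transitively into unique QTLs; connected components of
the co-localization graph containing all three classes are QTL clusters,
and the top-5-loading concordance test asks whether a co-localized
elemental QTL's element appears among the five highest-|loading| elements
of the PC/aPC trait that detected the overlapping record.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CLASSES = ("elemental", "PC", "aPC")


def _nanreduce(fn, values) -> float:
    vals = [v for v in values if not np.isnan(v)]
    return float(fn(vals)) if vals else float("nan")

_PC_RE = re.compile(r"^(?P<env>.+)_PC(?P<k>\d+)$")
_APC_RE = re.compile(r"^(?P<set>[^_]+)_(?P<env>.+)_aPC(?P<k>\d+)$")


def classify_trait(trait: str) -> str:
    """QTL class from the trait-label grammar.

    ``<set>_<env>_aPC<k>`` -> aPC; ``<env>_PC<k>`` -> PC; anything else
    (an element name or an LS-mean label) -> elemental.
    """
    if _APC_RE.match(trait):
        return "aPC"
    if _PC_RE.match(trait):
        return "PC"
    return "elemental"


@dataclass
class QtlRecord:
    id: str
    qtl_class: str
    trait: str
    env: str
    lg: int
    ci_lo_cM: float
    ci_hi_cM: float
    lod: float
    pve_pct: float
    peak_cM: float = np.nan
    phys_lo_kb: float = np.nan
    phys_hi_kb: float = np.nan
    element: str | None = None          # elemental class only
    top5_elements: list[str] | None = None  # PC/aPC classes
    member_envs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.qtl_class not in CLASSES:
            raise ValueError(f"unknown QTL class {self.qtl_class!r}")
        if self.ci_lo_cM > self.ci_hi_cM:
            raise ValueError("support interval lo > hi")
        expected = classify_trait(self.trait)
        if expected != self.qtl_class:
            raise ValueError(
                f"trait label {self.trait!r} implies class {expected}, "
                f"got {self.qtl_class}")
        if not self.member_envs:
            self.member_envs = [self.env]

    def overlaps(self, other: "QtlRecord") -> bool:
        """Closed-interval intersection on the same linkage group."""
        return (self.lg == other.lg
                and self.ci_lo_cM <= other.ci_hi_cM
                and other.ci_lo_cM <= self.ci_hi_cM)


def records_to_frame(records: list[QtlRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "class": r.qtl_class, "trait": r.trait,
            "env": r.env, "lg": r.lg, "peak_cM": r.peak_cM,
            "ci_lo_cM": r.ci_lo_cM, "ci_hi_cM": r.ci_hi_cM,
            "phys_lo_kb": r.phys_lo_kb, "phys_hi_kb": r.phys_hi_kb,
            "lod": r.lod, "pve_pct": r.pve_pct,
            "element": r.element or "",
            "top5_elements": " ".join(r.top5_elements or []),
            "member_envs": " ".join(r.member_envs),
        })
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[QtlRecord]:
    """Inverse of :func:`records_to_frame` (reads a qtl.csv table)."""
    out = []
    for _, r in df.iterrows():
        top5 = str(r.get("top5_elements", "") or "")
        envs = str(r.get("member_envs", "") or "")
        out.append(QtlRecord(
            id=str(r["id"]), qtl_class=str(r["class"]),
            trait=str(r["trait"]), env=str(r["env"]), lg=int(r["lg"]),
            ci_lo_cM=float(r["ci_lo_cM"]), ci_hi_cM=float(r["ci_hi_cM"]),
            lod=float(r["lod"]), pve_pct=float(r["pve_pct"]),
            peak_cM=float(r.get("peak_cM", np.nan)),
            phys_lo_kb=float(r.get("phys_lo_kb", np.nan)),
            phys_hi_kb=float(r.get("phys_hi_kb", np.nan)),
            element=(str(r["element"]) if isinstance(r.get("element"), str)
                     and r.get("element") else None),
            top5_elements=top5.split() if top5.strip() else None,
            member_envs=envs.split() if envs.strip() else []))
    return out


# ---------------------------------------------------------------------------
# unique-QTL merging


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def merge_unique(records: list[QtlRecord]) -> list[QtlRecord]:
    """Merge repeated detections of the same element into unique QTLs.

    Records for the same element whose support intervals overlap on the
    same linkage group are merged transitively; the merged interval is the
    union, the representative LOD/PVE the member maximum, and provenance
    keeps every member environment. Idempotent.
    """
    for r in records:
        if r.qtl_class != "elemental":
            raise ValueError("merge_unique applies to elemental records")
    uf = _UnionFind(len(records))
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            key_a = a.element or a.trait
            key_b = b.element or b.trait
            if key_a == key_b and a.overlaps(b):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(records)):
        groups.setdefault(uf.find(i), []).append(i)
    merged = []
    for members in groups.values():
        rs = [records[i] for i in members]
        best = max(rs, key=lambda r: r.lod)
        envs = sorted({e for r in rs for e in r.member_envs})
        merged.append(replace(
            best,
            id=best.id if len(rs) == 1 else best.id + "+",
            ci_lo_cM=min(r.ci_lo_cM for r in rs),
            ci_hi_cM=max(r.ci_hi_cM for r in rs),
            phys_lo_kb=_nanreduce(np.nanmin, [r.phys_lo_kb for r in rs]),
            phys_hi_kb=_nanreduce(np.nanmax, [r.phys_hi_kb for r in rs]),
            lod=max(r.lod for r in rs),
            pve_pct=max(r.pve_pct for r in rs),
            member_envs=envs))
    merged.sort(key=lambda r: (r.lg, r.ci_lo_cM, r.trait, r.env))
    return merged


# ---------------------------------------------------------------------------
# overlap report


@dataclass
class OverlapReport:
    neighbors: dict[str, dict[str, list[str]]]  # id -> class -> ids
    venn: dict[str, int]   # per class: counts by co-localizing class combo


def overlap_classes(records: list[QtlRecord]) -> OverlapReport:
    """Pairwise co-localization lists and Venn-style counts.

    For each record, lists co-localized record ids per class (own class
    excluded from the Venn bookkeeping but included in neighbor lists);
    ``venn["elemental&PC"]`` counts elemental records overlapping at least
    one PC record, etc.
    """
    present = sorted({r.qtl_class for r in records})
    if len(present) < 2:
        warnings.warn("records from < 2 classes; overlap report is trivial")
    neighbors: dict[str, dict[str, list[str]]] = {
        r.id: {c: [] for c in CLASSES} for r in records}
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            if a.overlaps(b):
                neighbors[a.id][b.qtl_class].append(b.id)
                neighbors[b.id][a.qtl_class].append(a.id)
    venn: dict[str, int] = {}
    for cls in CLASSES:
        recs = [r for r in records if r.qtl_class == cls]
        others = [c for c in CLASSES if c != cls]
        for other in others:
            key = f"{cls}&{other}"
            venn[key] = sum(
                1 for r in recs if neighbors[r.id][other])
        venn[f"{cls}&{others[0]}&{others[1]}"] = sum(
            1 for r in recs
            if neighbors[r.id][others[0]] and neighbors[r.id][others[1]])
        venn[f"{cls}_total"] = len(recs)
    return OverlapReport(neighbors=neighbors, venn=venn)


# ---------------------------------------------------------------------------
# clusters


@dataclass
class QtlCluster:
    cluster_id: int
    lg: int
    ci_lo_cM: float
    ci_hi_cM: float
    phys_lo_kb: float
    phys_hi_kb: float
    members: dict[str, list[QtlRecord]]
    concordant: bool

    @property
    def n_members(self) -> int:
        return sum(len(v) for v in self.members.values())


def find_clusters(records: list[QtlRecord]) -> list[QtlCluster]:
    """Loci identified by all three QTL classes.

    Connected components of the co-localization graph; components missing
    any of the three classes are discarded. The cluster interval is the
    union of member intervals; the concordance flag records whether any
    member PC/aPC top-5 loading list contains the element of a co-localized
    member elemental QTL.
    """
    uf = _UnionFind(len(records))
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            if records[i].overlaps(records[j]):
                uf.union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(len(records)):
        comps.setdefault(uf.find(i), []).append(i)
    clusters = []
    for members in comps.values():
        rs = [records[i] for i in members]
        by_class = {c: [r for r in rs if r.qtl_class == c] for c in CLASSES}
        if not all(by_class[c] for c in CLASSES):
            continue
        pairs = _concordant_pairs(rs)
        clusters.append(QtlCluster(
            cluster_id=0,
            lg=rs[0].lg,
            ci_lo_cM=min(r.ci_lo_cM for r in rs),
            ci_hi_cM=max(r.ci_hi_cM for r in rs),
            phys_lo_kb=_nanreduce(np.nanmin, [r.phys_lo_kb for r in rs]),
            phys_hi_kb=_nanreduce(np.nanmax, [r.phys_hi_kb for r in rs]),
            members=by_class,
            concordant=bool(pairs["concordant"].any())
            if len(pairs) else False))
    clusters.sort(key=lambda c: (c.lg, c.ci_lo_cM))
    for k, c in enumerate(clusters):
        c.cluster_id = k + 1
    return clusters


def _concordant_pairs(records: list[QtlRecord]) -> pd.DataFrame:
    rows = []
    pcs = [r for r in records if r.qtl_class in ("PC", "aPC")]
    els = [r for r in records if r.qtl_class == "elemental"
           and r.element is not None]
    for p in pcs:
        for e in els:
            if not p.overlaps(e):
                continue
            if p.top5_elements is None:
                warnings.warn(f"{p.id}: no top-5 loading list; pair with "
                              f"{e.id} skipped")
                continue
            rows.append({"pc_id": p.id, "pc_class": p.qtl_class,
                         "elemental_id": e.id, "element": e.element,
                         "concordant": e.element in p.top5_elements})
    return pd.DataFrame(rows, columns=["pc_id", "pc_class", "elemental_id",
                                       "element", "concordant"])


def concordance_top5(records: list[QtlRecord]
                     ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Top-5 loading concordance for every co-localized (PC/aPC, elemental)
    pair, plus aggregate fractions per class.

    A pair is concordant when the elemental QTL's element appears in the
    PC/aPC record's top-5 |loading| list.
    """
    pairs = _concordant_pairs(records)
    agg: dict[str, float] = {}
    for cls in ("PC", "aPC"):
        # a PC/aPC record counts as concordant if any of its pairs is
        sub = pairs[pairs["pc_class"] == cls]
        if not len(sub):
            agg[cls] = float("nan")
            continue
        per_rec = sub.groupby("pc_id")["concordant"].any()
        agg[cls] = float(per_rec.mean())
    return pairs, agg


def clusters_to_frame(clusters: list[QtlCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        rows.append({
            "cluster_id": c.cluster_id, "lg": c.lg,
            "ci_lo_cM": c.ci_lo_cM, "ci_hi_cM": c.ci_hi_cM,
            "phys_lo_kb": c.phys_lo_kb, "phys_hi_kb": c.phys_hi_kb,
            "n_elemental": len(c.members["elemental"]),
            "n_pc": len(c.members["PC"]),
            "n_apc": len(c.members["aPC"]),
            "elements": " ".join(sorted({r.element for r in
                                         c.members["elemental"]
                                         if r.element})),
            "concordant": c.concordant,
        })
    return pd.DataFrame(rows, columns=[
        "cluster_id", "lg", "ci_lo_cM", "ci_hi_cM", "phys_lo_kb",
        "phys_hi_kb", "n_elemental", "n_pc", "n_apc", "elements",
        "concordant"])


def clusters_to_json(clusters: list[QtlCluster], path: str | Path) -> None:
    obj = []
    for c in clusters:
        obj.append({
            "cluster_id": c.cluster_id, "lg": c.lg,
            "interval_cM": [c.ci_lo_cM, c.ci_hi_cM],
            "interval_kb": [c.phys_lo_kb, c.phys_hi_kb],
            "concordant": c.concordant,
            "members": {cls: [r.id for r in rs]
                        for cls, rs in c.members.items()},
        })
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def annotate_clusters(clusters: list[QtlCluster],
                      genes: pd.DataFrame) -> pd.DataFrame:
    """Intersect cluster physical intervals with gene annotations.

    ``genes`` columns: chrom, start_bp, end_bp, name (BED-like). Reporting
    only — no ranking. Linkage group is assumed to equal chromosome id.
    """
    rows = []
    for c in clusters:
        lo, hi = c.phys_lo_kb * 1e3, c.phys_hi_kb * 1e3
        sub = genes[(genes["chrom"] == c.lg)
                    & (genes["start_bp"] <= hi)
                    & (genes["end_bp"] >= lo)]
        for _, g in sub.iterrows():
            rows.append({"cluster_id": c.cluster_id, "gene": g["name"],
                         "gene_start_bp": int(g["start_bp"]),
                         "gene_end_bp": int(g["end_bp"])})
    return pd.DataFrame(rows, columns=["cluster_id", "gene",
                                       "gene_start_bp", "gene_end_bp"])
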