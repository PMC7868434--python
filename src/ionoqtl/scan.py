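"""Univariate QTL scanning by Haley-Knott regression on a cM grid.

Any trait (an element concentration, an LS-mean composite, or a PC score)
is regressed, at every position of a 1-cM grid along each linkage group, on
the expected genotype E[x] = 2 P(TQ) - 1 obtained from a two-state Markov
chain conditioned on the line's observed bin markers (forward-backward).
LOD = (n/2) log10(RSS0 / RSS1). Genome-wide significance thresholds come
from trait permutations; peaks carry 1.5-LOD support intervals, percent
variance explained PVE = 100 (1 - 10^(-2 LOD / n)), and the fitted additive
effect of the TQ allele.

An imputation-based scan (sampling genotype realizations from the same
Markov chain and combining per-imputation LODs on the likelihood scale) is
provided as a stochastic cross-check of the deterministic HK engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binmap import BinMatrix
from .codes import LM, TQ
from .linkage import LinkageMap, inverse_map_distance, ril_observed


# ---------------------------------------------------------------------------
# conditional genotype probabilities


@dataclass
class _GroupProbs:
    pos: np.ndarray            # grid + marker positions, cM, ascending
    p_tq: np.ndarray           # (n_ril, n_pos)
    trans_R: np.ndarray        # (n_pos - 1,) RIL-level recombinant fraction
    marker_idx: np.ndarray     # indices into pos that carry >= 1 bin marker
    obs: np.ndarray            # (n_ril, n_pos) int8 observed state, -9 none
    alpha: np.ndarray          # (n_ril, n_pos, 2) normalized forward msgs


@dataclass
class GenoProbs:
    """P(TQ) per RIL on a step-cM grid along each linkage group."""

    groups: dict[int, _GroupProbs]
    ril_ids: list[str]
    step_cM: float

    def x_matrix(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Expected genotype matrix (n_ril, n_pos_total) and position meta.

        x = 2 P(TQ) - 1; meta columns: lg, pos_cM, is_marker.
        """
        cols = []
        meta = []
        for lg in sorted(self.groups):
            g = self.groups[lg]
            cols.append(2.0 * g.p_tq - 1.0)
            is_m = np.zeros(len(g.pos), dtype=bool)
            is_m[g.marker_idx] = True
            meta.append(pd.DataFrame(
                {"lg": lg, "pos_cM": g.pos, "is_marker": is_m}))
        return np.hstack(cols), pd.concat(meta, ignore_index=True)


_NOOBS = -9


def genotype_probs(bin_matrix: BinMatrix, linkage_map: LinkageMap,
                   step_cM: float = 1.0) -> GenoProbs:
    """Forward-backward P(TQ) on the union of grid and marker positions.

    The chain state is the parental origin {LM, TQ}; the transition
    probability across a map distance d is the RIL-level recombinant
    fraction R = 2r/(1+2r) with r recovered from d by the map function's
    inverse. HET and MISSING marker calls are uninformative. A RIL with no
    markers on a group has P(TQ) = 0.5 everywhere.
    """
    if not len(linkage_map.table):
        raise ValueError("empty linkage map")
    n_ril = len(bin_matrix.ril_ids)
    groups: dict[int, _GroupProbs] = {}
    for lg, sub in linkage_map.table.groupby("lg"):
        mpos = sub["cm"].to_numpy()
        bin_ids = sub["bin_id"].to_numpy()
        lo, hi = float(mpos.min()), float(mpos.max())
        grid = np.arange(lo, hi + step_cM * 0.5, step_cM)
        pos = np.unique(np.round(np.concatenate((grid, mpos, [hi])), 9))
        # observed state per RIL per position (merging markers at same pos)
        obs = np.full((n_ril, len(pos)), _NOOBS, dtype=np.int8)
        conflict = 0
        for mp, b in zip(mpos, bin_ids):
            j = int(np.searchsorted(pos, np.round(mp, 9)))
            g = bin_matrix.geno[b]
            informative = np.isin(g, (LM, TQ))
            prev = obs[informative, j]
            new = g[informative]
            clash = (prev != _NOOBS) & (prev != new)
            conflict += int(clash.sum())
            take = informative.copy()
            take[informative] = ~clash
            obs[take, j] = g[take]
        if conflict:
            warnings.warn(f"lg {lg}: {conflict} conflicting co-located "
                          "marker call(s) ignored")
        d = np.diff(pos)
        r = inverse_map_distance(d, linkage_map.map_function)
        R = np.asarray(ril_observed(r), dtype=float)

        P = len(pos)
        alpha = np.empty((n_ril, P, 2))
        a = np.full((n_ril, 2), 0.5)
        _emit(a, obs[:, 0])
        _norm(a)
        alpha[:, 0] = a
        for t in range(1, P):
            Rt = R[t - 1]
            a = np.stack((a[:, 0] * (1 - Rt) + a[:, 1] * Rt,
                          a[:, 0] * Rt + a[:, 1] * (1 - Rt)), axis=1)
            _emit(a, obs[:, t])
            _norm(a)
            alpha[:, t] = a
        beta = np.ones((n_ril, 2))
        p_tq = np.empty((n_ril, P))
        post = alpha[:, P - 1] * beta
        p_tq[:, P - 1] = post[:, 1] / post.sum(axis=1)
        for t in range(P - 2, -1, -1):
            b = beta.copy()
            _emit(b, obs[:, t + 1])
            Rt = R[t]
            beta = np.stack((b[:, 0] * (1 - Rt) + b[:, 1] * Rt,
                             b[:, 0] * Rt + b[:, 1] * (1 - Rt)), axis=1)
            _norm(beta)
            post = alpha[:, t] * beta
            p_tq[:, t] = post[:, 1] / post.sum(axis=1)
        marker_idx = np.unique(np.searchsorted(pos, np.round(mpos, 9)))
        groups[int(lg)] = _GroupProbs(pos=pos, p_tq=p_tq, trans_R=R,
                                      marker_idx=marker_idx, obs=obs,
                                      alpha=alpha)
    return GenoProbs(groups=groups, ril_ids=bin_matrix.ril_ids,
                     step_cM=step_cM)


def _emit(msg: np.ndarray, obs_col: np.ndarray) -> None:
    """Apply delta emissions in place; degenerate rows reset to uniform."""
    is_lm = obs_col == LM
    is_tq = obs_col == TQ
    msg[is_lm, 1] = 0.0
    msg[is_tq, 0] = 0.0


def _norm(msg: np.ndarray) -> None:
    s = msg.sum(axis=1, keepdims=True)
    dead = s[:, 0] == 0
    if dead.any():
        msg[dead] = 0.5
        s[dead] = 1.0
    msg /= s


# ---------------------------------------------------------------------------
# Haley-Knott scan


@dataclass
class LodCurve:
    trait: str
    table: pd.DataFrame        # lg, pos_cM, lod
    n_used: int

    def max_lod(self) -> float:
        return float(self.table["lod"].max())


def _prep_trait(probs: GenoProbs, trait) -> np.ndarray:
    if isinstance(trait, pd.Series):
        y = trait.reindex(probs.ril_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
        if len(y) != len(probs.ril_ids):
            raise ValueError("trait length does not match RIL panel")
    return y


def _lod_columns(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column single-regressor LOD and slope for complete data."""
    n = len(y)
    yc = y - y.mean()
    syy = float(yc @ yc)
    Xc = X - X.mean(axis=0)
    sxx = (Xc * Xc).sum(axis=0)
    sxy = yc @ Xc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    rss1 = np.maximum(syy - slope * sxy, 1e-300)
    lod = (n / 2.0) * np.log10(syy / rss1)
    return np.maximum(lod, 0.0), slope


def hk_scan(probs: GenoProbs, trait, name: str | None = None) -> LodCurve:
    """Haley-Knott regression LOD at every grid position.

    Regresses the trait on E[x] = 2 P(TQ) - 1; RILs with a missing trait
    value are dropped pairwise. Raises on a constant trait; warns for
    n < 10.
    """
    y = _prep_trait(probs, trait)
    ok = ~np.isnan(y)
    n = int(ok.sum())
    if n < 2 or np.nanstd(y) == 0:
        raise ValueError("trait is constant or empty after removing "
                         "missing values")
    if n < 10:
        warnings.warn(f"only {n} RILs with trait data; scan is unstable")
    X, meta = probs.x_matrix()
    lod, _ = _lod_columns(X[ok], y[ok])
    table = meta[["lg", "pos_cM"]].copy()
    table["lod"] = lod
    tname = name if name is not None else getattr(trait, "name", "trait")
    return LodCurve(trait=str(tname), table=table, n_used=n)


# ---------------------------------------------------------------------------
# imputation scan


def _sample_paths(g: _GroupProbs, n_draws: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Forward-filter backward-sample genotype paths, (draws, n_ril, P)."""
    n_ril, P, _ = g.alpha.shape
    out = np.empty((n_draws, n_ril, P), dtype=np.int8)
    for k in range(n_draws):
        s = (rng.random(n_ril) < g.alpha[:, P - 1, 1]).astype(np.int8)
        out[k, :, P - 1] = s
        for t in range(P - 2, -1, -1):
            Rt = g.trans_R[t]
            a = g.alpha[:, t]
            # P(s_t = TQ | s_{t+1}) proportional to alpha_t(TQ) T(TQ, s_next)
            t_tq = np.where(s == 1, 1 - Rt, Rt)
            t_lm = np.where(s == 1, Rt, 1 - Rt)
            w1 = a[:, 1] * t_tq
            w0 = a[:, 0] * t_lm
            p1 = w1 / (w0 + w1)
            s = (rng.random(n_ril) < p1).astype(np.int8)
            out[k, :, t] = s
    return out


def imputation_scan(probs: GenoProbs, trait, n_imputations: int = 64,
                    seed: int = 0, name: str | None = None) -> LodCurve:
    """Multiple-imputation scan; converges to HK when markers are dense.

    Draws genotype realizations from the conditional Markov chain, computes
    a per-imputation single-regressor LOD at every position, and combines
    across imputations on the likelihood scale:
    LOD = log10(mean_i 10^LOD_i).
    """
    y = _prep_trait(probs, trait)
    ok = ~np.isnan(y)
    n = int(ok.sum())
    if n < 2 or np.nanstd(y) == 0:
        raise ValueError("trait is constant or empty")
    rng = np.random.default_rng(seed)
    tables = []
    for lg in sorted(probs.groups):
        g = probs.groups[lg]
        paths = _sample_paths(g, n_imputations, rng)
        lods = np.empty((n_imputations, len(g.pos)))
        for k in range(n_imputations):
            Xk = 2.0 * paths[k, ok].astype(float) - 1.0
            lods[k], _ = _lod_columns(Xk, y[ok])
        # log-mean-likelihood combination, numerically stable
        m = lods.max(axis=0)
        comb = m + np.log10(np.mean(10.0 ** (lods - m), axis=0))
        tables.append(pd.DataFrame(
            {"lg": lg, "pos_cM": g.pos, "lod": np.maximum(comb, 0.0)}))
    tname = name if name is not None else getattr(trait, "name", "trait")
    return LodCurve(trait=str(tname), table=pd.concat(tables,
                                                      ignore_index=True),
                    n_used=n)


# ---------------------------------------------------------------------------
# permutation threshold


@dataclass
class PermutationResult:
    threshold: float
    max_lods: np.ndarray
    n_perm: int
    alpha: float
    seed: int


def permute_threshold(probs: GenoProbs, trait, n_perm: int = 1000,
                      alpha: float = 0.05, seed: int = 0
                      ) -> PermutationResult:
    """Genome-wide LOD threshold by trait permutation.

    Trait values are shuffled across RILs with genotypes fixed; the
    threshold is the empirical (1 - alpha) quantile (type-7 interpolation)
    of the per-permutation genome-wide maximum LOD.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable quantile")
    y = _prep_trait(probs, trait)
    ok = ~np.isnan(y)
    yo = y[ok]
    n = len(yo)
    rng = np.random.default_rng(seed)
    X, _ = probs.x_matrix()
    Xc = X[ok] - X[ok].mean(axis=0)
    sxx = (Xc * Xc).sum(axis=0)
    sxx_safe = np.where(sxx > 0, sxx, 1.0)
    yc = yo - yo.mean()
    syy = float(yc @ yc)
    perm = np.empty((n, n_perm))
    for k in range(n_perm):
        perm[:, k] = yc[rng.permutation(n)]
    sxy = Xc.T @ perm                      # (P, n_perm)
    rss1 = np.maximum(syy - sxy * sxy / sxx_safe[:, None], 1e-300)
    lods = (n / 2.0) * np.log10(syy / rss1)
    max_lods = lods.max(axis=0)
    thr = float(np.quantile(max_lods, 1.0 - alpha))
    return PermutationResult(threshold=thr, max_lods=max_lods,
                             n_perm=n_perm, alpha=alpha, seed=seed)


# ---------------------------------------------------------------------------
# peaks


def pve_from_lod(lod: float | np.ndarray, n: int) -> float | np.ndarray:
    """PVE (%) implied by a LOD score: 100 (1 - 10^(-2 LOD / n))."""
    return 100.0 * (1.0 - 10.0 ** (-2.0 * np.asarray(lod, dtype=float) / n))


def lod_from_pve(pve_pct: float | np.ndarray, n: int) -> float | np.ndarray:
    """Inverse of :func:`pve_from_lod`."""
    return -(n / 2.0) * np.log10(1.0 - np.asarray(pve_pct, dtype=float) / 100.0)


@dataclass
class QtlPeak:
    trait: str
    lg: int
    peak_cM: float
    lod: float
    threshold: float
    ci_lo_cM: float
    ci_hi_cM: float
    pve_pct: float
    additive_effect: float
    phys_lo_kb: float = field(default=np.nan)
    phys_hi_kb: float = field(default=np.nan)


def _support_interval(pos: np.ndarray, lod: np.ndarray, i_peak: int,
                      drop: float) -> tuple[float, float]:
    floor = lod[i_peak] - drop
    lo = i_peak
    while lo > 0 and lod[lo - 1] >= floor:
        lo -= 1
    hi = i_peak
    while hi < len(lod) - 1 and lod[hi + 1] >= floor:
        hi += 1
    return float(pos[lo]), float(pos[hi])


def _physical_interval(linkage_map: LinkageMap, lg: int,
                       lo_cM: float, hi_cM: float) -> tuple[float, float]:
    sub = linkage_map.group(lg)
    inside = sub[(sub["cm"] >= lo_cM - 1e-9) & (sub["cm"] <= hi_cM + 1e-9)]
    if not len(inside):
        nearest = sub.iloc[(sub["cm"] - (lo_cM + hi_cM) / 2).abs().argmin()]
        return float(nearest["start_bp"]) / 1e3, float(nearest["end_bp"]) / 1e3
    return (float(inside["start_bp"].min()) / 1e3,
            float(inside["end_bp"].max()) / 1e3)


def find_peaks(curve: LodCurve, threshold: float,
               min_sep_cM: float = 10.0, drop: float = 1.5,
               probs: GenoProbs | None = None, trait=None,
               linkage_map: LinkageMap | None = None) -> list[QtlPeak]:
    """Significant peaks with support intervals, PVE and additive effects.

    Local maxima with LOD >= threshold; maxima on the same group closer
    than ``min_sep_cM`` are merged keeping the higher. The support interval
    is the contiguous region where LOD stays within ``drop`` of the peak.
    When ``probs`` and ``trait`` are given the additive effect is the
    fitted HK slope at the peak (positive: the TQ allele raises the trait).
    """
    peaks: list[QtlPeak] = []
    y = _prep_trait(probs, trait) if (probs is not None
                                      and trait is not None) else None
    for lg, sub in curve.table.groupby("lg"):
        pos = sub["pos_cM"].to_numpy()
        lod = sub["lod"].to_numpy()
        cand = [i for i in range(len(lod))
                if lod[i] >= threshold
                and (i == 0 or lod[i] >= lod[i - 1])
                and (i == len(lod) - 1 or lod[i] > lod[i + 1])]
        cand.sort(key=lambda i: -lod[i])
        kept: list[int] = []
        for i in cand:
            if all(abs(pos[i] - pos[j]) >= min_sep_cM for j in kept):
                kept.append(i)
        for i in sorted(kept):
            lo, hi = _support_interval(pos, lod, i, drop)
            effect = np.nan
            if y is not None:
                g = probs.groups[int(lg)]
                jj = int(np.argmin(np.abs(g.pos - pos[i])))
                ok = ~np.isnan(y)
                x = 2.0 * g.p_tq[ok, jj] - 1.0
                xc = x - x.mean()
                denom = float(xc @ xc)
                if denom > 0:
                    effect = float(xc @ (y[ok] - y[ok].mean()) / denom)
            plo, phi = (np.nan, np.nan)
            if linkage_map is not None:
                plo, phi = _physical_interval(linkage_map, int(lg), lo, hi)
            peaks.append(QtlPeak(
                trait=curve.trait, lg=int(lg), peak_cM=float(pos[i]),
                lod=float(lod[i]), threshold=float(threshold),
                ci_lo_cM=lo, ci_hi_cM=hi,
                pve_pct=float(pve_from_lod(lod[i], curve.n_used)),
                additive_effect=effect, phys_lo_kb=plo, phys_hi_kb=phi))
    return peaks


# ---------------------------------------------------------------------------
# LS-mean composite traits


def ls_means(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Least-squares line means across environments (per element).

    Fits the additive two-way fixed-effects model
    ``trait = mu + line + environment`` by least squares and returns, per
    line, the model mean averaged over environment levels. With balanced
    data this equals the simple per-line mean. Lines absent from every
    environment are excluded.
    """
    if not tables:
        raise ValueError("no environment tables supplied")
    envs = sorted(tables)
    elements = list(tables[envs[0]].columns)
    rils = sorted(set().union(*(set(t.index) for t in tables.values())))
    long = []
    for e_i, env in enumerate(envs):
        t = tables[env]
        for el in elements:
            if list(t.columns) != elements:
                raise ValueError("element columns differ across environments")
        long.append(pd.DataFrame({
            "ril": t.index, "env": e_i, **{el: t[el].to_numpy()
                                           for el in elements}}))
    df = pd.concat(long, ignore_index=True)
    ril_index = {r: i for i, r in enumerate(rils)}
    ri = df["ril"].map(ril_index).to_numpy()
    ei = df["env"].to_numpy()
    n_obs, n_ril, n_env = len(df), len(rils), len(envs)
    # design: intercept + ril dummies (ref = first) + env dummies (ref = first)
    D = np.zeros((n_obs, 1 + (n_ril - 1) + (n_env - 1)))
    D[:, 0] = 1.0
    for k in range(1, n_ril):
        D[ri == k, k] = 1.0
    for k in range(1, n_env):
        D[ei == k, n_ril - 1 + k] = 1.0
    out = {}
    env_avg_cols = np.zeros(D.shape[1])
    env_avg_cols[0] = 1.0
    env_avg_cols[n_ril:] = 1.0 / n_env  # average over env levels (ref = 0)
    for el in elements:
        yv = df[el].to_numpy(dtype=float)
        m = ~np.isnan(yv)
        beta, *_ = np.linalg.lstsq(D[m], yv[m], rcond=None)
        ls = np.empty(n_ril)
        for k in range(n_ril):
            v = env_avg_cols.copy()
            if k > 0:
                v[k] = 1.0
            ls[k] = v @ beta
        out[el] = ls
    res = pd.DataFrame(out, index=pd.Index(rils, name="ril_id"))
    present = df.groupby("ril").size().reindex(rils).fillna(0) > 0
    return res[present.to_numpy()]
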