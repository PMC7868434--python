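"""Descriptive statistics and PCA composite traits for the ionome.

Element concentrations are z-scored per element and decomposed by PCA of
the correlation matrix, either within a single environment/tissue (PC
traits) or over rows stacked across an environment set (aPC traits, one
score vector per environment per component). PC scores become traits for
QTL scanning; loadings identify which elements drive each component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codes import ConfigError


# ---------------------------------------------------------------------------
# descriptive statistics


@dataclass
class StatsReport:
    per_element: pd.DataFrame   # skewness, kurtosis, shapiro W/p, fold range,
                                # ANOVA F/p across lines
    corr: pd.DataFrame          # element-pair Pearson r
    corr_p: pd.DataFrame        # two-sided p for r (t transform)
    sig_mask: pd.DataFrame      # True where p < alpha

    @property
    def alpha(self) -> float:
        return self._alpha

    def __post_init__(self) -> None:
        self._alpha = 0.01


def _pearson_matrix(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson r with two-sided p by t transform."""
    cols = list(X.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    arr = X.to_numpy(dtype=float)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            ok = ~np.isnan(arr[:, i]) & ~np.isnan(arr[:, j])
            n = int(ok.sum())
            if n < 3:
                continue
            xi, xj = arr[ok, i], arr[ok, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            rij = float(np.corrcoef(xi, xj)[0, 1])
            rij = float(np.clip(rij, -1.0, 1.0))
            if abs(rij) >= 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((n - 2) / (1.0 - rij * rij))
                pij = float(2 * stats.t.sf(abs(t), n - 2))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def phenotype_stats(table: pd.DataFrame, ril_col: str = "ril_id",
                    alpha: float = 0.01) -> StatsReport:
    """Per-element distribution statistics and the element correlation map.

    ``table`` is long format: one row per measurement with a ``ril_col``
    line identifier and one column per element; replicate rows per line
    (e.g. one per environment) feed the across-line ANOVA. Skewness,
    kurtosis, the Shapiro-Wilk normality test, fold range, and pairwise
    Pearson correlations are computed on per-line means. Correlations with
    p >= ``alpha`` are masked out, mirroring the convention of reporting
    only significant r values.
    """
    if ril_col in table.columns:
        df = table
    else:
        df = table.reset_index()
        if ril_col not in df.columns:
            raise ValueError(f"no {ril_col!r} column or index level")
    elements = [c for c in df.columns if c not in (ril_col, "env")]
    means = df.groupby(ril_col)[elements].mean()
    has_reps = (df.groupby(ril_col).size() > 1).any()

    rows = []
    for el in elements:
        x = means[el].dropna().to_numpy()
        if len(x) < 3 or x.std() == 0:
            rows.append({"element": el, "skewness": np.nan,
                         "kurtosis": np.nan, "shapiro_W": np.nan,
                         "shapiro_p": np.nan, "fold_range": np.nan,
                         "anova_F": np.nan, "anova_p": np.nan})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W, sp = stats.shapiro(x)
        fold = float(x.max() / x.min()) if x.min() > 0 else np.nan
        F = pv = np.nan
        if has_reps:
            groups = [g.dropna().to_numpy()
                      for _, g in df.groupby(ril_col)[el]]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) >= 3:
                F, pv = stats.f_oneway(*groups)
        rows.append({"element": el,
                     "skewness": float(stats.skew(x)),
                     "kurtosis": float(stats.kurtosis(x)),
                     "shapiro_W": float(W), "shapiro_p": float(sp),
                     "fold_range": fold,
                     "anova_F": float(F), "anova_p": float(pv)})
    per_element = pd.DataFrame(rows).set_index("element")
    corr, corr_p = _pearson_matrix(means)
    report = StatsReport(per_element=per_element, corr=corr, corr_p=corr_p,
                         sig_mask=corr_p < alpha)
    report._alpha = alpha
    return report


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaModel:
    """Correlation-matrix PCA of the multi-element phenotype.

    ``loadings``: element x PC orthonormal matrix; ``scores``: row x PC
    (rows follow the input, index (env, ril) for across-environment fits);
    ``var_fraction``: per-PC share of total variance; ``center``/``scale``:
    the per-element z-score parameters; ``scope``: environment label or
    set name; ``n_dropped``: rows removed for missing values.
    """

    scope: str
    loadings: pd.DataFrame
    scores: pd.DataFrame
    var_fraction: np.ndarray
    center: pd.Series
    scale: pd.Series
    n_dropped: int = 0

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[1]


def _pca_core(Z: np.ndarray, elements: list[str], index, scope: str,
              center: pd.Series, scale: pd.Series,
              n_dropped: int) -> PcaModel:
    n = Z.shape[0]
    corr = (Z.T @ Z) / (n - 1)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    # deterministic sign: the largest-|loading| element loads positively
    for j in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, j])))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    pcs = [f"PC{j + 1}" for j in range(v.shape[1])]
    loadings = pd.DataFrame(v, index=elements, columns=pcs)
    scores = pd.DataFrame(Z @ v, index=index, columns=pcs)
    return PcaModel(scope=scope, loadings=loadings, scores=scores,
                    var_fraction=w / w.sum(), center=center, scale=scale,
                    n_dropped=n_dropped)


def pca_within(table: pd.DataFrame, scope: str = "within") -> PcaModel:
    """PCA of one environment/tissue (rows = lines, columns = elements).

    Each element is z-scored (mean 0, SD 1, ddof 1) and the correlation
    matrix eigendecomposed; rows with any missing element are dropped with
    a logged count. Returns as many PCs as elements.
    """
    complete = table.dropna()
    n_dropped = len(table) - len(complete)
    if n_dropped:
        warnings.warn(f"{scope}: dropped {n_dropped} incomplete row(s)")
    if len(complete) < 2:
        raise ConfigError("need at least 2 complete rows for PCA")
    sd = complete.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ConfigError(f"constant element column(s): {bad}")
    mu = complete.mean()
    Z = ((complete - mu) / sd).to_numpy(dtype=float)
    return _pca_core(Z, list(table.columns), complete.index, scope,
                     mu, sd, n_dropped)


def pca_across(tables: dict[str, pd.DataFrame], set_name: str) -> PcaModel:
    """PCA over rows stacked across an environment set (long format).

    Rows are (line, environment) observations of the 16 elements; z-scoring
    is over the stacked rows, so between-environment mean shifts remain in
    the decomposition. Scores carry a (env, ril_id) MultiIndex; use
    :func:`scores_by_env` to regroup them into per-environment trait
    vectors.
    """
    if not tables:
        raise ConfigError("empty environment set")
    envs = sorted(tables)
    if len(envs) == 1:
        warnings.warn("environment set of size 1; delegating to pca_within")
        m = pca_within(tables[envs[0]], scope=set_name)
        m.scores.index = pd.MultiIndex.from_product(
            [[envs[0]], m.scores.index], names=["env", "ril_id"])
        return m
    elements = list(tables[envs[0]].columns)
    for e in envs:
        if list(tables[e].columns) != elements:
            raise ConfigError("element sets differ across environments")
    stacked = pd.concat({e: tables[e] for e in envs},
                        names=["env", "ril_id"])
    model = pca_within(stacked, scope=set_name)
    return model


def scores_by_env(model: PcaModel, set_name: str | None = None
                  ) -> dict[str, pd.DataFrame]:
    """Regroup across-environment PC scores into per-environment tables.

    Returns {env: DataFrame(ril x aPCs)} with trait-style column labels
    ``<set>_<env>_aPC<k>``.
    """
    name = set_name or model.scope
    if not isinstance(model.scores.index, pd.MultiIndex):
        raise ValueError("model scores are not grouped by environment")
    out = {}
    for env, sub in model.scores.groupby(level="env"):
        sub = sub.droplevel("env")
        sub = sub.rename(columns={
            f"PC{k + 1}": f"{name}_{env}_aPC{k + 1}"
            for k in range(model.n_pc)})
        out[str(env)] = sub
    return out


def top_loading_elements(model: PcaModel, pc: int, k: int = 5
                         ) -> list[tuple[str, float]]:
    """Elements with the k largest |loadings| on a PC (1-based index).

    Sorted by |loading| descending; ties broken by element column order.
    Returns (element, signed loading) pairs; k is clipped to the number of
    elements.
    """
    if not 1 <= pc <= model.n_pc:
        raise ValueError(f"pc must be in 1..{model.n_pc}")
    col = model.loadings[f"PC{pc}"]
    k = min(k, len(col))
    order = sorted(range(len(col)),
                   key=lambda i: (-abs(col.iloc[i]), i))
    return [(col.index[i], float(col.iloc[i])) for i in order[:k]]
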