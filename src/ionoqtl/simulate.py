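"""Synthetic RIL ionome generator with a known truth set.

Emulates the data-generating process of a low-coverage-sequenced rice RIL
panel: two fully homozygous parents differing at every SNP site, F_k lines
produced by single-seed-descent selfing with Poisson (no-interference)
crossovers, sparse per-line SNP observation at ~2x mean depth with a small
genotyping-error rate, and multi-environment element concentrations driven
by planted additive QTLs (optionally pleiotropic and environment-specific)
on top of correlated residual noise.

All randomness derives from ``SimConfig.seed`` through named sub-streams, so
every artifact is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codes import ELEMENTS, HET, LM, MISSING, STUDY_ENVS, TQ, ConfigError
from .binmap import SnpTable


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PlantedQtl:
    """A known additive QTL planted by the simulator.

    ``additive_effects`` maps element name -> effect of the TQ allele in
    residual-SD units; a line's contribution to that element is
    ``effect * x`` with ``x = +1`` for TQ, ``-1`` for LM, ``0`` for HET.
    ``environments`` restricts where the QTL is active (None = all).
    """

    chrom: int
    position_cM: float
    additive_effects: dict[str, float]
    environments: list[str] | None = None

    @property
    def affected_elements(self) -> list[str]:
        return list(self.additive_effects)

    def theoretical_pve(self, element: str, total_genetic_var: float) -> float:
        """Expected percent variance explained for ``element``.

        With balanced +/-1 genotypes the QTL variance is a^2 and the
        phenotype variance is (sum of active a^2 over QTLs) + 1 (unit
        residual SD), so PVE = a^2 / sigma^2_total.
        """
        a = self.additive_effects[element]
        return 100.0 * a * a / (total_genetic_var + 1.0)


@dataclass
class SimConfig:
    n_ril: int = 257
    n_chrom: int = 12
    chrom_len_bp: int = 30_000_000
    chrom_len_cM: float = 146.0
    n_snp_per_chrom: int = 4000
    generation: int = 20
    mean_depth: float = 2.0
    genotyping_error: float = 0.005
    env_names: list[str] = field(default_factory=lambda: list(STUDY_ENVS))
    elements: list[str] = field(default_factory=lambda: list(ELEMENTS))
    qtl_spec: list[PlantedQtl] = field(default_factory=list)
    element_corr_noise: np.ndarray | None = None
    env_effect_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ril < 2:
            raise ConfigError("n_ril must be >= 2")
        if self.generation < 2:
            raise ConfigError("generation must be >= 2 (F1 cannot be a RIL)")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.chrom_len_cM <= 0:
            raise ConfigError("chromosome map length must be positive")
        if not 0 <= self.genotyping_error < 0.5:
            raise ConfigError("genotyping_error must be in [0, 0.5)")
        for q in self.qtl_spec:
            if not q.additive_effects:
                raise ConfigError("planted QTL must affect >= 1 element")
            if not 0 <= q.position_cM <= self.chrom_len_cM:
                raise ConfigError(
                    f"QTL position {q.position_cM} cM outside chromosome "
                    f"map [0, {self.chrom_len_cM}]")
            if not 1 <= q.chrom <= self.n_chrom:
                raise ConfigError(f"QTL chromosome {q.chrom} out of range")
        if self.element_corr_noise is not None:
            c = np.asarray(self.element_corr_noise, dtype=float)
            k = len(self.elements)
            if c.shape != (k, k):
                raise ConfigError("element_corr_noise has wrong shape")
            if not np.allclose(c, c.T):
                raise ConfigError("element_corr_noise must be symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ConfigError("element_corr_noise must have unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ConfigError("element_corr_noise must be PSD")

    @property
    def n_env(self) -> int:
        return len(self.env_names)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def cm_to_bp(self, pos_cM: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(pos_cM) / self.chrom_len_cM * self.chrom_len_bp

    def bp_to_cm(self, pos_bp: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(pos_bp) / self.chrom_len_bp * self.chrom_len_cM


# ---------------------------------------------------------------------------
# meiosis on piecewise-constant haplotypes

# A haplotype along one chromosome is a step function of parental origin:
# (breaks, origins) with len(origins) == len(breaks) + 1, breaks in cM.


def _eval_hap(breaks: np.ndarray, origins: np.ndarray,
              pos: np.ndarray) -> np.ndarray:
    return origins[np.searchsorted(breaks, pos, side="right")]


def _compress(breaks: list[float], origins: list[int]):
    """Drop breakpoints between segments of equal origin."""
    out_b: list[float] = []
    out_o: list[int] = [origins[0]]
    for b, o in zip(breaks, origins[1:]):
        if o != out_o[-1]:
            out_b.append(b)
            out_o.append(o)
    return np.asarray(out_b), np.asarray(out_o, dtype=np.int8)

def _meiosis(hapA, hapB, length_cM: float, rng: np.random.Generator):
    """One gamete from a diploid, Poisson crossovers (no interference).

    Crossover count ~ Poisson(length in Morgans); positions uniform.
    """
    n_co = rng.poisson(length_cM / 100.0)
    xs = np.sort(rng.uniform(0.0, length_cM, n_co))
    start = int(rng.integers(2))
    haps = (hapA, hapB)
    bounds = np.concatenate(([0.0], xs, [length_cM]))
    breaks: list[float] = []
    origins: list[int] = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        hb, ho = haps[(start + i) % 2]
        j0 = np.searchsorted(hb, lo, side="right")
        j1 = np.searchsorted(hb, hi, side="left")
        origins.append(int(ho[j0]))
        for j in range(j0, j1):
            breaks.append(float(hb[j]))
            origins.append(int(ho[j + 1]))
        if hi < length_cM:
            breaks.append(float(hi))
    return _compress(breaks, origins)


# ---------------------------------------------------------------------------
# truth set


@dataclass
class TruthSet:
    """Ground truth of a simulated RIL panel.

    ``tracks[r][c]`` is the diploid parental-origin track of RIL r on
    chromosome c as ``(breaks_cM, genos)`` with genotype codes LM/TQ/HET;
    ``snp_pos[c]`` are the SNP site positions (bp, 1-based, sorted);
    ``true_genotypes[c]`` is an (n_ril, n_snp) int8 matrix of true codes.
    """

    config: SimConfig
    tracks: list[list[tuple[np.ndarray, np.ndarray]]]
    snp_pos: list[np.ndarray]
    true_genotypes: list[np.ndarray]
    planted_qtls: list[PlantedQtl]
    realized_pve: pd.DataFrame | None = None

    @property
    def ril_ids(self) -> list[str]:
        return [f"RIL{i + 1:04d}" for i in range(self.config.n_ril)]

    def crossovers_bp(self, ril: int, chrom: int) -> np.ndarray:
        """Positions (bp) where the diploid genotype of a RIL changes."""
        breaks, _ = self.tracks[ril][chrom - 1]
        return np.asarray(np.round(self.config.cm_to_bp(breaks)), dtype=np.int64)

    def genotype_at(self, chrom: int, pos_bp: np.ndarray) -> np.ndarray:
        """True genotype codes (n_ril, len(pos)) at arbitrary bp positions."""
        pos_cm = self.config.bp_to_cm(np.asarray(pos_bp, dtype=float))
        out = np.empty((self.config.n_ril, len(np.atleast_1d(pos_cm))),
                       dtype=np.int8)
        for r in range(self.config.n_ril):
            breaks, genos = self.tracks[r][chrom - 1]
            out[r] = _eval_hap(breaks, genos, np.atleast_1d(pos_cm))
        return out

    def het_fraction(self) -> np.ndarray:
        """Per-RIL heterozygous genome fraction (cM-weighted, exact)."""
        cfg = self.config
        total = cfg.n_chrom * cfg.chrom_len_cM
        fr = np.zeros(cfg.n_ril)
        for r in range(cfg.n_ril):
            het = 0.0
            for c in range(cfg.n_chrom):
                breaks, genos = self.tracks[r][c]
                edges = np.concatenate(([0.0], breaks, [cfg.chrom_len_cM]))
                seg = np.diff(edges)
                het += seg[genos == HET].sum()
            fr[r] = het / total
        return fr

    def qtl_genotype(self, qtl: PlantedQtl) -> np.ndarray:
        """x in {-1, 0, +1} per RIL at a planted QTL (TQ allele = +1)."""
        pos_bp = self.config.cm_to_bp(qtl.position_cM)
        g = self.genotype_at(qtl.chrom, np.asarray([pos_bp]))[:, 0]
        x = np.zeros(self.config.n_ril)
        x[g == TQ] = 1.0
        x[g == LM] = -1.0
        return x

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        cfg = self.config
        obj = {
            "config": {
                "n_ril": cfg.n_ril, "n_chrom": cfg.n_chrom,
                "chrom_len_bp": cfg.chrom_len_bp,
                "chrom_len_cM": cfg.chrom_len_cM,
                "n_snp_per_chrom": cfg.n_snp_per_chrom,
                "generation": cfg.generation,
                "mean_depth": cfg.mean_depth,
                "genotyping_error": cfg.genotyping_error,
                "env_names": cfg.env_names, "elements": cfg.elements,
                "env_effect_sd": cfg.env_effect_sd, "seed": cfg.seed,
                "element_corr_noise":
                    None if cfg.element_corr_noise is None
                    else np.asarray(cfg.element_corr_noise).tolist(),
            },
            "qtls": [
                {"chrom": q.chrom, "position_cM": q.position_cM,
                 "additive_effects": q.additive_effects,
                 "environments": q.environments}
                for q in self.planted_qtls
            ],
            "snp_pos": [p.tolist() for p in self.snp_pos],
            "tracks": [
                [[b.tolist(), g.tolist()] for b, g in ril]
                for ril in self.tracks
            ],
        }
        Path(path).write_text(json.dumps(obj, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        obj = json.loads(Path(path).read_text())
        c = obj["config"]
        qtls = [PlantedQtl(q["chrom"], q["position_cM"],
                           q["additive_effects"], q["environments"])
                for q in obj["qtls"]]
        cfg = SimConfig(
            n_ril=c["n_ril"], n_chrom=c["n_chrom"],
            chrom_len_bp=c["chrom_len_bp"], chrom_len_cM=c["chrom_len_cM"],
            n_snp_per_chrom=c["n_snp_per_chrom"], generation=c["generation"],
            mean_depth=c["mean_depth"],
            genotyping_error=c["genotyping_error"],
            env_names=c["env_names"], elements=c["elements"],
            qtl_spec=qtls,
            element_corr_noise=None if c["element_corr_noise"] is None
            else np.asarray(c["element_corr_noise"]),
            env_effect_sd=c["env_effect_sd"], seed=c["seed"])
        tracks = [
            [(np.asarray(b, dtype=float), np.asarray(g, dtype=np.int8))
             for b, g in ril]
            for ril in obj["tracks"]
        ]
        snp_pos = [np.asarray(p, dtype=np.int64) for p in obj["snp_pos"]]
        true_g = _genotypes_at_snps(cfg, tracks, snp_pos)
        return cls(cfg, tracks, snp_pos, true_g, qtls)

    def equals(self, other: "TruthSet") -> bool:
        if self.config.n_ril != other.config.n_ril:
            return False
        for a, b in zip(self.snp_pos, other.snp_pos):
            if not np.array_equal(a, b):
                return False
        for ra, rb in zip(self.tracks, other.tracks):
            for (ba, ga), (bb, gb) in zip(ra, rb):
                if not (np.allclose(ba, bb) and np.array_equal(ga, gb)):
                    return False
        return True


def _genotypes_at_snps(cfg, tracks, snp_pos):
    out = []
    for c in range(cfg.n_chrom):
        pos_cm = cfg.bp_to_cm(snp_pos[c].astype(float))
        g = np.empty((cfg.n_ril, len(snp_pos[c])), dtype=np.int8)
        for r in range(cfg.n_ril):
            breaks, genos = tracks[r][c]
            g[r] = _eval_hap(breaks, genos, pos_cm)
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# operations


def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ["genomes", "snp_pos", "observe", "pheno", "env"]
    return {n: np.random.default_rng(s)
            for n, s in zip(names, ss.spawn(len(names)))}


def simulate_ril_genomes(config: SimConfig) -> TruthSet:
    """Breed an F_k RIL panel by single-seed descent from the F1.

    Each of ``generation - 1`` selfing rounds draws two independent gametes
    per chromosome (Poisson crossovers at rate map-length-in-Morgans, no
    interference) from the current plant. Returns the full truth set.
    """
    rngs = _streams(config.seed)
    rng = rngs["genomes"]
    L = config.chrom_len_cM
    empty = np.empty(0)
    f1 = [(
        (empty, np.asarray([LM], dtype=np.int8)),
        (empty, np.asarray([TQ], dtype=np.int8)),
    ) for _ in range(config.n_chrom)]

    tracks: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for _ in range(config.n_ril):
        plant = f1
        for _gen in range(config.generation - 1):
            plant = [
                (_meiosis(hA, hB, L, rng), _meiosis(hA, hB, L, rng))
                for hA, hB in plant
            ]
        ril_tracks = []
        for hA, hB in plant:
            bA, oA = hA
            bB, oB = hB
            cut = np.unique(np.concatenate((bA, bB)))
            mids = np.concatenate((cut, [L + 1.0]))
            # genotype on each segment between consecutive cuts
            probe = np.concatenate(([0.0], cut)) + 1e-9
            gA = _eval_hap(bA, oA, probe)
            gB = _eval_hap(bB, oB, probe)
            geno = np.where(gA == gB, gA, HET).astype(np.int8)
            breaks, genos = _compress(list(cut), list(geno))
            ril_tracks.append((breaks, genos))
        tracks.append(ril_tracks)

    snp_rng = rngs["snp_pos"]
    snp_pos = []
    for _c in range(config.n_chrom):
        pos = np.sort(snp_rng.choice(
            np.arange(1, config.chrom_len_bp + 1, 7, dtype=np.int64),
            size=config.n_snp_per_chrom, replace=False))
        snp_pos.append(pos)

    true_g = _genotypes_at_snps(config, tracks, snp_pos)
    return TruthSet(config, tracks, snp_pos, true_g, list(config.qtl_spec))


_BASES = np.array(list("ACGT"))


def simulate_snp_observations(truth: TruthSet, config: SimConfig | None = None
                              ) -> SnpTable:
    """Sample sparse sequencing-based SNP calls from the truth set.

    Per RIL per site: depth ~ Poisson(mean_depth); zero depth is MISSING;
    covered sites report the true parental allele, flipped with probability
    ``genotyping_error``; truly heterozygous sites report either allele with
    equal probability. Parents are observed at high depth, error-free.
    """
    cfg = config or truth.config
    rng = _streams(cfg.seed)["observe"]
    n_ril = cfg.n_ril

    sites_frames = []
    calls_parts = []
    depth_parts = []
    for c in range(cfg.n_chrom):
        pos = truth.snp_pos[c]
        n = len(pos)
        ref_idx = rng.integers(0, 4, n)
        alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
        p_depth1 = rng.poisson(60, n).clip(min=10)
        p_depth2 = rng.poisson(60, n).clip(min=10)
        sites_frames.append(pd.DataFrame({
            "chrom": np.full(n, c + 1, dtype=np.int32),
            "pos": pos,
            "p1_allele": _BASES[ref_idx],
            "p2_allele": _BASES[alt_idx],
            "p1_depth": p_depth1.astype(np.int32),
            "p2_depth": p_depth2.astype(np.int32),
            "p1_hom": True,
            "p2_hom": True,
        }))
        depth = rng.poisson(cfg.mean_depth, (n, n_ril)).astype(np.int16)
        g = truth.true_genotypes[c].T  # (n_snp, n_ril)
        obs = g.copy()
        het = g == HET
        if het.any():
            obs[het] = np.where(rng.random(het.sum()) < 0.5, LM, TQ)
        if cfg.genotyping_error > 0:
            flip = rng.random((n, n_ril)) < cfg.genotyping_error
            obs = np.where(flip, 1 - obs, obs)
        obs = np.where(depth == 0, MISSING, obs).astype(np.int8)
        calls_parts.append(obs)
        depth_parts.append(depth)

    sites = pd.concat(sites_frames, ignore_index=True)
    return SnpTable(sites=sites,
                    calls=np.vstack(calls_parts),
                    depth=np.vstack(depth_parts),
                    ril_ids=truth.ril_ids)


def simulate_phenotypes(truth: TruthSet, config: SimConfig | None = None
                        ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate per-environment element concentration tables.

    For environment e and element j:
    ``y = sum_q a_qj * x_q + mu_ej + eps`` with x in {-1, +1} (HET -> 0),
    environment shifts mu_ej ~ N(0, env_effect_sd^2), and eps multivariate
    normal with unit variances and correlation ``element_corr_noise``.
    Returns ``(tables, realized_pve)`` where realized_pve reports, per
    (QTL, element, environment), the sample PVE alongside theory.
    """
    cfg = config or truth.config
    rngs = _streams(cfg.seed)
    rng = rngs["pheno"]
    env_rng = rngs["env"]
    k = cfg.n_elements
    corr = (np.eye(k) if cfg.element_corr_noise is None
            else np.asarray(cfg.element_corr_noise, dtype=float))
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))

    xs = {id(q): truth.qtl_genotype(q) for q in truth.planted_qtls}
    # per-element total genetic variance (all environments pooled view)
    tot_gen = {el: sum(q.additive_effects.get(el, 0.0) ** 2
                       for q in truth.planted_qtls)
               for el in cfg.elements}

    mu = env_rng.normal(0.0, cfg.env_effect_sd, (cfg.n_env, k))
    tables: dict[str, pd.DataFrame] = {}
    rows = []
    for e_i, env in enumerate(cfg.env_names):
        eps = rng.standard_normal((cfg.n_ril, k)) @ chol.T
        y = eps + mu[e_i]
        for q in truth.planted_qtls:
            if q.environments is not None and env not in q.environments:
                continue
            x = xs[id(q)]
            for el, a in q.additive_effects.items():
                j = cfg.elements.index(el)
                y[:, j] += a * x
        df = pd.DataFrame(y, index=pd.Index(truth.ril_ids, name="ril_id"),
                          columns=cfg.elements)
        tables[env] = df
        for qi, q in enumerate(truth.planted_qtls):
            if q.environments is not None and env not in q.environments:
                continue
            x = xs[id(q)]
            vx = x.var()
            for el, a in q.additive_effects.items():
                yv = y[:, cfg.elements.index(el)]
                slope = (np.cov(yv, x)[0, 1] / vx) if vx > 0 else np.nan
                realized = (100.0 * slope * slope * vx / yv.var()
                            if vx > 0 else np.nan)
                rows.append({
                    "qtl": qi, "chrom": q.chrom,
                    "position_cM": q.position_cM, "element": el,
                    "env": env, "effect": a,
                    "theoretical_pve": q.theoretical_pve(el, tot_gen[el]),
                    "realized_pve": realized,
                })
    report = pd.DataFrame(rows)
    truth.realized_pve = report
    return tables, report


def write_fixture(truth: TruthSet, observations: SnpTable,
                  phenotypes: dict[str, pd.DataFrame],
                  outdir: str | Path) -> dict[str, Path]:
    """Write VCF + phenotype CSVs + truth JSON; byte-stable given seed."""
    from .io import write_vcf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    vcf = out / "genotypes.vcf"
    write_vcf(observations, vcf,
              contig_lengths={c + 1: truth.config.chrom_len_bp
                              for c in range(truth.config.n_chrom)})
    paths["vcf"] = vcf
    for env, df in phenotypes.items():
        p = out / f"pheno_{env}.csv"
        df.to_csv(p, float_format="%.8g")
        paths[f"pheno_{env}"] = p
    tj = out / "truth.json"
    truth.to_json(tj)
    paths["truth"] = tj
    return paths


def truth_bin_matrix(truth: TruthSet, bin_cM: float = 1.0):
    """Idealized bin matrix read directly off the truth set.

    Tiles each chromosome with uniform ``bin_cM`` bins and takes each RIL's
    true genotype at the bin midpoint — the dense-marker, error-free limit
    of the window-calling pipeline. Used to isolate map- and scan-stage
    behaviour from genotyping noise.
    """
    from .binmap import BinMatrix

    cfg = truth.config
    frames = []
    genos = []
    n_bins_per = max(2, int(round(cfg.chrom_len_cM / bin_cM)))
    for c in range(1, cfg.n_chrom + 1):
        edges = np.linspace(0, cfg.chrom_len_bp, n_bins_per + 1,
                            dtype=np.int64)
        mids = (edges[:-1] + edges[1:]) / 2.0
        frames.append(pd.DataFrame({
            "chrom": c, "start_bp": edges[:-1], "end_bp": edges[1:],
            "n_merged": 1}))
        genos.append(truth.genotype_at(c, mids).T)
    return BinMatrix(bins=pd.concat(frames, ignore_index=True),
                     geno=np.vstack(genos), ril_ids=truth.ril_ids)


def example_qtl_spec(elements: list[str] | None = None) -> list[PlantedQtl]:
    """A paper-like truth set: pleiotropic loci on correlated elements.

    Mirrors the qualitative architecture of the reference cross: a strong
    Cu/As locus (chr 2), a Sr/Ca locus (chr 3), a Mn locus (chr 7), a
    P-K-Mg locus (chr 1), and one environment-specific Mo locus.
    """
    qtls = [
        PlantedQtl(2, 55.0, {"Cu": 0.55, "As": 0.35}),
        PlantedQtl(3, 67.0, {"Sr": 0.5, "Ca": 0.45}),
        PlantedQtl(7, 40.0, {"Mn": 0.5, "Cd": 0.3}),
        PlantedQtl(1, 30.0, {"P": 0.4, "K": 0.35, "Mg": 0.3}),
        PlantedQtl(8, 5.0, {"Mo": 0.6},
                   environments=["02GF", "03GF", "06GF", "07GF", "08GF2"]),
    ]
    if elements is not None:
        keep = set(elements)
        qtls = [q for q in qtls
                if set(q.additive_effects) <= keep]
    return qtls


def study_corr_noise(elements: list[str] | None = None,
                     pairs: dict[tuple[str, str], float] | None = None
                     ) -> np.ndarray:
    """Residual correlation matrix emulating observed element couplings.

    Defaults plant the chemical-analog and nutrient couplings reported for
    this cross (strong Ca-Sr; moderate P-K-Mg; weak Mn-Cd), then project to
    the nearest PSD correlation matrix if needed.
    """
    els = elements or ELEMENTS
    k = len(els)
    c = np.eye(k)
    default_pairs = {
        ("Ca", "Sr"): 0.6,
        ("P", "K"): 0.45, ("P", "Mg"): 0.45, ("K", "Mg"): 0.4,
        ("Mn", "Cd"): 0.3, ("Cu", "As"): 0.3,
    }
    for (a, b), r in (pairs or default_pairs).items():
        if a in els and b in els:
            i, j = els.index(a), els.index(b)
            c[i, j] = c[j, i] = r
    w, v = np.linalg.eigh(c)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        c = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
    return c
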