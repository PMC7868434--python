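# Methods

This note records the models, parameter choices, numerical conventions,
and known limitations of the `ionoqtl` pipeline. Nothing here asserts an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Population and genotype model

**Breeding.** A RIL panel descends from an F1 between two fully homozygous
parents by single-seed descent. Each selfing round draws, per chromosome,
two independent gametes from the current plant; crossovers per meiosis are
Poisson with mean equal to the chromosome map length in Morgans, placed
uniformly, with no interference. The haplotype is a piecewise-constant
parental-origin function in cM; bp and cM interconvert linearly (uniform
recombination density). No residual-heterozygosity selection is modelled:
heterozygosity simply halves each generation, h_t = h_{t-1}/2 from h_1 = 1,
giving (1/2)^19 ≈ 1.9·10⁻⁶ at F20. The Poisson (Haldane-consistent) model
was chosen as the simplest one compatible with the map functions used
downstream; Kosambi mapping of such data is slightly conservative but the
bias is far below the 10% recovery tolerance at bin-scale distances.

**Observation.** Per line per SNP site, read depth ~ Poisson(mean depth,
default 2.0); zero-depth sites are missing (zero class e⁻² ≈ 13.5%);
covered sites report the true parental allele flipped with the genotyping
error probability (default 0.5% per call — the study this emulates states
no error rate, so the default is an assumption exposed as a parameter).
Truly heterozygous sites report either allele with equal probability.
Parents are simulated at high depth (≥ 10x), error-free, and opposite
homozygous at every site: the real pipeline's SNP discovery step only
retains parent-divergent sites, so all simulated sites are informative by
construction. Simulated SNP positions keep ≥ 7 bp spacing so the 5-bp
adjacency filter does not silently remove simulated sites.

**Phenotypes.** For environment e and element j,
y = Σ_q a_qj·x_q + μ_ej + ε, with x ∈ {−1, +1} for the two parental
genotypes (0 for residual heterozygotes), per-(environment, element)
shifts μ_ej ~ N(0, 0.5²), and ε multivariate normal with unit variances
and a configurable residual correlation matrix. Effects are in residual-SD
units, so a single QTL's theoretical PVE is a²/(a² + 1); with several QTLs
on one element the denominator adds their variances. The default residual
correlation (`study_corr_noise`) plants the couplings observed in rice
ionome panels: Ca–Sr 0.6 (chemical analogs), P–K 0.45, P–Mg 0.45,
K–Mg 0.4, Mn–Cd 0.3, Cu–As 0.3, projected to the nearest positive
semi-definite correlation matrix. What the generator does **not** emulate:
measurement batch effects, genotype-by-environment interaction beyond
on/off activity lists, non-normal concentration distributions, segregation
distortion, and structural variation — so green tests demonstrate
correctness of the algorithms under the stated model, not robustness to
every artifact of field data. The default environment-shift SD (0.5) is
modest; the dominance of the leading across-environment PC grows with it
and with tissue-scale shifts, which real grain/root/shoot contrasts
exceed.

## Bin genotyping

Windows slide over each line's *observed* calls (not genomic sites): at 2x
coverage a fixed-site window would be mostly empty. A 15-SNP window is
called for a parent when that parent's call count exceeds 11; when neither
parent wins and both counts reach 4 the window is heterozygous; otherwise
missing. The two-sided HET rule is this package's decision (the source
methodology defines only the parental rule); it is conservative against
sparse-window noise, and every composition (c_TQ, c_LM) with
c_TQ + c_LM ≤ 15 maps to exactly one label (enumeration-tested).

**Blocks and breakpoints.** Maximal runs of identical window labels become
blocks; a breakpoint between discordant blocks is the midpoint between the
last window anchor (median observed-SNP position) of the left run and the
first anchor of the right run. Interior missing runs are absorbed only
when both flanks agree. One refinement proved necessary: the majority rule
deterministically emits a ~8-window HET run at every true crossover
(compositions 11/4 … 4/11 as the window crosses the junction), which a
literal blocks-from-runs reading would call as spurious heterozygous
segments at every crossover (~0.5–1% of all (line, bin) calls — an order
of magnitude above the accuracy this stage achieves otherwise). A HET run
between *opposite* parental flanks shorter than `min_het_run` (default:
one window, 15) is therefore interpreted as the crossover transition zone
and split at its midpoint; HET runs between *agreeing* flanks are kept as
genuine blocks whatever their length, which preserves short
double-crossover segments and residual-heterozygous tracts.

**Resolution limit.** A majority window cannot, even in principle, place a
breakpoint for a double-crossover segment spanning fewer than ~4 observed
SNPs, nor for a junction inside the terminal half-window of a chromosome;
under the no-interference model ~1–2% of F20 junctions fall in these
classes. Recovery experiments therefore report both overall recovery and
recovery of *resolvable* crossovers (≥ 15 observed SNPs from any other
crossover and from the ends); completeness is asserted on the resolvable
subset.

**Bins.** Population bin boundaries are the union of all lines'
breakpoints; a bin's genotype per line is its covering block's label. Bins
shorter than 20 kb are merged into the neighbour with fewer
population-level genotype conflicts (ties merge left; configurable exempt
chromosomes — default chromosome 4, which in the emulated design lacks
marker density — skip the filter). Coordinates are 0-based half-open
internally and 1-based in reports. Heterozygosity is the bp-weighted HET
fraction of non-missing bins.

## Linkage map

R between adjacent bins counts discordant lines among those with parental
calls at both bins (HET is uninformative — at ~10⁻³ frequency modelling it
would add noise, not information), clamped to [0, 0.5). The selfing-RIL
correction r = R/(2(1−R)) inverts the panel-level R = 2r/(1+2r);
distances follow Kosambi by default (standard in rice mapping; Haldane by
flag). Marker order is fixed to physical order — de novo ordering is out
of scope and collinearity with the reference is an invariant, not a
result. Adjacent pairs with no informative line are bridged by estimating
against the last informative bin; the intervening bin is co-located with
its predecessor.

## QTL scans

P(TQ) along a 1-cM grid comes from a two-state forward–backward pass per
linkage group; transition probability over map distance d is the
panel-level R(d) = 2r/(1+2r) with r from the inverse map function.
Observed parental markers are delta emissions (P ∈ {0,1} at markers —
tested); co-located conflicting calls are dropped with a warning; a line
with no markers on a group stays at P = 0.5.

Haley–Knott is the primary engine: deterministic, testable against the
closed-form single-marker regression (equality to 1e−8 at markers on
fully observed panels is an acceptance invariant), and fast enough to
vectorize permutations as a single matrix product per trait. The
imputation method (forward-filter backward-sample paths; per-imputation
LODs combined as log₁₀ of the mean likelihood) is retained as a
cross-check because the emulated study used imputation; the two agree to
1e−8 under full observation and within ~0.5 LOD on sparse panels.

Permutation thresholds shuffle the trait across lines with genotypes
fixed; the threshold is the empirical (1−α) quantile (type-7
interpolation) of genome-wide max LOD, per trait, with no cross-trait
multiplicity correction (matching the per-trait α = 0.05 design).
Support intervals use the conventional 1.5-LOD drop for RILs; the
"10-cM window" of the emulated scan settings is read as the minimum peak
separation (the most plausible reading of a non-standard single-QTL scan
argument) and exposed as a flag. PVE = 100(1 − 10^(−2·LOD/n)) exactly
round-trips the LOD. The additive effect is the fitted slope at the peak;
positive means the TQ allele raises the trait. Missing trait values are
dropped per trait, never imputed. LS-mean composites fit the additive
two-way model trait = line + environment by least squares and average
model predictions over environment levels (equal to the plain per-line
mean for balanced data).

## PC traits

PCA is by eigendecomposition of the correlation matrix of z-scored
(mean 0, SD 1, ddof 1) element columns; rows with any missing element are
dropped with a logged count. Eigenvector sign is fixed so the
largest-|loading| element of each component loads positively — signs are
otherwise arbitrary and trait definitions must be stable across runs and
platforms. Across-environment PCA stacks rows in long format (one row per
line × environment, 16 columns) and z-scores over the stacked rows, so
between-environment mean structure stays in the decomposition; scores are
regrouped per environment into one trait vector per (set, environment,
component), labelled `<set>_<env>_aPC<k>`. The stacked-rows reading is
this package's interpretation — it is the only stacking consistent with
16 aPCs and per-environment aPC trait names. Top-5 loading lists sort by
|loading| descending with ties broken by the fixed element order.

## Co-localization

Two QTL records co-localize when their support intervals intersect as
closed intervals in cM on the same linkage group (physical kb intervals
are reporting-only). Same-element records merge transitively (union-find)
into unique QTLs keeping the union interval, the maximum LOD/PVE, and all
member environments; the operation is idempotent. QTL clusters are
connected components of the co-localization graph containing at least one
record of each class (elemental, PC, aPC). Concordance flags whether a
co-localized elemental record's element appears in the PC/aPC record's
top-5 list; per-class aggregates count a PC/aPC record as concordant if
any of its pairs is. Gene annotation, when supplied, is a plain interval
intersection with cluster physical spans — no ranking or effect calls.

## Problem sizes and tolerances

Validation experiments run at desk scale, chosen to mirror the emulated
population's structure: rice-like recombination density (~5 cM/Mb;
150 cM / 30 Mb chromosomes), panels of 100–500 lines, 2,000–5,000 SNPs
per chromosome, 200–300 permutations per trait in replicated experiments
(the single-trait default stays 1,000), and 50–100 replicates per power
experiment. The multivariate experiment plants one locus giving three
elements 5% PVE each over residual correlation 0.4 among them — a
moderate coupling between the greenhouse P–K–Mg (~0.4) and hydroponic
Ca–Sr (0.84–0.90) ranges — selected a priori by a power calculation for
n = 250. Numerical tolerances: exact identities (PVE↔LOD, RIL-correction
round trip, PCA reconstruction) at 1e−8…1e−12; oracle equivalence at
1e−8; Monte-Carlo assertions at 3–4 standard errors with the binomial SE
floor under the null when the empirical SE degenerates at zero counts.

## Known limitations

- Physical marker order is assumed correct; misassemblies would fold the
  map rather than be detected.
- The two-state chain ignores residual heterozygosity in genotype
  probabilities (HET markers are skipped); fine at ~10⁻³ HET frequency,
  wrong for early-generation panels.
- Single-QTL scans only: linked QTLs closer than the support-interval
  scale merge; no composite interval mapping, multiple-QTL models, or
  epistasis.
- Broad true signals can exceed the threshold at shoulder maxima more
  than the minimum peak separation from the summit; downstream merging by
  interval overlap absorbs these, but per-scan peak counts are inflated
  for very strong loci.
- Permutation thresholds assume exchangeable lines (no population
  structure beyond the cross).
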