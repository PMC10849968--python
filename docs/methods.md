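# Methods

## Scope and data model

`sleepscreen` operates on clustered droplet single-cell count data. The
in-memory container is an `AnnData` (cells × genes, sparse integer counts)
whose `obs` carries five per-cell fields: `cluster` (the cell population the
screens iterate over — clustering itself is an upstream step, not part of
this package), `condition` (experimental condition label), `zt` (Zeitgeber
time in hours, present for cells on the circadian sampling grid), `genotype`
and `run` (library batch). On disk a dataset is the sparse exchange layout
`matrix.mtx` (genes × cells) + `genes.tsv` + `barcodes.tsv` +
`cell_metadata.tsv`, with the condition registry in `design.json`.

A `ConditionDesign` attaches design information to conditions: ZT time,
membership in the pooled *sleep* or *wake* group, and an ordinal
`drive_rank` on the sleep-pressure axis. The drive template maps the k
ranked conditions to evenly spaced values i/(k−1) on [0, 1], in rank order
— 0 at the lowest sleep pressure (e.g. pharmacologically induced sleep) and
1 at the highest (prolonged sleep deprivation).

## Preprocessing

Cell QC removes, in this order of reported reason: cells of excluded
conditions (default `{ZT2-Wake}`: the early-day spontaneous-wake condition
has no matched counterpart and is dropped from all analyses), cells with
fewer than `min_genes_per_cell` = 200 detected genes, and cells whose
mitochondrial UMI fraction (genes prefixed `mt:`) exceeds a per-run
threshold (default 0.30, configurable per run because sequencing batches
differ in ambient stress). QC is idempotent.

Kept cells are scaled to 10,000 counts and log1p-transformed (`.X`); a
counts-per-million layer (`cpm`) is kept alongside because the cycling
prefilter is defined on CPM. Raw counts remain in `layers["counts"]`.

Genes with batch-associated expression are masked from all screens: per
cluster, a Kruskal–Wallis test of expression across runs, pooled over
clusters by Fisher's method, Bonferroni-corrected, masked at p < 0.001.
The conservative α and the rank-based test make the rule reproducible where
"obvious batch difference" would otherwise be a judgment call; an explicit
user exclude-list is honored regardless.

## Exact JTK cycling screen

**Reference.** For each lag L ∈ {0, 6, 12, 18} h the reference is
cos(2π(t−L)/24) evaluated at the sampled ZTs {2, 8, 14, 20}. Only the rank
ordering of the reference matters; all observations at one ZT share a
reference value, so the reference consists of tie groups. The lag grid
matches the 6-h sampling interval — the design cannot resolve finer phase.

**Statistic.** S = Σ_{i<j} sign(xᵢ−xⱼ)·sign(refᵢ−refⱼ); pairs tied in the
reference or in the data contribute 0. Reported `tau` is the tie-corrected
(tau-b) normalization of S.

**Exact null.** Under uniform permutation of distinct data values, S is an
affine map (S = 2J − M, M = Σ_{i<j} nᵢnⱼ) of the Jonckheere–Terpstra-type
cross-group concordance count J for the reference's tie groups sorted by
reference value. The number of arrangements with a given J is the
coefficient of q^J in the Gaussian multinomial, built exactly by q-Pascal
convolution of Gaussian binomials. The two-tailed p is P(|S_null| ≥ |S|).
This equals exhaustive permutation enumeration to machine precision
(verified on every input shape up to 8 observations); constant genes get
p = 1. The minimum p over lags is Bonferroni-corrected by the number of
lags (4), mirroring the lag-adjustment of the reference JTK implementation;
the best lag is the p-minimizing lag, ties broken toward the largest signed
S so that an anti-phase gene reports lag 12 rather than a negative score at
lag 0.

**Pseudo-replicates and consensus.** Within a cluster, cells at each ZT are
randomly partitioned into `n_pseudo_reps` = 3 groups; entries are mean
log-normalized expression, so the JTK input is a genes × (4 ZT × 3 rep)
matrix. A cluster is *eligible* only if every ZT has at least
`n_pseudo_reps` cells — the minimum for non-empty replicates; ineligible
clusters are reported as such, never silently dropped. Genes enter the test
only if their maximum per-ZT mean CPM is ≥ 0.8 and their max/min per-ZT CPM
ratio is ≥ 1.5 (pseudocount 1e-9; the same per-ZT CPM means define the
reported `amplitude_fold`). The allocation is repeated `n_allocations` = 3
times with seeds derived from the screen seed; BH correction runs across
tested genes within each allocation, and `is_cycler` requires BH p < 0.05
in *all* allocations. Zero-expression cells count as pseudo-replicate
members — dropout is data.

Note on guarantees: the triple consensus removes sensitivity to the random
allocation, not to cell-level sampling noise — all allocations re-partition
the same cells, so a null gene whose per-ZT cell means happen to both pass
the amplitude filter and order like a cosine will be significant in every
allocation. The procedure therefore controls FDR at the BH level (observed
false-discovery proportions in simulation are ~0.01), but cannot promise
literally zero false calls when many true cyclers make the BH step-up
permissive.

## Sleep-drive template screen

Per eligible cluster, per gene: Pearson r between the k per-condition mean
log-normalized expression values and the template, two-tailed p from the
t-distribution with k−2 df, BH across the cluster's testable genes.
Two-tailed because negative correlates (genes suppressed by sleep pressure)
are biologically meaningful. Constant genes are excluded from BH and carry
p = 1. Correlation is computed on condition *means* (k points), not on
cells, matching a per-cluster gene × condition matrix design; a cluster is
eligible only if every ranked condition has ≥ `min_cells_per_condition` = 3
cells (below that a mean is too unstable to rank), which mirrors how matrix
generation fails for sparse clusters. Missing conditions are missing — never
imputed as zero.

`correlate_overlap` reports the asymmetric row-normalized overlap
|A∩B|/|A| between per-cluster hit sets, for drive correlates, cyclers or
DEGs alike.

## Sleep/wake differential expression

Per cluster, two-tailed Wilcoxon rank-sum between pooled sleep and wake
cells on log-normalized expression; exact Mann–Whitney null when both
groups have ≤ 20 cells and the pooled sample is tie-free, tie-corrected
normal approximation otherwise. logFC = log₂((mean de-logged sleep
expression + 1e-9)/(mean de-logged wake + 1e-9)); `is_deg` requires BH
p < 0.05 and |logFC| > 0.5. Clusters with fewer than 3 cells in either
group are skipped with a reason.

Neurotransmitter assignment thresholds normalized expression of *VAChT*,
*Gad1* and *VGlut* at 0.5/0.4/0.5: exactly one above → that class, none →
`unknown`, several → `ambiguous` (the rule is silent on conflicts; we
refuse to force a class).

## Classifier transfer

Within a background of related subtypes, subtype markers (one-vs-rest
log₂FC above 3.5 for glia-like backgrounds, 2.0 for Kenyon-cell-like; both
configurable) are removed from the feature space so state models cannot key
on identity. Per subtype, a boosted additive classifier — gradient-boosted
depth-1 stumps (100 rounds, learning rate 0.1, deterministic given the
seed); each stump is a single-feature step function, so the ensemble is a
sum of per-gene shape functions with a scalar global importance per gene —
is trained on a stratified 75% split to predict sleep vs wake. The transfer
grid entry (train s, eval t) is the mean predicted probability of the true
label over subtype t's held-out 25%; the control grid repeats this after
permuting training labels within the subtype. Stratified splitting guards
against class-imbalance artifacts.

The distilled state gene list keeps genes whose state importance exceeds
mean + 2·sd (sample sd, n−1) over all features of their subtype, drops
genes that also exceed the same threshold in a control classifier trained
to predict subtype identity from the identical features, and intersects the
rest with the background's DEA-significant genes (BH p < 0.05).

## Integration and annotation

Process assignment: for each screen, threshold = mean over that screen's
eligible clusters of √(hit count); a cluster is assigned when its own
√(count) strictly exceeds the threshold (a cluster exactly at the threshold
is not assigned; the comparison is on the √ scale because that is the scale
the mean is taken on). Thresholds are always recomputed from the input
counts. The two eligibility universes may differ, so each threshold uses
its own; a cluster missing either screen gets an NA label.

NNLS annotation: marker z-score of gene g in cluster c is
(centroid − mean over clusters)/sd over clusters; the panel is the union of
each cluster's top 10 genes by z-score; the query is regressed on the
centroid columns by non-negative least squares; best match = largest
coefficient (coefficient ties broken by the smaller lone-centroid
residual); all-zero coefficients → unassigned. Queries missing more than
half the panel are rejected.

## Synthetic data generator

The generator emulates the study design the screens assume: conditions =
4 ZTs × {Sleep, Wake} plus seven drive-ranked conditions d0…d6 (the
registry is configurable; the default mirrors a multi-condition
sleep-pressure design without committing to condition names). Counts are
gamma–Poisson (negative binomial) with mean = baseline · cell library
factor · planted modulations and dispersion θ:

* library factors log-normal with σ = 0.3, normalized to mean 1 — a
  standard droplet library-size model;
* θ = 10 and baseline mean 0.5 raw counts/gene — typical of moderately
  expressed genes at usual droplet depth;
* cyclers: mean × (1 + a·cos(2π(zt−φ)/24)) with a = (fold−1)/(fold+1), so
  the peak/trough ratio equals the planted fold exactly; default fold 3;
* drive genes: mean × exp(slope · template value), i.e. log-linear in the
  0–1 template; default slope 1.0 (an e-fold from lowest to highest
  pressure);
* DEGs: mean × 2^logfc in the pooled sleep group; `shared_deg_genes=True`
  plants one common DEG set across clusters (for transfer experiments);
* markers: mean × marker_fold in the gene's own cluster;
* doublets: extra droplets summing two same-genotype cells, at a requested
  fraction whose default can follow the device doublet-rate formula
  0.008·(n_cells/1000)/num_lines; doublets are flagged in the truth object.

Planted sets are pairwise disjoint within a cluster and recorded in a
`SyntheticTruth`. Generation is byte-reproducible from the seed.

What the generator does **not** emulate: gene-to-gene baseline variation
(all genes share one baseline, so power estimates are per-effect-size, not
per-expression-stratum), gene–gene correlation, ambient RNA, batch effects
(runs are assigned but carry no effect unless a test constructs one), zero
inflation beyond NB, and cluster imbalance. Passing tests therefore show
the screens' calibration and power under clean NB noise at the stated
depths — not their behavior under real-data artifacts like batch structure
or expression-dependent dropout.

## Numerical choices and degenerate inputs

* BH via `statsmodels.stats.multitest.multipletests(method="fdr_bh")`,
  always within cluster across tested genes.
* Exact rank-sum only when tie-free and n ≤ 20 per group: exact enumeration
  with ties would require a different null, and at n > 20 the tie-corrected
  normal approximation is accurate.
* Constant genes: p = 1 everywhere (JTK, drive, DEA), excluded from BH in
  the drive screen, tau/r reported as 0/NaN.
* Reference cosine values are rounded to 12 decimals before tie detection
  so lag grids that produce coincident reference values collapse into the
  correct tie structure.
* Pseudocounts: 1e-9 on fold denominators and logFC ratios.
* All seeds: a screen's seed spawns per-allocation seeds via a generator;
  the acceptance script derives one sub-seed per stage from `--seed`.

## Simulation sizes used by tests and the acceptance script

Oracle sweep: 200 random 4×2 inputs against full 8! enumeration. Null
calibration: 1,000 genes, 50 cells/ZT (cycling) and 2,000 genes, 50
cells/condition (drive). Planted recovery: 100 cyclers among 1,000 genes at
300 cells/ZT; 100 drive genes among 1,000 at 100 cells/condition. Transfer:
3 subtypes × 800 cells, 600 genes, 20 private state genes each at
log₂FC 1.5. End-to-end integration: 3 clusters × 1,500 cells, 1,000 genes,
50 planted cyclers/drive genes per signal-bearing cluster. These sizes give
stable statistics while keeping a full run around a minute on one CPU.

## Known limitations

* Drive-screen sensitivity at slope 1.0 and 100 cells/condition sits near a
  BH step-up equilibrium (raw p of planted genes ≈ 1e-3 against a
  data-dependent cutoff of the same order), so measured sensitivity varies
  by a few points around 0.8 across seeds.
* The cycling consensus controls FDR, not the absolute false-call count
  (see the note above); with ~100 true cyclers among ~105 tested genes, an
  occasional single false consensus call is the expected cost of BH at
  α = 0.05.
* The exact JTK null assumes exchangeable distinct values; heavily tied
  inputs (many identical pseudo-replicate means) make the test conservative.
* Phase resolution is limited to the 6-h lag grid; no multi-period
  scanning or unevenly spaced designs.
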