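# Methods

`regucircuit` integrates four layers of evidence about transcriptional
regulation in a two-condition (control vs mutant), two-time-point count-based
study: differential gene expression, differential H3K27 acetylation over
promoter windows, differential acetylation over CRE (cAMP response element)
motif regions assigned to genes by TSS distance, and a general TF→target
regulatory network contextualized to each condition. On top of the
contextualized networks it infers *master regulators* (MRs) in the Davis &
Rebay sense: TFs inside a densely inter-regulating, physically interacting
set that sits upstream of the differentially expressed genes.

## Coordinates and interval algebra

All in-memory coordinates are 0-based, half-open (BED convention). GTF I/O
(1-based, closed) converts at the file boundary only. The promoter window of
a gene is the symmetric region `[tss − w, tss + w]` *including* the TSS
base, so an untruncated window is `2w + 1` bp (2001 bp at the default
`w = 1000`). The TSS is strand-aware: `start` on the plus strand, `end − 1`
on the minus strand. Windows are clipped at position 0 only; chromosome
lengths are optional, so no clipping is applied at the right end. Windows
are not strand-flipped — the window is symmetric, so strand only decides
which coordinate is the TSS.

`intersect_common` reproduces `bedtools intersect -u` (report-A) semantics:
an interval of A is reported once if any interval of B overlaps it by at
least `min_overlap` bp (default 1). Half-open abutting intervals do not
overlap. A `fragments` mode reports the overlap pieces instead, matching
the bedtools default output. The implementation is an interval tree; the
test suite checks it against an all-pairs oracle and against the bedtools
binary itself.

## Negative-binomial differential testing

One engine serves gene counts, promoter-window counts and CRE-region counts
(no genomics-specific branching). The model for feature *i*, sample *s*:

    y_is ~ NB(μ_is, α_i),    Var = μ + α μ²,
    log μ_is = x_s' β_i + log s_s

with `s_s` the median-of-ratios size factor (median taken in ratio space,
matching the literal definition) and `x_s` encoding condition, or condition
plus time in the additive two-factor design. The genotype effect is tested
with a Wald statistic on the condition coefficient (standard-normal
reference), and BH adjustment is applied across tested features. Features
with all-zero counts are excluded from testing and reported `ns` with
p = 1; features with an all-zero group report a pseudo-count (+0.5)
`log2fc` because the GLM coefficient sits at the separation boundary.

**Dispersion.** The per-feature pooled within-group method-of-moments
estimate `α̂ = (s² − μ̄)/μ̄²` (exposed as `estimate_dispersion`) is far too
noisy at 3 replicates per group, and an under-estimate inflates the Wald
statistic. The working dispersion therefore combines it with a
mean-dispersion trend `α(μ) = a0 + a1/μ` fitted across features by trimmed
weighted least squares *in the response space* `s² − μ̄ ≈ a0 μ̄² + a1 μ̄`
(weights from a pilot NB variance; fitting in response space avoids the
severe bias of regressing per-feature `α̂` values, which divides by a noisy
`μ̄²`). Each feature then uses the trend value at its mean unless its own
estimate exceeds twice the trend, in which case the higher per-feature
value is kept — a deliberately conservative escape for genuinely
over-dispersed features. This is a method-of-moments analogue of the
classic shared-dispersion designs in the established count-model packages,
not an empirical-Bayes posterior shrinkage. Measured on NB data (2000
features, dispersion 0.1, 3 vs 3): null fraction of raw p < 0.05 around
0.04–0.05, sensitivity for 4-fold effects at BH 0.05 around 0.83–0.93, and
genotype-null level in the two-factor design around 0.03–0.06.

The GLM is fitted by Fisher scoring vectorized across all features
(dampened steps, linear predictor clipped to ±40); per-feature agreement
with an independent statsmodels NB GLM fit is asserted in the tests to
1e-5 on coefficients.

**Conventions.** Expression analyses call significance on BH-adjusted
p-values at α = 0.05; acetylation analyses (promoter and CRE counts) use
raw p < 0.05, both switchable via `DiffConfig.use_adjusted`. No independent
filtering, no outlier replacement, no lfc shrinkage; exact concordance with
any external differential-expression tool is a non-goal.

## CRE assignment and location labels

A motif occurrence is assigned to *every* gene on its chromosome whose TSS
lies within ±3 kb (inclusive) of the occurrence midpoint
(`floor((start+end)/2)`); `--nearest-only` restricts to the closest gene.
Distance is unsigned (no upstream/downstream asymmetry) and motif strand is
carried but ignored. Region location labels use the precedence
promoter > gene body > downstream > intergenic, evaluated at the region
midpoint; "downstream" means within 1000 bp past the strand-appropriate 3'
end. The precedence makes the categories disjoint, and midpoint membership
prevents a straddling region from being counted twice. Ties inside a
category go to the nearest TSS, then lexicographic gene id.

When a table of region-level differential results is merged onto the
assignments, every (region, gene) row keeps its own status — a gene with
one up- and one down-acetylated CRE keeps both rows. The single-valued
network node attribute `cre_acetyl` summarizes a gene by its most
significant signed region (smallest p, ties by region id).

## Network contextualization and comparison

The general network is the union of edge-list files (duplicate edges
merged; conflicting modes become `unknown`; sources concatenated).
Contextualization keeps edge (tf → target) iff the TF is expressed;
targets are kept regardless of their own expression, and the node set is
exactly the endpoints of retained edges (no isolated nodes). "Expressed"
means a mean normalized count of at least 10 in the condition's samples
(size factors estimated on the full matrix so both conditions share a
scale); the cutoff is a config value, logged with the run, because no
principled universal threshold exists for this design. Network comparison
reports totals and one-sided unique counts for nodes, TFs (nodes with
outgoing edges) and edges, computed by set algebra on a common union.

## Master-regulator inference

1. **Upstream neighborhood.** From the DE genes, walk regulatory edges in
   reverse for two steps (first and second upstream regulators) and take
   the subgraph *induced* by the reached nodes, so lateral edges among
   regulators are retained.
2. **Densest core.** On the largest weakly connected component, repeatedly
   delete the node with the lowest out-degree (ties: lowest in-degree, then
   lexicographic id), one node per iteration. Pruning stops when (a) every
   remaining node has the same out-degree — there is then no node with a
   *lower* out-degree to delete, the natural terminal state on a uniformly
   dense core; (b) the deletion would disconnect or empty the remainder
   (the offending deletion is not committed); or (c) the remainder would
   drop below `min_core_size` (default 2, preventing degenerate singleton
   cores). The ordered deletion trace (node, out-degree at deletion) is
   part of the output and is fully deterministic.
3. **Validation.** Candidates are the surviving nodes that are TFs in the
   general network. Each candidate's evidence is (a) the other candidates
   with an edge into it and (b) the other candidates it physically
   interacts with. The default rule `both` requires both kinds of
   evidence — a pair of candidates that interact physically but do not
   regulate each other is *not* validated; `either` and `regulation_only`
   are provided because the definition in the source literature is
   ambiguous between the conjunction and the disjunction.

Connectivity always means weak connectivity of the directed graph.
Condition contrasts (shared / control-only / mutant-only MRs) are plain set
algebra on the validated sets of two runs.

## Synthetic studies

The generator emulates the data shapes above with planted, recorded truth:

* **Genome**: 300 genes (30 of them TF genes) placed without overlap on two
  2.5-Mb chromosomes, random strands, 2–8 kb lengths and gaps.
* **Motifs**: 30% of genes get a CRE occurrence planted uniformly within
  ±3 kb of the TSS (recorded in the truth map); background occurrences are
  Poisson-uniform at 0.02/kb.
* **Counts**: gamma-Poisson with lognormal baselines (log2 mean 6.64 ≈ 100
  reads, sd 1), dispersion 0.1, lognormal(0, 0.2) library-size multipliers;
  3 replicates per condition × time. Planted effects: 4-fold (|log2fc| = 2)
  expression changes in 10% of genes, 2^1.5-fold acetylation changes in 15%
  of promoters and in half of the planted CRE regions. Effects are scaled
  0.5× at the early time point and 1× at the late one — a qualitative
  early-vs-late disease course; MR inference runs at the late time point.
  TF genes' baselines are floored at 50 so regulator expression does not
  accidentally censor the network (planted-core recovery is then a test of
  the inference, not of baseline sampling).
* **Network**: a planted core of 6 TFs, fully mutually regulating at the
  default `core_density = 1.0`, each fanning out to 20 targets from a
  shared pool; the planted DE genes are drawn from the covered core
  targets, so the upstream neighborhood of the DE genes contains the whole
  core. Peripheral TFs are regulated by a core TF and regulate ≤3 targets,
  which keeps them weakly attached and cleanly prunable. Physical
  interactions are planted between all core pairs.

At `core_density = 1.0` the pruning terminates exactly at the planted core
(uniform out-degree plateau); at densities below 1 the in-core out-degrees
are unequal and exact termination at the core is not guaranteed — the
recovery claim is specific to the fully dense core. Everything is driven by
one seeded `numpy` generator; a fixed seed yields byte-identical output
files, including the MR deletion traces.

**What passing tests do and do not show.** The generator produces clean NB
counts with a correct mean-variance law, independent features, no batch
effects, no GC/length biases, no mapping artifacts, and a planted network
that is exactly recoverable by construction. Passing the calibration and
recovery tests therefore validates the algorithms and their implementation,
not their behavior on real sequencing data, where dispersion varies per
gene, networks are incomplete and noisy, and "expressed" is a modelling
choice.

## Numerical choices and degenerate inputs

* IRLS: ≤80 iterations, step clip ±3, convergence at max |Δβ| < 1e-10,
  ridge 1e-10 on the information matrix; separation handled by the η clip.
* Dispersion floor 1e-8 (Poisson limit); trend degenerates to zero when
  fewer than 10 informative features exist.
* Size factors require at least one feature positive in all samples and
  raise otherwise (a pseudo-reference fallback is deliberately left to the
  caller).
* Empty promoter-window collections refuse to write; empty networks are
  legal; an empty expressed set is an error (it silently voids the
  contextualization contract otherwise).
* All set-valued choices (tie-breaks, file ordering) are lexicographic, so
  every output is reproducible byte-for-byte.

## Problem sizes in the standard checks

The bundled acceptance script uses 100 random instances per interval/
network operation, 2000-feature count matrices for calibration (3 vs 3
samples; 2 × 2 × 3 for the two-factor design), 200-gene annotations for the
promoter-window contract, and 100 seeded pipeline runs (300 genes, 30 TFs
each) for planted-core recovery — sizes at which all checks complete in a
few seconds while keeping Monte-Carlo error well inside the stated bands.
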