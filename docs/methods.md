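# Methods

## Conservation strata on a chronogram

A chronogram is a rooted ultrametric tree whose leaves are genome
identifiers; node ages in MYA are derived from branch lengths (root age =
root-to-leaf path length, node age = root age minus depth). Trees whose
leaf depths differ from the root age by more than `1e-6 × root_age` are
rejected with the offending leaf named, never repaired: a silently
"fixed" chronogram would shift stratum boundaries.

A stratum scheme is an ordered list of labelled rules over presence
patterns (presence = copy count ≥ 1; higher copy numbers never affect the
stratum, only the single/multi copy class). Two rule families exist:

* **MRCA rules**, anchored at nodes on the root-to-focal path, for the
  sequential host-style subsets. When every focal genome is present, the
  pattern is assigned to the *ancestral-most anchor at or below the MRCA
  of all genomes carrying the family*. This is the Dollo reading: the
  family originated once at its MRCA, and a patchy pattern whose MRCA
  falls between two anchors is rounded down to the next younger anchor,
  because only that clade is fully compatible with the observed sharing.
  Schemes are validated at load time: anchors must lie on the
  root-to-focal path, be listed oldest to youngest, and the youngest
  anchor must be the focal MRCA — this guarantees every focal-complete
  pattern finds an anchor.
* **Predicate rules** (`all_of`, `any_group_all`, `count_range`,
  `remainder`), applied first-match-wins, for accessory subsets and for
  bacterial-style schemes defined purely by sharing counts over the focal
  strains. Every scheme must end in a `remainder` rule, making the
  assignment total by construction (checked at load, never at assignment).

Scheme files are explicit YAML rather than inferred from the tree: which
nodes carry strata, and whether an accessory subset requires all
accessions of exactly one species, are study-design choices that should be
visible and editable, not guessed.

Replicon consistency of a core-gene set is the fraction of orthogroups
whose member genes, across all genomes, share one replicon class
(chromosome, chromid, symbiosis plasmid, accessory plasmid). Orthogroups
with a single gene are trivially consistent.

## Differential expression

The count model is a two-group negative binomial with gene dispersion
`α` (variance `μ + αμ²`). The caller is deliberately minimal and fully
transparent:

* **Size factors** by median-of-ratios against a geometric-mean
  pseudo-reference built from genes positive in every sample. Factors are
  not renormalized; the identifiable quantity is the factor *ratio* (the
  reference absorbs a factor `c^(1/n)` when one sample is scaled by `c`,
  so only ratios shift by exactly `c`). The matching generator convention
  normalizes true size factors to geometric mean 1.
* **Dispersion** by method of moments on normalized counts, pooled within
  groups: `α̂ = max(1e-8, (s² − ȳ)/ȳ²)` with `ȳ` the grand mean and `s²`
  the pooled within-group variance (denominator `n − G`). No shrinkage,
  no trend fitting: at the replicate numbers this package targets (n ≥ 6
  per group for inference-grade runs) the moment estimator is adequate,
  and its bias shows up honestly in the calibration tests rather than
  being hidden by an empirical prior.
* **Wald test** on `ln μ̂_t − ln μ̂_r` with delta-method standard error
  `SE² = Σ_groups (1/n_g)(1/μ̂_g + α̂)`; two-sided normal p. The reported
  fold change is `log2((μ̂_t + c)/(μ̂_r + c))` with pseudocount `c = 0.5`
  applied only when either group mean is below `c`, so exact integer
  ratios stay exact; genes all-zero in both groups get `p = 1` and are
  never dropped silently. Simulation shows mild anticonservatism under
  the null (rejection ≈ 0.06–0.07 at nominal 0.05 with 10 vs 10
  replicates), the known price of plugging a moment dispersion into a
  Wald statistic; the DEG rule's fold-change cutoff keeps the false DEG
  rate at effectively zero.
* **BH adjustment** (step-up, capped at 1) within one organism and one
  comparison. **DEG rule**: `|log2FC| > 1` strictly and `q < 0.05`
  strictly; a gene at exactly log2FC = 1 is not a DEG.

TPM and RPKM follow their standard definitions; TPM columns sum to 1e6
for any non-degenerate sample, and all-zero samples produce zero columns
with a warning instead of an error. Stratum expression summaries average
replicates per treatment first, then report the mean TPM per (stratum,
copy class, treatment) with a 95% percentile bootstrap CI over genes
(default 1,000 resamples, seeded); the bootstrap was chosen because gene
TPM distributions are heavy-tailed and a normal-theory CI would be
anti-conservative. Empty strata yield rows with n = 0 and missing means.

## Enrichment and clustering

Fisher exact p-values are two-sided under the "probability at most
observed" rule (relative tie tolerance 1e-7, the convention of mainstream
statistical environments); the odds ratio is the sample odds ratio
`ad/bc` with `+∞` allowed. Stratum and replicon-stratified enrichment is
called at raw per-unit alpha = 0.05 — deliberately uncorrected, matching
the per-subset convention of the figure style this mirrors — while
pathway enrichment applies BH across pathways within a comparison and
calls at `q < 0.05`; the asymmetry is intentional. A "+" call requires
both significance and odds ratio > 1, "−" requires odds ratio < 1; an
odds ratio of exactly 1 is never called. The default background is all
annotated genes of the organism, not expressed-only genes (a switch at
the call site allows the latter). Replicon-stratified tests restrict the
background to the genes of one replicon class, so a class with a single
stratum has no contrast and returns only `ns`.

Log-ratio profiles `log2((TPM̄_t + c)/(TPM̄_ref + c))` (replicate-averaged,
pseudocount rule as above) are clustered agglomeratively with average
linkage on Euclidean distances — the distance is configurable in the API;
Euclidean is the default because the profiles are already on a symmetric
log scale. Exact ties merge by smallest original row index; merge heights
are nondecreasing by construction. The dendrogram is exported as Newick
with branch lengths equal to height differences.

## Synthetic data generator

The generator emulates a dual pantranscriptomics study design: a dated
phylogeny, gene families gained once (Dollo) at a weighted-random tree
node, lost along descendant branches with probability `loss_prob` per
branch (losing a branch prunes its clade), and expanded to two copies
with probability `multi_copy_prob`; a multipartite replicon map in which
each orthogroup's genes share one class with probability
`replicon_consistency`, otherwise one member gene moves class; and NB
counts `k_gs ~ NB(sf_s · μ_g · 2^(x_s β_g), α)` with log-uniform size
factors normalized to geometric mean 1, log-uniform baselines, and
effects `β_g = ±de_log2fc` planted only in genes of the target stratum,
signs alternating deterministically so directional tests have balanced
truth. Dispersion below 1e-12 switches to exact Poisson sampling.

Defaults are the study conditions the generator emulates: root age
106 MYA (the divergence of the soybean- and Medicago-associated symbiont
lineages), two samples per group (two independent nodule sample sets),
dispersion 0.1 (typical bulk RNA-seq), planted effect 2 (comfortably
above the DEG cutoff of 1), and replicon consistency 0.834 (the measured
consistent fraction of core genes in multipartite symbiont genomes).
Orthogroups that lose every leaf are resampled up to 100 times, then
dropped with a warning; truth records only emitted orthogroups. One seed
drives one generator stream consumed in fixed order (tree → orthogroups →
replicons → lengths → counts), so identical configurations are
bit-identical; partial reruns are not reproducible by design.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: no sequence-level simulation (no
read mapping noise, multi-mapping or length bias beyond the declared gene
lengths), no horizontal gene transfer (gain is strictly single-origin),
no per-gene dispersion trends, batch effects or outlier samples, no
correlation between expression and gene age, and orthogroup inference is
assumed perfect. Results on real data additionally depend on the
upstream orthogrouping and counting being sound.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale sizes chosen to make every
statistical assertion decisive without waste: 255-pattern exhaustive
scheme sweeps on 8-leaf fixtures, 1,000 orthogroups for Dollo recovery,
all 20,474 2×2 tables with total ≤ 24 against exact enumeration, 10,000
genes at 10 vs 10 replicates for null calibration, 100 seeded end-to-end
runs of 150 orthogroups at 6 vs 6 for planted-truth recovery, and 1,000
label permutations for enrichment calibration. Monte-Carlo assertions use
99% binomial/variance bands at the stated n. Ultrametricity tolerance is
relative (1e-6 × root age); BH uses a stable mergesort so ties preserve
input order; the Wald p is clipped to [0, 1] against rounding.

## Known limitations

* The MoM-dispersion Wald test is mildly anticonservative at small n and
  offers no shrinkage; it is a transparent reference implementation, not
  a replacement for mature DE frameworks on marginal designs.
* Fold changes are unshrunken; low-count genes can show large but noisy
  log2FC (mitigated by the pseudocount and the q threshold).
* Stratum assignment is Dollo-only: no gene-tree reconciliation, no
  transfer-aware reconstruction, so convergent losses can age a family
  too young.
* The per-stratum enrichment deliberately applies no multiplicity
  correction across strata; with many strata, occasional false "+"/"−"
  calls at alpha = 0.05 are expected and quantified by the permutation
  calibration.
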