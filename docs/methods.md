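# Methods

`clonetrace` reconstructs the clonal evolution of a tumour between two
timepoints — diagnosis and relapse — from deep-sequencing read counts of
somatic variants, with a matched remission sample used as a contamination
control. This note documents the models, the algorithmic and numerical
choices, and what the synthetic-data experiments do and do not demonstrate.

## Input model

Each somatic variant *i* carries a mutant read count and a total depth
(X_i, N_i) at each timepoint. The mutant allele fraction (MAF) is
p̂_i = X_i / N_i. For a heterozygous mutation on a diploid, copy-neutral
locus in a sample of tumour purity ρ, a mutation carried by a fraction *f*
of tumour cells has expected MAF ρ·f/2; variants on non-diploid loci are
retained in the tables but excluded from mixture fitting and purity
estimation, because their MAF is confounded by copy number.

A variant is called **present** at a timepoint when its MAF is at least
0.01 and at least 3 non-duplicate mutant reads support it; at the depths
this pipeline targets (combined exome + capture, ~880-fold), 0.01 is the
MAF at which detection power reaches ~99%. Presence at the two tumour
timepoints assigns each variant to one of three categories — diagnosis-
specific, relapse-specific, shared — and a variant absent from both
tumours is flagged and excluded. When the same variant was sequenced on
two platforms, counts are summed before the presence call.

## Binomial mixture clustering

Variants of one category are clustered by a finite mixture of binomials:
X_i ~ Σ_k λ_k·Binom(N_i, p_k), with cluster centres p_k and mixing
weights λ_k. Modelling the counts rather than the MAF values makes the
clustering coverage-aware: a 0.01-MAF cluster at 800-fold depth is
resolvable because each variant's likelihood is sharp in proportion to its
depth. Shared variants use the multiplicative variant of the model: each
cluster has an independent diagnosis centre and relapse centre and a
variant's likelihood is the product of the two binomial terms, so clusters
that coincide at one timepoint (e.g. two clusters clonal at relapse) are
separated by the other.

Fitting is EM. The E-step computes responsibilities Z_ik; the M-step sets
λ_k to the mean responsibility and p_k to the responsibility-weighted
pooled MAF Σ_i Z_ik X_i / Σ_i Z_ik N_i (per timepoint for the shared
model). The K=1 M-step therefore reproduces the pooled MAF exactly, which
the tests use as a closed form.

Numerical choices:

* centres are initialised at the quantiles of the raw MAFs; 10 restarts
  (the first unjittered, the rest with N(0, 0.03) jitter) are run as one
  vectorised batch and the best-likelihood restart kept;
* convergence at |Δ log L| < 1e-8 or 500 iterations; centres clamped to
  [1e-6, 1−1e-6] to avoid degenerate likelihoods; the log-likelihood
  trace of the winning restart is stored and asserted non-decreasing;
* clusters are reported in descending order of (diagnosis) centre; hard
  assignments are argmax responsibilities with ties to the smaller index;
* the binomial coefficient term is precomputed once per dataset, so EM
  iterations cost one (restarts × variants × K) broadcast.

K is selected by AIC = 2k − 2 ln L over K = 1..K_max (default 6), ties
toward smaller K. The free-parameter counts are k = 2K−1 for the
timepoint-specific model (K centres, K−1 weights) and k = 3K−1 for the
shared model (2K centres, K−1 weights) — the standard mixture counts for
the parameters these models actually have.

**Known limitation.** AIC is mildly liberal for mixture order: on exact
three-component simulations (centres 0.45/0.20/0.05, depth 800, 100
variants) it admits a spurious extra component — typically of weight
~0.05, gaining 2–4 log-likelihood units against the 2-unit penalty — in
roughly 10% of replicates. Centre estimates are unaffected (RMSE ~0.002).
The selection criterion is kept as stated rather than patched with
pruning rules; downstream consequences are quantified in the recovery
experiments below.

## Purity estimation

For one timepoint, the diploid variants present in that sample are
clustered with the specific model and purity is estimated as twice the
highest cluster centre among centres ≤ 0.5 (capped at 1): the most
ancestral detectable cluster is heterozygous in every tumour cell, so its
centre is ρ/2. Because a clonal cluster in a pure sample centres at
exactly 0.5 and drifts above it by sampling noise, eligibility extends to
0.52 (about three binomial standard errors at these depths); if every
centre exceeds that, the loci are inconsistent with diploid heterozygous
mutations and the estimator raises instead of guessing. Purity clustering
reuses the binomial mixture rather than a Gaussian model-based clustering
so that depth information is used consistently throughout.

## Lineage reconstruction

Cluster centres are converted to cell fractions f = min(1, 2·MAF/ρ);
fractions more than 10% above 1 are flagged super-clonal before capping.
Trees are then built greedily under the pigeonhole sum rule (children's
total fractions cannot exceed their parent's):

1. **Shared clusters first**, in descending diagnosis fraction. The
   largest is the founder. Each subsequent cluster attaches to the clone
   with the largest unallocated (residual) diagnosis population, which is
   then reduced by the newcomer's fraction. Because a shared cluster's
   clone persists to relapse, a candidate parent must also have room for
   it at relapse (residual ≥ fraction − ε there too); without this joint
   constraint a falling clone (e.g. 75% → 8% of cells) would wrongly
   adopt a rising sibling (12.5% → 92%) and violate the sum rule at
   relapse.
2. **Diagnosis-specific clusters** by the same rule on diagnosis
   residuals.
3. **Relapse side**: persisting clones keep the nesting established at
   diagnosis — they are the same clones — with residuals recomputed from
   relapse fractions; relapse-specific clusters then attach greedily on
   those residuals.

Residuals may dip to −ε (default ε = 0.05 cell-fraction units, matching
sampling noise on cluster centres at these depths); a cluster that no
clone can accommodate within ε raises an explicit infeasibility error.
Exact residual ties go to the deeper clone — equal-fraction clonal
clusters thereby nest into chains, the standard reading of a clonal
sweep — then to the lexicographically smaller clone id, so identical
inputs always produce identical trees. A clone whose diagnosis residual
falls below the 1% detection level while having children is marked
`inferred`: an ancestral population whose pure form is no longer
observable (the grey-box founder situation where a diagnosis-specific
cluster and a shared cluster are both clonal).

**Founder mapping.** A persisting clone is a relapse-founder anchor when
it has a relapse-specific child, or when its relapse residual exceeds the
noise tolerance ε (residuals below ε at clonal levels are centre noise,
not evidence of a surviving subpopulation). One diagnosis→relapse edge is
emitted per anchor — to its largest relapse-specific child, or to itself
when it persists without new mutations. Two or more anchors constitute a
dual-lineage relapse. If no relapse clone shares any cluster with the
diagnosis tree, the samples lack a common ancestral clone and the mapping
raises.

**Ambiguity resolution.** During construction, every cluster with more
than one admissible parent is recorded with its alternatives. Two
biological rules then filter the candidates: (1) mutual exclusivity — a
parent is rejected if its lineage path would stack two activating driver
mutations of the same gene/pathway (driver keys default to the clusters'
annotated pathways); (2) spectrum consistency — among survivors, parents
whose own cluster's transition/transversion spectrum is not significantly
different from the child's (two-sided Fisher exact test, P ≥ 0.05) are
preferred, which places hypermutated clusters under hypermutated parents.
A unique survivor is adopted and the subtree re-parented (residuals and
carried cluster sets recomputed from scratch); otherwise the default
stands and the alternatives remain annotated — ambiguity is reported,
never silently resolved. Re-parenting uses the candidates recorded at
attachment time and does not revisit later placements; the same
first-order correction a manual review would apply.

**SV/CNV placement** is qualitative (read-depth and array resolution do
not support fractional estimates): events detected at both timepoints are
ancestral by default, with two exceptions — capture-positive but
WGS-negative at diagnosis means a diagnosis subclone, and a relapse-
specific automated call overridden by manual array review is likewise
diagnosis-subclonal. One-timepoint events are timepoint-specific; the
`dx_specific` label extends the placement vocabulary because an event
seen only at diagnosis fits none of the other three. No detection
anywhere is contradictory input and raises.

## Statistics

* **Detection power**: P(X ≥ 3 | Binom(N, maf)) — the probability that a
  mutation at a given MAF yields at least the minimum read support. At
  MAF 0.01: 28.8% at 187-fold, 97.0% at 696-fold, 99.3% at 883-fold.
* **Misclassification probability** for a site with zero mutant reads
  that could belong to a clone at MAF α: P(X=0) = (1−α)^N, computed as
  exp(N·log1p(−α)). (At N = 520, α = 0.01 this is 0.0054; a printed
  value of 0.003 for that configuration is consistent with per-site
  coverages above the 520 minimum.)
* **Compound distinctness**: with x of n sites individually unlikely
  (p ≤ 0.05, inclusive), the compound P value is the inclusive upper
  tail P(X ≥ x | Binom(n, 0.05)); x = 0 gives 1. Binomial tails come
  from scipy's survival functions, stable to P ~ 1e-300. P(X ≥ 14 | 38)
  ≈ 1.9e-9; 0.05^5 ≈ 3.1e-7.
* **Spectrum comparison**: transitions are A↔G and C↔T; two clusters'
  (transition, transversion) tables are compared by a two-sided Fisher
  exact test, the same test the ambiguity rule 2 consumes.

## Synthetic data

The generator draws a ground-truth architecture and then the read counts
the analysis would observe:

* a clonal founder with `n_clones_dx − 1` sibling subclones; sibling
  fractions are drawn descending under a budget so that all cluster MAF
  centres are separated by ≥ 0.05 (configurable) and nest under the
  founder; the first sibling is predominant (~55–75% of cells), the last
  ≤ 20%;
* exactly one diagnosis clone survives (by default the smallest sibling,
  emulating a minor rising clone of 2–20% of cells); its cluster and the
  founder's are the shared clusters; the relapse is a nested chain of
  `n_clones_rel` new clones under it;
* per cluster, 8–20 mutations (hypermutator mode: 150–300 mutations in
  the relapse founder cluster with a 0.99 transition fraction against
  0.77 otherwise);
* depths are Poisson with mean 883 (the combined two-platform depth);
  mutant reads are Binomial(N, ρ·f/2) with ρ = 0.9 per timepoint by
  default; remission counts are 0 unless a residual-disease MAF is set
  (real remission samples showed traces at MAF 0.001–0.005).

Infeasible requests (fractions that cannot nest at the requested
separation) raise rather than silently bending the configuration.

What the simulator does **not** emulate: sequencing error and alignment
artefacts (counts are exact binomial draws — the evidence-screening
module is exercised on constructed read fixtures instead), copy-number
changes and non-diploid MAF distortion, overdispersion beyond
Poisson-binomial, multi-clone relapse seeding in a single configuration
(dual lineage is tested through explicit cluster fixtures), and clonal
structure more general than founder + siblings + relapse chain. Passing
recovery tests therefore demonstrate correctness of the inference under
its own model assumptions, not robustness to artefacts of real data.

## Read-evidence screening

For low-MAF sites, per-read evidence is screened before counting:
duplicates are dropped; each read is locally realigned
(Smith–Waterman/Gotoh affine scoring: match +2, mismatch −1, gap open
−3, gap extend −1 — chosen to prefer a single gap over scattered
mismatches, the artefact mode the filter targets) against the reference
window, and if any best-scoring alignment restores the reference base at
the site (or leaves it uncovered) the read is wild-type; reads whose
variant base is the strict minimum of base quality in a 5-bp window fail
(ties pass — flat-quality reads carry no valley signal; the window
truncates at read ends); and a site whose surviving evidence lies
entirely in the overlapping portion of read pairs fails as a whole.
Presence requires 3 surviving reads. The alignment itself is Biopython's
`PairwiseAligner` in local mode; the test suite cross-checks it against
an independent Gotoh dynamic program with full optimal-traceback
enumeration on fixtures up to 30 bp.

## Pipeline and reproducibility

`run_pipeline` chains the stages — simulate/ingest, presence calls,
per-timepoint purity, per-category mixture fits with AIC curves, cell
fractions, lineage with founder mapping and ambiguity resolution,
distinctness tests (each relapse founder cluster against the minor shared
cluster of its surviving diagnosis clone, over its zero-count diagnosis
sites), and spectrum tables. Every stochastic step receives a seed
derived from the run seed, and every stage artifact is a plain TSV/JSON
file (tree additionally as Graphviz DOT and a fish-plot-style TSV), so a
run is bit-reproducible from its emitted `config.yaml` and any stage can
be inspected in isolation.

## Recovery experiments (problem sizes)

The validation experiments use 100-seed batches at depth 800 with 100
variants (mixture recovery) or 5-clone architectures with 8–12 mutations
per cluster (end-to-end recovery) — sizes at which the binomial centres
are sharp and the experiments complete in a few minutes on one CPU.
Measured behaviour: centre RMSE ≈ 0.002; AIC selects the true K in ~90%
of seeds (the liberality discussed above); the full
simulate→cluster→lineage chain recovers the exact topology and founder
edge in ~89% of seeds, with essentially every failure caused by a
spurious AIC component adding a phantom clone rather than by misplaced
true clusters.
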