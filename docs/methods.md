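# Methods

`metaclone` analyses paired tumor lesions (a primary colorectal tumor and its
liver metastasis, though nothing is colorectal-specific) from somatic variant
calls, allele-specific copy-number segments, HLA allele coverage and RNA read
counts. This note records the models, the defaults and why, and what the
synthetic cohorts do and do not establish.

## Cancer cell fraction and clonality

For a mutation with `t_alt` of `t_depth` reads in a sample of purity `p`,
local tumor copy number `q = cn_major + cn_minor`, normal copy number 2 and
multiplicity `m` (mutated copies per tumor cell), the expected variant allele
fraction at cancer cell fraction `f` is

    E[VAF] = f * p * m / (p * q + (1 - p) * 2).

Multiplicity is the nearest integer (half-up) to the value that makes the
observed VAF consistent with `f = 1`, clamped to `[1, q]`. The posterior over
`f` is computed on a fixed grid {0.00, 0.01, ..., 1.00} with a
Binomial(`t_alt` | `t_depth`, E[VAF]) likelihood and a uniform prior. The
0.01 step is below the read-count resolution at the ~150x depths this is
meant for. Reported per mutation:

* `ccf_hat` — the posterior mode;
* `ccf_ci95_low/high` — the 95% **highest-posterior-density** interval.
  An equal-tailed interval was rejected deliberately: CCF is bounded at 1 and
  truly clonal mutations live at that boundary, where an equal-tailed upper
  quantile sits below 1 almost surely and the interval's frequentist coverage
  collapses (measured ~82% at true CCF 1.0 versus ~95% for the HPD form).
  Away from the boundary the two coincide.
* `pr_clonal` — posterior mass at CCF >= 0.5, i.e. the posterior odds that
  the mutation is nearer fully clonal than absent. A stricter mass cut (e.g.
  0.9) makes this conjunct, rather than the credible-interval conjunct, the
  binding constraint of the clonal call and caps true-clonal sensitivity
  around 65% at 150x / purity 0.6 — a short calculation shows the truncated
  posterior holds < 0.5 mass above 0.9 whenever the alt count falls ~half a
  standard deviation below its expectation. The cut is a config knob
  (`clonal_mass_cut`).

A mutation is **clonal** iff `ccf_ci95_high >= 0.95` (on the capped [0, 1]
scale) **and** `pr_clonal > pr_subclonal`; otherwise subclonal. Samples with
purity strictly below 0.20 are excluded before any estimation. Normal copy
number is fixed at 2; sex chromosomes are out of scope.

## Evolution patterns

Variants are matched across the lesion pair by `chrom:pos:ref:alt` (gene
symbols are ignored for matching, so annotation differences cannot split a
variant). Each variant's per-lesion status — absent (0), subclonal (S) or
clonal (C) — yields one of eight pattern labels `<primary>-<metastasis>`
(C-C, C-S, S-C, S-S, 0-C, 0-S, C-0, S-0). Within a lesion, genes are ranked
by descending median CCF as a proxy for event timing (high median = early);
ties break lexicographically. A gene is a recurrent carrier of a pattern
when it shows that pattern in >= 2 patients (configurable).

Gene-list enrichment against user-supplied gene sets uses the one-sided
hypergeometric tail. The background universe is caller-supplied; no pathway
database is shipped.

## Arm-level copy-number events

Per chromosome arm (packaged hg19 boundaries), the segment log2 ratios are
averaged weighted by overlap length; the arm is amplified at mean log2 >=
+0.2, deleted at <= -0.2, else neutral. The thresholds are a common WES
convention, exposed in config. The fraction of tumor cells carrying an arm
event assumes one event of integer copy change `d` on a diploid background:

    ratio = (2 + p * f * d) / 2   =>   f = (2^(log2 + 1) - 2) / (p * d),

clamped to [0, 1]; arms whose two lesions disagree in direction are flagged
`discordant` rather than forced into a pattern. The event is clonal at
`f >= 0.9` (the same mass-cut convention as SNVs; a point estimate has no
credible interval to threshold). Note the resolution limit this implies: at
purity 0.6 a single-copy gain needs `f` >= ~0.56 before the arm mean reaches
+0.2, so lower-fraction subclonal arm events are genuinely invisible at
these thresholds. Multi-event arms are not decomposed.

## Phylogeny

Per patient, variants x samples presence/absence (with the matched normal as
an all-zero outgroup) form a binary character matrix. All unrooted
topologies are enumerated — patients here contribute 2–3 tumor samples, and
enumeration is capped at 8 leaves ((2n-5)!! = 10,395 topologies) with a hard
error beyond — and scored by Fitch's algorithm; the minimum-score topology
wins, ties broken by lexicographically smallest canonical Newick. Branch
lengths are integer mutation counts from the Fitch traceback with the
germline state forced at the normal leaf and parent-state preference on
ambiguity, so a variant shared by all tumor samples lands on the trunk edge
below the normal. With two tumor samples this reduces exactly to trunk =
shared, branches = lesion-private counts. Variants requiring more than one
change are flagged as homoplastic and counted once per change. Output is
Newick rooted at the normal leaf with counts as branch lengths; no bootstrap
values, no per-site rates.

## Immune escape

**HLA-LOH.** Each HLA gene contributes paired per-bin log copy ratios for
its two alleles. Allele-specific copy number inverts
`ratio = p * cn + (1 - p)` at the mean log ratio. A gene has LOH iff the
minor allele CN is below 0.5 **and** a two-sided paired t test on the
bin-wise log-ratio differences gives p < 0.01. The test choice follows the
established allele-imbalance callers; it and both thresholds are config
knobs. P values are used raw, one per gene — with three class-I genes per
sample the multiplicity is small and the CN guard dominates the error rate.

**Neoantigens.** Depth screens: records with normal depth <= 5 and normal
VAF >= 2% are removed as likely germline (the normal-depth cutoff can be
raised to 20 in strict mode); only records with tumor depth >= 10 and tumor
VAF >= 40% are retained. A neoantigen is expressed iff >= 5 RNA reads cover
the mutation site and >= 3 carry the mutant base; records without RNA are
"unknown" and excluded from expression denominators rather than counted
non-expressed. Clonality is inherited from the source mutation by variant
key. A peptide binds an allele at netMHC percentile rank <= 2 (the standard
weak-binder cut, configurable).

**HLA-corrected TMB.** `tmb_total` counts the sample's nonsynonymous
mutations, split into clonal/subclonal. The corrected burden subtracts
mutations **all** of whose binding alleles were lost per the LOH calls —
their neoantigens can no longer be presented. Mutations with no predicted
binder are retained. Counts are raw mutations; `per_megabase()` divides by a
53 Mb capture size.

## Synthetic cohorts

Each simulated patient is a set of clones with per-lesion CCFs; the default
template is one truncal clone (CCF 1/1, 40 mutations) plus seven smaller
clones spanning all eight pattern labels. Read counts invert the CCF model
exactly: depth ~ Poisson(150), alt ~ Binomial(depth, E[VAF]); a mutation is
emitted in a lesion's call table when >= 3 alt reads are drawn. Defaults:
15 patients, purity 0.6 in both lesions, matched-normal error rate 0, 15% of
mutations on a (2,1) segment, multiplicity 1. Arm events per patient: 20q
amp and 17p del clonal in both lesions, 13q amp subclonal (f = 0.6) in the
primary and clonal in the metastasis, 8q amp metastasis-private. HLA
coverage is binned Poisson per allele (20 bins); 13% of patients carry a
truncal one-allele HLA loss and a further 13% a metastasis-private one.
RNA depth is Poisson(50) at transcribed sites (60% of mutations) with mutant
reads at the DNA VAF, and sparse (Poisson 1.5) otherwise. Neoantigen
candidates cover ~40% of detected mutations with log-uniform binding ranks.

What this does **not** emulate: sequencing error and FFPE artifacts, mapping
bias, subclonal copy number under the mutations, overdispersed (non-Poisson)
coverage, germline contamination of the tumor, multi-region sampling within
a lesion, and inter-patient heterogeneity of the clone structure (every
patient shares the template). Recovery rates measured on these cohorts are
therefore upper bounds on real-data performance: they validate the
inference logic against its own generative assumptions, not robustness to
model misspecification.

## Problem sizes and determinism

The test suite and the reproduction script run cohorts of 15 patients
(~110 detected mutations per lesion), 200 replicates for the LOH operating
characteristics, and 200 random matrices (4–6 leaves) against a brute-force
parsimony oracle; each block completes in seconds on one core. All
randomness flows through `numpy.random.default_rng` seeded from a single
integer; a fixed seed reproduces every table byte for byte.

## Known limitations

* Purity and allele-specific copy number are inputs; there is no joint
  purity/ploidy inference.
* The SCNA cell-fraction inversion assumes one event per arm on a diploid
  background; complex arms are only flagged.
* The HLA-corrected TMB subtraction treats binding as all-or-nothing at the
  rank cutoff and ignores partial presentation by retained weaker binders.
* Exhaustive parsimony does not scale beyond 8 samples per patient by
  design; no heuristic search is provided.
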