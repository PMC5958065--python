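# Methods

`haplogic` finds Boolean 3-SNP haplotype patterns associated with a binary
disease outcome in phased case-control data, restricted to gene-centered
analytic windows, and quantifies each pattern with an additive-copy-count
logistic model. This note documents the models, the numerical choices, and
what the bundled synthetic validation does and does not establish.

## Data model

Input is a phased cohort: an ordered list of biallelic SNPs and a
chromosome-by-variant allele matrix with two rows per subject (rows `2i`,
`2i+1` belong to subject `i`), alleles coded 0 = reference, 1 = alternative,
-1 = missing. Phasing itself is upstream (e.g. SHAPEIT); the package
consumes HAPS/SAMPLE or phased VCF and treats the supplied configuration as
observed. Positions are 1-based inclusive internally everywhere; BED-style
inputs (gene tables, annotation tracks) are 0-based half-open on disk and
converted on read.

Variant/sample QC mirrors standard GWAS practice and runs in a fixed order:
SNP call rate >= 0.95, MAF >= 0.05, Hardy-Weinberg exact p >= 0.001
computed in controls (conditional-on-allele-count enumeration, plain p
rather than mid-p), then exclusion of samples with < 0.97 call rate among
retained SNPs. Applying the filter twice changes nothing.

## Gene analytic windows

Each gene's transcripts are merged to one span; the window is the span plus
a 500 kb flank on each side (clipped at position 1), and a SNP maps to the
window iff its position lies inside. Windows with fewer than two mapped
SNPs are dropped; overlapping windows are expected and kept, and each
window records every gene whose span it contains. Within a window, SNPs
are thinned to tags by a greedy sweep in ascending position: keep a SNP iff
its haplotypic r² with every already-kept SNP is <= 0.8. Ascending-position
order is a deterministic choice where any sequential order would do;
r² is computed on phased chromosomes, not genotype dosages, because phase
is available and the downstream predictor is haplotypic.

## Haplotype logic trees and the search score

A *logic tree* is an AND/OR combination of up to three literals
`(SNP = allele)`, evaluated on a single haplotype. Because SNPs are
biallelic, `(SNP = ref)` is the negation of `(SNP = alt)`, so NOT nodes are
unnecessary and not represented. Tree identity is *structural*: operands
of one operator are sorted and same-operator chains flattened into a
canonical key, so `(A or B) and C` equals `C and (B or A)` but is distinct
from logically equivalent rearrangements with different structure. A
subject's copy count `L` in {0, 1, 2} is the number of their two haplotypes
satisfying the tree; a subject missing an allele at any leaf SNP on either
chromosome is dropped from that tree's model.

During the search a candidate tree is scored by the residual deviance of a
logistic regression of case status on the binary tree indicator over all
2N chromosome copies (each carrying its subject's phenotype). With a
single binary predictor the ML fit is closed-form in the 2x2
indicator-by-phenotype counts,

    D = -2 * sum_g [ y_g log(y_g/n_g) + (n_g - y_g) log(1 - y_g/n_g) ],

summed over the indicator-true and indicator-false groups. A constant
indicator returns the null deviance with a flag; complete separation
returns D = 0 with a flag. This chromosome-level score is used only for
ranking trees; inference uses the subject-level model below. Literal truth
columns are bit-packed per window so a tree evaluation is a few bitwise
AND/OR operations plus popcounts, and scores are cached by tree.

## Simulated-annealing search

Logic-tree space is explored by simulated annealing with five moves —
replace-leaf-SNP, flip-leaf-allele, toggle-operator, grow-leaf, prune-leaf
(leaf count capped at three; weights 0.50/0.15/0.10/0.15/0.10 — replace-
leaf carries half the mass because SNP choice dominates the space — with
inapplicable moves falling through to the next applicable one). A proposal with
deviance change dD is accepted with probability min(1, exp(-dD/T)) under a
geometric cooling schedule, T: 10 -> 0.01. Each restart starts from a
random single literal; the reported tree is the best state visited across
restarts among trees with the required number of distinct SNPs (three, or
the window size if smaller), with ties broken by canonical-key order so
results are exactly reproducible. Restart seeds derive deterministically
from (master seed, window id, restart index).

Defaults are 100 restarts of 2,000 iterations. No annealing schedule is
canonical for this problem; these values were chosen so that on small
windows (<= 6 tag SNPs) the search attains the exhaustively enumerated
optimum essentially always, and on 50-SNP windows with an embedded strong
signal it recovers the generating tree reliably (see Validation). All of
this is configurable; the exhaustive enumerator (`exhaustive_search`) is
exact for any window but cubic in window size.

## Permutation-based candidate selection

For each window, case/control labels are permuted at the subject level
(both chromosomes move together) and the full multi-restart search is
re-run per permutation — the statistic compares best-achievable fits, not
re-scores of one fixed tree. With 20 permutation deviances D_1..D_20:
deviations d_i = D_i - median(D_{-i}) (leave-one-out medians); D_med is the
median of all 20; MAD is the median absolute deviation of the d_i, scaled
by 1.4826 by default (raw MAD available); the evaluation statistic is
(D_obs - D_med)/MAD. MAD = 0 marks the window degenerate and excludes it
from ranking. Trees found in several overlapping windows are deduplicated
by canonical key keeping the best (most negative) statistic, and the top
ceil(fraction x n_unique) statistics (default fraction 0.01) are selected;
the realized cutoff is reported rather than assumed. The permuted searches
may run with a reduced restart/iteration budget for compute; any such
reduction applies identically to every window so the ranking stays
comparable.

## Additive haplotype association model

Inference for a tree uses one observation per subject:

    logit P(case) = beta0 + beta1 * L,      OR per copy = exp(beta1),

fitted by ML (IRLS via the GLM machinery) with two-sided Wald p-values.
Grouped counts per copy number and subject-level data give identical fits;
with two support points the MLE is the closed-form logit difference.
Complete separation (case fraction a 0/1 step in L) is flagged and the
p-value withheld. Replication requires, for m selected candidates,
p < alpha/m (strict) in the replication cohort *and* a replication odds
ratio on the same side of 1 as discovery; combined-cohort fits pool the two
cohorts with no cohort covariate — a choice validated by exact reproduction
of published grouped-count odds ratios (below).

`reconstruct_group_counts` inverts a printed "N (x.y% cases)" display:
admissible integer case counts are those whose exact percentage rounds
half-up to the printed one-decimal value, and the combination summing to
the known case total must be unique. Against one published table this
pipeline reproduces all five checked combined-cohort ORs to the printed
three decimals (3.665, 3.075, 0.365, 0.066 — reciprocal 15.246 — and
1.672), which also fixes the rounding convention empirically.

## Benchmark: EM frequencies and the global score test

The benchmark emulates the classical sliding-window analysis of unphased
genotypes (the phased input is collapsed to dosages). Within each 3-SNP
window, haplotype frequencies are estimated by EM under random mating,
started from uniform frequencies over genotype-compatible haplotypes;
the observed-data log-likelihood is non-decreasing by construction and
iteration stops at a 1e-8 change or 500 iterations. The global association
test uses the score vector U = sum_i (y_i - ybar) x_i, where x_i is
subject i's posterior expected haplotype dosage vector, and the variance
V = ybar(1-ybar) sum_i (x_i - xbar)(x_i - xbar)' — the permutation variance
of U given the observed dosages. Phase uncertainty shrinks the dosages
toward their mean and V shrinks with them, keeping the null distribution
calibrated at any level of ambiguity; with fully phase-determined subjects
the statistic equals the Pearson contingency score statistic on the
haplotype-class-by-phenotype table. The statistic is U'V⁻U with a
Moore-Penrose inverse (relative eigenvalue tolerance 1e-10); df = rank(V),
i.e. h - 1 for h scorable haplotypes with nondegenerate V, the most common
haplotype serving as reference. Haplotypes with estimated counts
(2N x frequency) below 20 are excluded from scoring by default; pooling
them into a remainder category is available instead. Sliding windows are
contiguous triples with skip 1; the scan Bonferroni threshold divides alpha
by the total number of window tests.

## Enrichment

Annotation enrichment compares the SNPs of selected trees against a
disjoint comparison SNP set for overlap with interval tracks, one
two-sided Fisher exact test (probability-mass criterion) per track, with a
Bonferroni threshold of alpha over the number of tracks in the assay
family. A SNP overlaps a track if its position falls in at least one
interval (intervals merged first, so nested peaks count once). eQTL
enrichment consumes a per-SNP significant-eQTL indicator table; the
counting unit is the SNP-gene pair by default, with a per-SNP collapse
option, since published summaries are ambiguous between the two.

## Synthetic cohorts

The generator draws each SNP's alternative-allele frequency uniformly from
a configured MAF range (with optional per-SNP pins), builds haplotypes
SNP-by-SNP with a first-order copying chain — copy the previous allele with
probability rho, else draw fresh — and pairs two independent haplotypes per
subject. Disease status is drawn at the subject level from
logit P(case) = beta0 + beta1 L with L the causal tree's copy count, i.e.
exactly the inference model, making parameter recovery a clean check. The
copying chain mixes marginal frequencies when adjacent MAFs differ, so
exact MAF recovery holds at rho = 0; realized frequencies and tree carrier
frequency are recorded in a truth record at generation time. The generator
deliberately has no recombination maps, demography, or genotyping error;
consequences: passing tests show correctness of the machinery under the
model's own assumptions, not robustness to population structure,
fine-scale LD, phasing error, or case-control ascertainment — all absent
here by design.

## Validation studies (`haplogic.validation`)

Genome-scale results from the motivating analysis require controlled-access
data, so the package validates properties instead; problem sizes are chosen
to exercise each property at meaningful scale while staying cheap to
re-run:

* **Search optimality** — 100 random 6-SNP windows, 500 subjects: the
  default annealing search must attain the enumerated optimum in >= 95%.
* **Selection calibration** — 300 null windows (8 SNPs, 400 subjects,
  beta1 = 0), reduced budget applied identically to observed and permuted
  searches: the realized selection fraction must sit within binomial 99%
  bounds of the configured 1%.
* **Signal recovery** — 20 replicates of 2,000 subjects; causal tree
  (a=1) or ((b=1) and (c=1)) with carrier frequency ~0.2 (MAFs pinned at
  0.12/0.30/0.30, rho = 0 so the carrier frequency is exact) and
  beta1 = ln 3 in one 50-SNP window among 99 null 15-SNP windows: the
  single 1%-selected candidate must use exactly the causal SNP set in
  >= 80% of replicates, and the mean additive-model slope must lie within
  3 Monte-Carlo SEs of ln 3.
* **Score-test oracles** — exact equality with the phase-known contingency
  statistic; null p-value uniformity (KS at alpha = 0.01) over 500 windows.
* **EM fixtures** — closed-form optima of three toy configurations.
* **Fisher oracle** — equality with full hypergeometric enumeration on
  1,000 random tables.

`scripts/acceptance.py` re-runs all of the above from scratch plus the
published-table refits and threshold arithmetic, and writes the numbers to
JSON.

## Known limitations

* The search is stochastic and non-exhaustive: it can miss the global
  optimum in large windows, and two structurally different but logically
  equivalent trees are treated as distinct (deliberately, to match
  structural deduplication).
* The evaluation statistic is a ranking device; no analytic p-value is
  attached to it.
* The additive model fits no covariates (no cohort indicator in combined
  fits, no principal components); confounding control must happen upstream
  or be added by the user.
* The benchmark score test assumes random mating within windows for the EM
  posterior; its calibration was verified under HWE-consistent simulation
  only.
* Sex chromosomes, multi-allelic sites and imputation dosages are out of
  scope.
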