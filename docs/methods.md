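# Methods

## Model and procedure

The package treats a cancer cohort as two binary gene-sample mutation
matrices: tumor M<sup>t</sup> ∈ {0,1}<sup>G×N_t</sup> and normal
M<sup>n</sup> ∈ {0,1}<sup>G×N_n</sup>, where an entry is 1 iff the gene
carries a protein-altering somatic mutation (missense, nonsense, nonstop,
frame-shift or in-frame insertion/deletion) in that sample. The modelling
assumption is the multi-hit hypothesis: each tumor sample is attributable
to some combination of h jointly mutated genes, so a good combination set
covers all tumor samples while matching as few normal samples as possible.

Selecting such a set is a weighted set-cover instance, approximated by the
standard greedy loop (score all combinations → select the argmax → exclude
covered tumor samples → repeat until all covered). The score of
combination i is F_i = (α·TP_i + TN_i)/(N_t + N_n). Two conventions matter
and are fixed here:

- **TP is counted against the remaining (not-yet-covered) tumor samples**,
  so a selected combination's TP equals its newly covered count and is
  always ≥ 1. TN is recomputed against **all** normal samples each
  iteration, and the denominator stays at the initial N_t + N_n. Within an
  iteration the constant denominator does not affect the argmax.
- **Zero-coverage guard**: a combination with TP = 0 is never selected.
  If the argmax has TP = 0 — equivalently, no remaining tumor sample has h
  mutated genes — the loop stops and reports those samples as uncovered.
  Without this guard the loop would not terminate on such samples.
  Consequently the loop always finishes within N_t iterations.

## Parameters

| parameter | default | meaning |
|---|---|---|
| h | 2 | genes per combination (1–4; cost grows as G^h, h = 4 is expensive) |
| α | 0.1 | weight of TP (sensitivity) against TN (specificity) in F; dimensionless |
| prune | off | branch-and-bound pruning; output-invariant, work-saving only |
| train_fraction | 0.75 | stratified train share of each label |
| confidence | 0.95 | level of the exact binomial intervals |

## Determinism and the parallel contract

The argmax is decomposed into independent partitions indexed by a linear
index λ over two-gene prefixes, mapped branch-free onto the strict upper
triangle by j = ⌊√(¼+2λ)+½⌋, i = λ − j(j−1)/2 (a floating-point closed
form followed by an exact integer correction step, verified as a bijection
up to G = 2000). Each partition yields a partial maximum; the reduction is
associative and tie-aware. Ties are broken by larger TP, then
lexicographically smallest gene tuple, which makes the argmax *unique*:
any partition order, chunking or executor returns the identical
combination. F is computed in double precision from integer TP/TN by one
fixed expression, so equal scores are bitwise equal and exact float
comparison is safe. Per-partition maxima are kept separate (no shared
mutable accumulator), so the same contract transfers to multi-process or
accelerator executors.

Bit packing places sample w·64+b in bit b (from the LSB) of word w; the
final partial word is low-bit aligned and padding bits are zero by
invariant, which makes popcounts exact without edge handling and the
pack/unpack round trip an identity.

## Pruning

For a prefix with masked tumor intersection count tp_prefix, every
completion satisfies F ≤ (α·tp_prefix + N_n)/(N_t+N_n), since adding genes
can only shrink TP and TN ≤ N_n always. A partition is skipped only when
this bound is **strictly** below the incumbent F: an equal-F candidate
could still win the TP/lexicographic tie-break, so pruning at equality
would not be output-invariant. The exact bound used in earlier CPU
implementations of this algorithm family is not standardized; this one is
valid and is guaranteed equivalent to this package's unpruned search
(asserted over seeded instances in the test suite).

## Synthetic cohorts

The generator emulates the input contract at realistic scale and sparsity:
G = 150 genes, 300 tumor + 300 normal samples, five planted h-hit
combinations on disjoint gene sets, and i.i.d. per-cell background noise at
2% — the density typical of protein-altering somatic calls. Each tumor
sample is assigned uniformly to one planted combination whose h genes are
forced to 1; all other cells (all cells, for normals) are Bernoulli(rate).
An optional shared hub gene across combinations emulates the hub role that
genes such as TP53 play in real combination lists.

What it does *not* emulate: per-gene mutation-rate heterogeneity (gene
length, chromatin state), mutational signatures, subclonality, or
overlapping planted combinations. Passing recovery tests therefore shows
the search and protocol are correct under the stated model, not that real
cohorts are this easy; on real data combinations may share genes and
background rates vary by orders of magnitude across genes.

## Evaluation protocol

Samples are split 75/25 **stratified by label** (plain random partition can
produce degenerate test sets at small n). Per-label train size is
round(fraction·n) under round-half-even; a label with fewer than two
samples goes wholly to train with a warning. A test sample is positive iff
it contains *all* genes of at least one discovered combination.
Sensitivity TP/N_t and specificity TN/N_n get exact Clopper-Pearson
intervals from beta quantiles (conservative: coverage ≥ nominal; the
boundary cases collapse to closed forms (0, 1−(a/2)^{1/n}) and
((a/2)^{1/n}, 1)). Metrics across cohorts are pooled from summed counts,
never averaged rates. A two-proportion normal-approximation test is
provided for comparing models (e.g. 2-hit vs 3-hit sensitivity); it is a
convenience approximation, not an exact test.

## Numerical and design choices

- Word size is fixed at 64 bits; no runtime option.
- Masks are immutable values; exclusion returns a new mask (reproducible
  iterations, safe parallel partitioning).
- The gene universe defaults to genes mutated anywhere in the input; an
  option restricts it to tumor-mutated genes.
- Matrix TSVs are canonical (0/1 characters, UTF-8, Unix newlines), so
  rewriting a read matrix is byte-identical; all readers fail loudly with
  line numbers rather than repairing input.
- The naive oracle refuses instances beyond 500 000 combinations unless
  overridden, since it exists for verification, not production use.
- MAF parsing keeps Hugo_Symbol verbatim (no alias resolution) and exposes
  the included Variant_Classification set as an option; the default is the
  protein-altering interpretation listed in the README.

## Problem sizes in the shipped checks

The equivalence suites run ~200 seeded instances at G ≤ 18 and ≤ 64
samples per cohort, where the exhaustive dense oracle is fast; the
recovery protocol runs at the full standard cohort scale (G = 150,
300+300 samples, h = 3) across five seeds. These sizes keep the entire
suite to well under a minute of compute while exercising every code path,
including the 64-bit word boundaries (sample counts 1, 63, 64, 65, 128).

## Known limitations

- h is capped at 4; the search is exhaustive within h, so G^h growth makes
  h = 4 slow beyond a few hundred genes.
- The i.i.d. noise model understates false-positive combinations expected
  under heterogeneous per-gene rates.
- Combination discovery is purely associative; selected combinations are
  candidates for experimental follow-up, not validated drivers.
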