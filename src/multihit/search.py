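"""Greedy weighted-set-cover search for multi-hit gene combinations.

Identifying the gene combinations most likely responsible for individual
cancer instances maps to weighted set cover: the universe is the tumor
samples, the candidate sets are h-gene combinations, and a combination's
weight is how well it separates tumor from normal samples.  Set cover is
NP-complete, so the classic greedy approximation is used: repeatedly score
every h-hit combination, select the best, exclude the tumor samples it
covers, and stop when every tumor sample is covered (or no remaining sample
can be covered).

Scoring.  A combination i is scored by the weighted accuracy metric

    F_i = (alpha * TP_i + TN_i) / (N_t + N_n)

where TP_i counts the not-yet-excluded tumor samples mutated in all h genes,
TN_i counts the normal samples NOT mutated in all h genes, N_t and N_n are
the total tumor and normal sample counts (fixed across iterations), and
alpha (default 0.1) balances sensitivity against specificity.

Parallel decomposition.  The argmax over all combinations is organized as
independent partitions indexed by a linear index lambda over two-gene
prefixes (i, j), i < j, mapped to the upper-triangular pair without
branching:

    j = floor(sqrt(1/4 + 2*lambda) + 1/2),   i = lambda - j*(j-1)/2

Each partition scans the completions of its prefix and yields a partial
maximum; an associative, tie-aware reduction combines them.  Ties are broken
by larger TP, then lexicographically smallest gene tuple, which makes the
argmax unique and therefore independent of partition order or chunking — any
executor (serial, multi-process, accelerator) produces the same result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .bitmatrix import PackedMatrix, SampleMask, apply_exclusion, coverage_vector
from .errors import ValidationError

__all__ = [
    "SearchConfig",
    "Combination",
    "CoverResult",
    "score_combination",
    "lambda_to_pair",
    "pair_to_lambda",
    "upper_bound_f",
    "best_combination",
    "greedy_cover",
    "classify_sample",
    "cover_result_to_report",
    "filter_gene_universe",
]

MAX_HITS = 4


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the greedy multi-hit search.

    h: genes per combination, 1-4 (4 is exhaustive and expensive).
    alpha: sensitivity weight in the F metric; 0.1 by default.
    prune: enable branch-and-bound pruning of prefixes whose F upper bound
        cannot beat the incumbent (never changes the output, only work done).
    max_iterations: optional cap on greedy iterations.
    """

    h: int = 2
    alpha: float = 0.1
    prune: bool = False
    max_iterations: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.h <= MAX_HITS:
            raise ValidationError(f"h must be in [1, {MAX_HITS}], got {self.h}")
        if self.alpha < 0:
            raise ValidationError(f"alpha must be non-negative, got {self.alpha}")
        if self.max_iterations is not None and self.max_iterations < 1:
            raise ValidationError("max_iterations must be positive when given")


@dataclass(frozen=True)
class Combination:
    """An h-gene combination with its score at selection time.

    ``tp`` counts only tumor samples still under consideration when the
    combination was scored, so for a selected combination it equals the
    number of newly covered samples.  ``tn`` is counted against all normal
    samples.
    """

    gene_indices: Tuple[int, ...]
    tp: int
    tn: int
    f: float


@dataclass(frozen=True)
class CoverResult:
    """Outcome of a greedy cover run, in selection order."""

    combinations: Tuple[Combination, ...]
    uncovered_tumor_sample_ids: Tuple[str, ...]
    iterations: int
    gene_universe: Tuple[str, ...]


def score_combination(tp: int, tn: int, n_t: int, n_n: int, alpha: float) -> float:
    """Weighted accuracy F = (alpha*TP + TN) / (N_t + N_n), double precision."""
    if n_t + n_n == 0:
        raise ValidationError("N_t + N_n must be positive")
    if not 0 <= tp <= n_t:
        raise ValidationError(f"tp={tp} outside [0, {n_t}]")
    if not 0 <= tn <= n_n:
        raise ValidationError(f"tn={tn} outside [0, {n_n}]")
    return (alpha * tp + tn) / (n_t + n_n)


def upper_bound_f(tp_prefix: int, n_t: int, n_n: int, alpha: float) -> float:
    """Upper bound on F for any completion of a partial combination.

    Adding genes can only shrink TP, and TN never exceeds N_n, so
    (alpha*tp_prefix + N_n)/(N_t+N_n) dominates every completion's F.
    """
    return (alpha * tp_prefix + n_n) / (n_t + n_n)


def lambda_to_pair(lam: int, n_genes: int) -> Tuple[int, int]:
    """Map a linear index onto the upper-triangular pair (i, j), i < j < G.

    Pairs are ordered by j then i, i.e. lam = j*(j-1)/2 + i.  The closed form
    avoids loop-control branching; a correction step guards against floating
    point edge cases at large lam.
    """
    total = n_genes * (n_genes - 1) // 2
    if not 0 <= lam < total:
        raise ValidationError(f"lambda={lam} outside [0, {total}) for G={n_genes}")
    j = int(math.sqrt(0.25 + 2.0 * lam) + 0.5)
    while j * (j - 1) // 2 > lam:
        j -= 1
    while (j + 1) * j // 2 <= lam:
        j += 1
    i = lam - j * (j - 1) // 2
    return i, j


def pair_to_lambda(i: int, j: int) -> int:
    """Inverse of :func:`lambda_to_pair`: lam = j*(j-1)/2 + i for 0 <= i < j."""
    if not 0 <= i < j:
        raise ValidationError(f"need 0 <= i < j, got ({i}, {j})")
    return j * (j - 1) // 2 + i


# ---------------------------------------------------------------------------
# argmax over all h-combinations

def _better(
    cand: Tuple[float, int, Tuple[int, ...]],
    incumbent: Optional[Tuple[float, int, Tuple[int, ...]]],
) -> bool:
    """Tie-aware comparison: max F, then max TP, then smallest gene tuple.

    Exact double equality on F is intentional — F is always derived from the
    same integer TP/TN by the same expression, so equal scores compare equal
    bit-for-bit and the argmax is unique and executor-independent.
    """
    if incumbent is None:
        return True
    f, tp, idx = cand
    bf, btp, bidx = incumbent
    if f != bf:
        return f > bf
    if tp != btp:
        return tp > btp
    return idx < bidx


def _partition_best(
    f: np.ndarray, tp: np.ndarray, tail: np.ndarray
) -> Tuple[float, int, int]:
    """Best completion within one prefix partition: (f, tp, tail gene index).

    Candidates share a prefix, so the lexicographic tie rule reduces to the
    smallest tail index among max-F, max-TP candidates.
    """
    fmax = f.max()
    at_fmax = np.flatnonzero(f == fmax)
    tp_sub = tp[at_fmax]
    winners = at_fmax[tp_sub == tp_sub.max()]
    k = int(winners[0])
    return float(fmax), int(tp[k]), int(tail[k])


def _popcounts(words: np.ndarray) -> np.ndarray:
    return np.bitwise_count(words).sum(axis=-1, dtype=np.int64)


def best_combination(
    tumor: PackedMatrix,
    normal: PackedMatrix,
    mask: SampleMask,
    cfg: SearchConfig,
) -> Combination:
    """Exhaustive argmax of F over all strictly-increasing h-tuples of genes.

    TP counts mask-included tumor samples; TN counts normal samples lacking
    the full combination.  Deterministic regardless of partition order (see
    module docstring for the tie rule).
    """
    if tumor.gene_ids != normal.gene_ids:
        raise ValidationError("tumor and normal matrices must share the gene universe")
    n_genes = tumor.n_genes
    if n_genes < cfg.h:
        raise ValidationError(f"need at least h={cfg.h} genes, have {n_genes}")
    if mask.n_samples != tumor.n_samples:
        raise ValidationError("mask does not match tumor sample count")
    if mask.popcount == 0:
        raise ValidationError("empty mask: all tumor samples already excluded")

    tw = tumor.words
    nw = normal.words
    mk = mask.words
    n_t, n_n = tumor.n_samples, normal.n_samples
    denom = n_t + n_n
    alpha = cfg.alpha

    best: Optional[Tuple[float, int, Tuple[int, ...]]] = None

    if cfg.h == 1:
        tp = _popcounts(tw & mk)
        tn = n_n - _popcounts(nw)
        f = (alpha * tp + tn) / denom
        fv, tpv, g = _partition_best(f, tp, np.arange(n_genes))
        best = (fv, tpv, (g,))
    elif cfg.h == 2:
        # chunk the lambda partitions by first gene; each chunk scans j > i
        for i in range(n_genes - 1):
            t_i = tw[i] & mk
            if cfg.prune and best is not None:
                bound = upper_bound_f(int(_popcounts(t_i)), n_t, n_n, alpha)
                if bound < best[0]:
                    continue
            tail = np.arange(i + 1, n_genes)
            tp = _popcounts(t_i & tw[i + 1 :])
            tn = n_n - _popcounts(nw[i] & nw[i + 1 :])
            f = (alpha * tp + tn) / denom
            fv, tpv, j = _partition_best(f, tp, tail)
            if _better((fv, tpv, (i, j)), best):
                best = (fv, tpv, (i, j))
    else:
        # lambda-indexed two-gene prefixes; tails are scanned vectorized
        for j in range(1, n_genes - 1):
            for i in range(j):
                prefix_t = tw[i] & tw[j] & mk
                if cfg.prune and best is not None:
                    bound = upper_bound_f(int(_popcounts(prefix_t)), n_t, n_n, alpha)
                    if bound < best[0]:
                        continue
                prefix_n = nw[i] & nw[j]
                if cfg.h == 3:
                    tail = np.arange(j + 1, n_genes)
                    tp = _popcounts(prefix_t & tw[j + 1 :])
                    tn = n_n - _popcounts(prefix_n & nw[j + 1 :])
                    f = (alpha * tp + tn) / denom
                    fv, tpv, c = _partition_best(f, tp, tail)
                    if _better((fv, tpv, (i, j, c)), best):
                        best = (fv, tpv, (i, j, c))
                else:  # h == 4
                    for c in range(j + 1, n_genes - 1):
                        tri_t = prefix_t & tw[c]
                        if cfg.prune and best is not None:
                            bound = upper_bound_f(
                                int(_popcounts(tri_t)), n_t, n_n, alpha
                            )
                            if bound < best[0]:
                                continue
                        tail = np.arange(c + 1, n_genes)
                        tp = _popcounts(tri_t & tw[c + 1 :])
                        tn = n_n - _popcounts(prefix_n & nw[c] & nw[c + 1 :])
                        f = (alpha * tp + tn) / denom
                        fv, tpv, d = _partition_best(f, tp, tail)
                        if _better((fv, tpv, (i, j, c, d)), best):
                            best = (fv, tpv, (i, j, c, d))

    assert best is not None
    fv, tpv, idx = best
    tn_final = n_n - int(
        _popcounts(np.bitwise_and.reduce(nw[list(idx)], axis=0))
    )
    return Combination(gene_indices=idx, tp=tpv, tn=tn_final, f=fv)


def greedy_cover(
    tumor: PackedMatrix,
    normal: PackedMatrix,
    cfg: SearchConfig,
    on_select: Optional[Callable[[int, Combination], None]] = None,
) -> CoverResult:
    """Iterate select-and-exclude until every tumor sample is covered.

    Each iteration scores all combinations against the remaining tumor
    samples, selects the best, and excludes the samples it covers.  A
    combination covering zero remaining samples is never selected; if the
    argmax has TP = 0 (e.g. the remaining samples have fewer than h mutated
    genes) the loop stops and those samples are reported as uncovered.
    Terminates in at most N_t iterations since every completed iteration
    strictly shrinks the remaining set.
    """
    if tumor.n_genes == 0 or tumor.n_samples == 0:
        raise ValidationError("tumor matrix must have at least one gene and one sample")
    if tumor.gene_ids != normal.gene_ids:
        raise ValidationError("tumor and normal matrices must share the gene universe")
    mask = SampleMask.full(tumor.n_samples)
    selected: List[Combination] = []
    while mask.popcount > 0:
        if cfg.max_iterations is not None and len(selected) >= cfg.max_iterations:
            break
        best = best_combination(tumor, normal, mask, cfg)
        if best.tp == 0:
            break
        selected.append(best)
        if on_select is not None:
            on_select(len(selected), best)
        mask = apply_exclusion(mask, coverage_vector(tumor, best.gene_indices))
    uncovered = tuple(tumor.sample_ids[s] for s in mask.included_indices())
    return CoverResult(
        combinations=tuple(selected),
        uncovered_tumor_sample_ids=uncovered,
        iterations=len(selected),
        gene_universe=tumor.gene_ids,
    )


def classify_sample(
    sample_gene_set: Set[str] | Iterable[str],
    combinations: Sequence,
) -> bool:
    """True (positive) iff the sample's mutated genes contain ALL genes of at
    least one combination; a partial hit is not a hit.

    ``combinations`` may be :class:`~multihit.io_formats.CombinationReport`
    rows or plain iterables of gene ids.
    """
    if not combinations:
        raise ValidationError("combinations must be non-empty")
    genes = set(sample_gene_set)
    for combo in combinations:
        combo_genes = getattr(combo, "gene_ids", combo)
        if set(combo_genes) <= genes:
            return True
    return False


def cover_result_to_report(result: CoverResult):
    """Render a :class:`CoverResult` as combination-report rows.

    ``newly_covered`` equals the selection-time TP because TP is counted
    against the not-yet-excluded tumor samples.
    """
    from .io_formats import CombinationReport

    return [
        CombinationReport(
            iteration=k,
            gene_ids=tuple(result.gene_universe[g] for g in combo.gene_indices),
            f_score=combo.f,
            tp=combo.tp,
            tn=combo.tn,
            newly_covered=combo.tp,
        )
        for k, combo in enumerate(result.combinations, start=1)
    ]


def filter_gene_universe(
    tumor_dense: np.ndarray,
    normal_dense: np.ndarray,
    gene_ids: Sequence[str],
    tumor_only: bool = False,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Restrict to genes mutated somewhere in the input.

    By default keeps genes with at least one mutation in any sample (tumor or
    normal); with ``tumor_only`` keeps only tumor-mutated genes.
    """
    tumor_dense = np.asarray(tumor_dense)
    normal_dense = np.asarray(normal_dense)
    if tumor_dense.shape[0] != len(gene_ids) or normal_dense.shape[0] != len(gene_ids):
        raise ValidationError("matrices and gene_ids disagree on gene count")
    has_t = tumor_dense.any(axis=1)
    keep = has_t if tumor_only else (has_t | normal_dense.any(axis=1))
    idx = np.flatnonzero(keep)
    return (
        tumor_dense[idx],
        normal_dense[idx],
        [gene_ids[i] for i in idx],
    )
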