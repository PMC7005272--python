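"""Deliberately naive dense-matrix reference implementation.

This module re-derives the greedy multi-hit search directly on the dense 0/1
matrices: every strictly-increasing h-tuple is enumerated explicitly and
scored from dense row products, with no bit packing, no lambda partitioning
and no pruning.  It exists so any small instance can be verified against an
independent computation path; the optimized search and this oracle share
only the scoring formula and the tie rule.

Exhaustive enumeration is exponential in h, so instances are guarded by a
combination-count ceiling; pass ``allow_large=True`` to override.
"""

from __future__ import annotations

import itertools
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .search import Combination, CoverResult, MAX_HITS

#: refuse instances with more combinations than this unless overridden
DEFAULT_MAX_COMBINATIONS = 500_000


def _check_instance(
    tumor_dense: np.ndarray,
    normal_dense: np.ndarray,
    h: int,
    allow_large: bool,
) -> None:
    if not 1 <= h <= MAX_HITS:
        raise ValidationError(f"h must be in [1, {MAX_HITS}], got {h}")
    if tumor_dense.shape[0] != normal_dense.shape[0]:
        raise ValidationError("tumor and normal matrices must share the gene universe")
    n_genes = tumor_dense.shape[0]
    if n_genes < h:
        raise ValidationError(f"need at least h={h} genes, have {n_genes}")
    n_combos = math.comb(n_genes, h)
    if n_combos > DEFAULT_MAX_COMBINATIONS and not allow_large:
        raise ValidationError(
            f"{n_combos} combinations exceeds the naive-oracle ceiling "
            f"({DEFAULT_MAX_COMBINATIONS}); pass allow_large=True to override"
        )


def naive_best_combination(
    tumor_dense: np.ndarray,
    normal_dense: np.ndarray,
    excluded_sample_flags: Sequence[bool],
    h: int,
    alpha: float,
    allow_large: bool = False,
) -> Combination:
    """Exhaustive dense argmax of F over all h-tuples.

    ``excluded_sample_flags[s]`` is True for tumor samples already covered.
    Applies the same tie rule as the optimized search: max F, then max TP,
    then lexicographically smallest tuple (guaranteed here by scanning
    tuples in lexicographic order and keeping the first winner).
    """
    tumor_dense = np.asarray(tumor_dense)
    normal_dense = np.asarray(normal_dense)
    _check_instance(tumor_dense, normal_dense, h, allow_large)
    excluded = np.asarray(excluded_sample_flags, dtype=bool)
    if excluded.shape != (tumor_dense.shape[1],):
        raise ValidationError("excluded_sample_flags must have one flag per tumor sample")
    included = ~excluded
    n_t = tumor_dense.shape[1]
    n_n = normal_dense.shape[1]
    denom = n_t + n_n
    if denom == 0:
        raise ValidationError("no samples")

    best: Optional[Tuple[float, int, Tuple[int, ...], int]] = None
    for combo in itertools.combinations(range(tumor_dense.shape[0]), h):
        rows = list(combo)
        tumor_hit = np.all(tumor_dense[rows] != 0, axis=0)
        tp = int(np.count_nonzero(tumor_hit & included))
        normal_hit = np.all(normal_dense[rows] != 0, axis=0)
        tn = n_n - int(np.count_nonzero(normal_hit))
        f = (alpha * tp + tn) / denom
        if (
            best is None
            or f > best[0]
            or (f == best[0] and tp > best[1])
            or (f == best[0] and tp == best[1] and combo < best[2])
        ):
            best = (f, tp, combo, tn)
    assert best is not None
    f, tp, combo, tn = best
    return Combination(gene_indices=combo, tp=tp, tn=tn, f=f)


def naive_greedy_cover(
    tumor_dense: np.ndarray,
    normal_dense: np.ndarray,
    h: int,
    alpha: float,
    gene_ids: Optional[Sequence[str]] = None,
    tumor_sample_ids: Optional[Sequence[str]] = None,
    max_iterations: Optional[int] = None,
    allow_large: bool = False,
) -> CoverResult:
    """Greedy cover with naive internals; same contract as
    :func:`multihit.search.greedy_cover`."""
    tumor_dense = np.asarray(tumor_dense)
    normal_dense = np.asarray(normal_dense)
    if tumor_dense.shape[0] == 0 or tumor_dense.shape[1] == 0:
        raise ValidationError("tumor matrix must have at least one gene and one sample")
    _check_instance(tumor_dense, normal_dense, h, allow_large)
    n_genes, n_t = tumor_dense.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if tumor_sample_ids is None:
        tumor_sample_ids = [f"s{j}" for j in range(n_t)]

    excluded = np.zeros(n_t, dtype=bool)
    selected: List[Combination] = []
    while not excluded.all():
        if max_iterations is not None and len(selected) >= max_iterations:
            break
        best = naive_best_combination(
            tumor_dense, normal_dense, excluded, h, alpha, allow_large=allow_large
        )
        if best.tp == 0:
            break
        selected.append(best)
        covered = np.all(tumor_dense[list(best.gene_indices)] != 0, axis=0)
        excluded |= covered
    uncovered = tuple(tumor_sample_ids[s] for s in np.flatnonzero(~excluded))
    return CoverResult(
        combinations=tuple(selected),
        uncovered_tumor_sample_ids=uncovered,
        iterations=len(selected),
        gene_universe=tuple(gene_ids),
    )
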