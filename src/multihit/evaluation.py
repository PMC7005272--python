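"""Train/test protocol and accuracy statistics.

Combinations are discovered on a training split (75% by default) and judged
on the held-out test split: a test sample is called positive when it
contains all genes of at least one discovered combination.  Sensitivity is
TP/N_t over test tumor samples, specificity TN/N_n over test normal
samples, each with an exact (Clopper-Pearson) binomial confidence interval.
Overall metrics across several cohorts are pooled from total counts, not
averaged rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
from scipy.stats import beta, norm

from .errors import ValidationError
from .search import classify_sample

__all__ = [
    "EvalReport",
    "split_train_test",
    "evaluate",
    "clopper_pearson_ci",
    "pooled_metrics",
    "gene_sets_from_dense",
    "two_proportion_test",
]


def clopper_pearson_ci(
    successes: int, n: int, confidence: float = 0.95
) -> Tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles.

    Conservative by construction (coverage >= nominal).  The lower bound is
    exactly 0 when successes == 0 and the upper exactly 1 when successes == n.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not 0 <= successes <= n:
        raise ValidationError(f"successes={successes} outside [0, {n}]")
    if not 0 < confidence < 1:
        raise ValidationError(f"confidence must be in (0, 1), got {confidence}")
    a = 1.0 - confidence
    lower = 0.0 if successes == 0 else float(beta.ppf(a / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(beta.ppf(1 - a / 2, successes + 1, n - successes))
    return lower, upper


@dataclass(frozen=True)
class EvalReport:
    """Classification accuracy on a test split, with exact CIs."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    sens_ci: Tuple[float, float]
    spec_ci: Tuple[float, float]
    confidence: float

    @classmethod
    def from_counts(
        cls, tp: int, fn: int, tn: int, fp: int, confidence: float = 0.95
    ) -> "EvalReport":
        n_t = tp + fn
        n_n = tn + fp
        if n_t < 1 or n_n < 1:
            raise ValidationError("need at least one tumor and one normal sample")
        return cls(
            tp=tp,
            fn=fn,
            tn=tn,
            fp=fp,
            sensitivity=tp / n_t,
            specificity=tn / n_n,
            sens_ci=clopper_pearson_ci(tp, n_t, confidence),
            spec_ci=clopper_pearson_ci(tn, n_n, confidence),
            confidence=confidence,
        )

    @property
    def n_tumor(self) -> int:
        return self.tp + self.fn

    @property
    def n_normal(self) -> int:
        return self.tn + self.fp

    def to_text(self) -> str:
        """Key: value rendering for report files."""
        pct = int(round(self.confidence * 100))
        return "\n".join(
            [
                f"tumor_samples: {self.n_tumor}",
                f"normal_samples: {self.n_normal}",
                f"tp: {self.tp}",
                f"fn: {self.fn}",
                f"tn: {self.tn}",
                f"fp: {self.fp}",
                f"sensitivity: {self.sensitivity:.6f}",
                f"sensitivity_ci{pct}: [{self.sens_ci[0]:.6f}, {self.sens_ci[1]:.6f}]",
                f"specificity: {self.specificity:.6f}",
                f"specificity_ci{pct}: [{self.spec_ci[0]:.6f}, {self.spec_ci[1]:.6f}]",
            ]
        )


def split_train_test(
    sample_ids_by_label: Mapping[str, Sequence[str]],
    train_fraction: float = 0.75,
    seed: int = 0,
) -> Tuple[Dict[str, List[str]], Dict[str, List[str]]]:
    """Stratified random train/test split, deterministic under ``seed``.

    Per label, the train size is round(fraction * n) (Python's
    round-half-even).  A label with fewer than 2 samples goes wholly to
    train with a warning.  Labels are processed in sorted order so the
    partition depends only on the seed and the contents.
    """
    if not 0 < train_fraction < 1:
        raise ValidationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    train: Dict[str, List[str]] = {}
    test: Dict[str, List[str]] = {}
    for label in sorted(sample_ids_by_label):
        ids = list(sample_ids_by_label[label])
        if len(ids) < 2:
            warnings.warn(
                f"label {label!r} has {len(ids)} sample(s); placing all in train",
                stacklevel=2,
            )
            train[label] = ids
            test[label] = []
            continue
        n_train = int(round(train_fraction * len(ids)))
        perm = rng.permutation(len(ids))
        train[label] = [ids[k] for k in perm[:n_train]]
        test[label] = [ids[k] for k in perm[n_train:]]
    return train, test


def gene_sets_from_dense(
    dense: np.ndarray,
    gene_ids: Sequence[str],
    sample_ids: Sequence[str],
) -> Dict[str, Set[str]]:
    """Per-sample sets of mutated gene ids from a dense 0/1 matrix."""
    dense = np.asarray(dense)
    if dense.shape != (len(gene_ids), len(sample_ids)):
        raise ValidationError("matrix shape does not match id lists")
    return {
        sample: {gene_ids[g] for g in np.flatnonzero(dense[:, j])}
        for j, sample in enumerate(sample_ids)
    }


def evaluate(
    tumor_test: Mapping[str, Set[str]],
    normal_test: Mapping[str, Set[str]],
    combinations: Sequence,
    confidence: float = 0.95,
) -> EvalReport:
    """Score discovered combinations on held-out samples.

    ``tumor_test`` / ``normal_test`` map sample id to its mutated-gene set
    (see :func:`gene_sets_from_dense`).  A sample is positive iff it contains
    some combination in full.
    """
    if not tumor_test or not normal_test:
        raise ValidationError("test sets must contain at least one tumor and one normal sample")
    if not combinations:
        raise ValidationError("combinations must be non-empty")
    tp = sum(classify_sample(genes, combinations) for genes in tumor_test.values())
    fp = sum(classify_sample(genes, combinations) for genes in normal_test.values())
    return EvalReport.from_counts(
        tp=tp,
        fn=len(tumor_test) - tp,
        tn=len(normal_test) - fp,
        fp=fp,
        confidence=confidence,
    )


def pooled_metrics(
    reports: Sequence[EvalReport], confidence: float = 0.95
) -> EvalReport:
    """Overall accuracy from total counts across reports (not averaged rates)."""
    if not reports:
        raise ValidationError("need at least one report to pool")
    return EvalReport.from_counts(
        tp=sum(r.tp for r in reports),
        fn=sum(r.fn for r in reports),
        tn=sum(r.tn for r in reports),
        fp=sum(r.fp for r in reports),
        confidence=confidence,
    )


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, confidence: float = 0.95
) -> Tuple[float, Tuple[float, float], float]:
    """Difference between two proportions with a normal-approximation CI and
    two-sided p-value (unpooled SE for the CI, pooled for the test).

    A convenience for comparing, e.g., 2-hit vs 3-hit sensitivity; it is an
    approximation, not an exact test.
    """
    if n1 < 1 or n2 < 1 or not 0 <= x1 <= n1 or not 0 <= x2 <= n2:
        raise ValidationError("invalid counts for two-proportion test")
    p1, p2 = x1 / n1, x2 / n2
    diff = p1 - p2
    se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z_crit = float(norm.ppf(1 - (1 - confidence) / 2))
    ci = (diff - z_crit * se, diff + z_crit * se)
    pooled = (x1 + x2) / (n1 + n2)
    se0 = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se0 == 0:
        p_value = 1.0
    else:
        z = diff / se0
        p_value = 2 * float(norm.sf(abs(z)))
    return diff, ci, p_value
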