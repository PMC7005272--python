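"""Seeded generator of tumor/normal mutation cohorts with planted structure.

Real somatic gene-sample mutation matrices are sparse — on the order of 2%
of cells are nonzero — and the multi-hit model assumes each tumor sample is
explained by some h-gene combination.  The generator emulates exactly that:
it plants a small number of disjoint h-gene combinations, assigns every
tumor sample to one of them (setting all h genes to 1), and overlays
i.i.d. background noise at the target density on every remaining cell of
both matrices.  The planted assignment is returned as ground truth so
recovery can be checked end to end.

Defaults match the cohort used throughout the test protocol: 150 genes,
300 tumor and 300 normal samples, five planted 3-hit combinations, 2%
background noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Tuple

import numpy as np

from .errors import ValidationError

__all__ = ["SyntheticSpec", "SyntheticTruth", "SyntheticCohort", "generate",
           "write_truth", "read_truth"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    shared_hub plants one gene common to every combination (emulating the
    hub role genes like TP53 play in real combination lists); the remaining
    h-1 genes of each combination stay disjoint.
    """

    n_genes: int = 150
    n_tumor: int = 300
    n_normal: int = 300
    h: int = 3
    n_combos: int = 5
    background_rate: float = 0.02
    seed: int = 0
    shared_hub: bool = False

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tumor", "n_normal", "h", "n_combos"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.background_rate < 1:
            raise ValidationError("background_rate must be in [0, 1)")
        needed = (
            1 + self.n_combos * (self.h - 1) if self.shared_hub else self.n_combos * self.h
        )
        if needed > self.n_genes:
            raise ValidationError(
                f"planted combinations need {needed} distinct genes "
                f"(n_combos*h = {self.n_combos}*{self.h}) but only "
                f"{self.n_genes} genes are available"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth: the planted combinations (as gene-id tuples) and each
    tumor sample's assigned combination index."""

    planted_combinations: Tuple[Tuple[str, ...], ...]
    assignment: Dict[str, int]


class SyntheticCohort(NamedTuple):
    tumor_dense: np.ndarray
    normal_dense: np.ndarray
    gene_ids: List[str]
    tumor_ids: List[str]
    normal_ids: List[str]
    truth: SyntheticTruth


def generate(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a cohort deterministically from ``spec.seed``.

    Planted cells are forced to 1; every other cell of the tumor matrix, and
    every cell of the normal matrix, is 1 independently with probability
    ``background_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    G, n_t, n_n = spec.n_genes, spec.n_tumor, spec.n_normal
    width = max(4, len(str(G)))
    gene_ids = [f"g{i:0{width}d}" for i in range(G)]
    tumor_ids = [f"T{j:04d}" for j in range(n_t)]
    normal_ids = [f"N{j:04d}" for j in range(n_n)]

    if spec.shared_hub:
        picked = rng.choice(G, size=1 + spec.n_combos * (spec.h - 1), replace=False)
        hub = int(picked[0])
        rest = picked[1:].reshape(spec.n_combos, spec.h - 1)
        combos = [tuple(sorted([hub, *map(int, row)])) for row in rest]
    else:
        picked = rng.choice(G, size=spec.n_combos * spec.h, replace=False)
        combos = [
            tuple(sorted(map(int, row)))
            for row in picked.reshape(spec.n_combos, spec.h)
        ]

    assignment_idx = rng.integers(spec.n_combos, size=n_t)

    tumor = (rng.random((G, n_t)) < spec.background_rate).astype(np.uint8)
    normal = (rng.random((G, n_n)) < spec.background_rate).astype(np.uint8)
    for j, c in enumerate(assignment_idx):
        tumor[list(combos[c]), j] = 1

    truth = SyntheticTruth(
        planted_combinations=tuple(
            tuple(gene_ids[g] for g in combo) for combo in combos
        ),
        assignment={tumor_ids[j]: int(assignment_idx[j]) for j in range(n_t)},
    )
    return SyntheticCohort(tumor, normal, gene_ids, tumor_ids, normal_ids, truth)


def write_truth(path: str | Path, truth: SyntheticTruth) -> None:
    """Write the ground-truth sidecar as JSON."""
    payload = {
        "planted_combinations": [list(c) for c in truth.planted_combinations],
        "assignment": truth.assignment,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return SyntheticTruth(
        planted_combinations=tuple(
            tuple(c) for c in payload["planted_combinations"]
        ),
        assignment={k: int(v) for k, v in payload["assignment"].items()},
    )
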