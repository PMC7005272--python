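"""Readers and writers for the formats the tool touches.

Three formats: MAF mutation files (GDC tab-delimited dialect, ``#`` comment
lines), dense 0/1 gene × sample matrix TSVs (the tool's canonical interchange
format), and multi-hit combination report TSVs.  All readers reject malformed
input rather than silently repairing it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import FormatError

#: Variant_Classification values treated as protein-altering by default:
#: missense and nonsense substitutions plus frame-shift and in-frame
#: insertions/deletions.  Silent, splice-site and UTR classes are excluded.
DEFAULT_MAF_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
    }
)

_MAF_REQUIRED = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call: which gene, which sample, what kind."""

    gene_symbol: str
    sample_barcode: str
    variant_classification: str


@dataclass(frozen=True)
class CombinationReport:
    """One selected multi-hit combination, as written to a report TSV."""

    iteration: int
    gene_ids: Tuple[str, ...]
    f_score: float
    tp: int
    tn: int
    newly_covered: int


def read_maf(
    path: str | Path,
    included_classes: Iterable[str] = DEFAULT_MAF_CLASSES,
) -> List[MutationRecord]:
    """Parse a MAF file, keeping records whose Variant_Classification is in
    ``included_classes``.

    Requires the Hugo_Symbol, Variant_Classification and Tumor_Sample_Barcode
    columns; leading ``#`` comment lines are skipped.  Deduplication at
    (gene, sample) granularity happens downstream, not here.
    """
    included = set(included_classes)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = [(i + 1, ln) for i, ln in enumerate(fh) if not ln.startswith("#")]
    lines = [(n, ln) for n, ln in lines if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: no content after comment lines")
    header = next(csv.reader([lines[0][1]], delimiter="\t"))
    col = {name: i for i, name in enumerate(header)}
    for required in _MAF_REQUIRED:
        if required not in col:
            raise FormatError(f"{path}: missing required MAF column {required!r}")
    gi, ci, si = (col[c] for c in _MAF_REQUIRED)
    records: List[MutationRecord] = []
    for lineno, line in lines[1:]:
        fields = next(csv.reader([line], delimiter="\t"))
        if len(fields) < len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
        gene, klass, sample = fields[gi].strip(), fields[ci].strip(), fields[si].strip()
        if not (gene and klass and sample):
            raise FormatError(f"{path}:{lineno}: empty gene/classification/sample field")
        if klass in included:
            records.append(MutationRecord(gene, sample, klass))
    return records


def records_to_dense(
    records: Sequence[MutationRecord],
    gene_universe: Optional[Sequence[str]] = None,
    sample_universe: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, List[str], List[str]]:
    """Build the binary gene × sample matrix from mutation records.

    ``matrix[i, j] = 1`` iff at least one record exists for (gene i, sample j).
    If a universe is given, records outside it are dropped; otherwise the
    universe is the sorted distinct set of observed values.  Order-independent
    in the record list.
    """
    if gene_universe is None:
        genes = sorted({r.gene_symbol for r in records})
    else:
        genes = list(gene_universe)
        if len(set(genes)) != len(genes):
            raise FormatError("gene_universe contains duplicates")
    if sample_universe is None:
        samples = sorted({r.sample_barcode for r in records})
    else:
        samples = list(sample_universe)
        if len(set(samples)) != len(samples):
            raise FormatError("sample_universe contains duplicates")
    gidx = {g: i for i, g in enumerate(genes)}
    sidx = {s: j for j, s in enumerate(samples)}
    dense = np.zeros((len(genes), len(samples)), dtype=np.uint8)
    for r in records:
        i = gidx.get(r.gene_symbol)
        j = sidx.get(r.sample_barcode)
        if i is not None and j is not None:
            dense[i, j] = 1
    return dense, genes, samples


def write_matrix_tsv(
    path: str | Path,
    dense: np.ndarray,
    gene_ids: Sequence[str],
    sample_ids: Sequence[str],
) -> None:
    """Write the canonical matrix TSV: header ``gene<TAB>sample...``, then one
    row per gene of 0/1 characters.  UTF-8, Unix newlines."""
    arr = np.asarray(dense)
    if arr.shape != (len(gene_ids), len(sample_ids)):
        raise FormatError(
            f"matrix shape {arr.shape} does not match id lists "
            f"({len(gene_ids)} genes, {len(sample_ids)} samples)"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(sample_ids) + "\n")
        for gene, row in zip(gene_ids, arr):
            fh.write(gene + "\t" + "\t".join("1" if v else "0" for v in row) + "\n")


def read_matrix_tsv(path: str | Path) -> Tuple[np.ndarray, List[str], List[str]]:
    """Read a matrix TSV written by :func:`write_matrix_tsv`.

    Rejects ragged rows, non-0/1 cells and duplicate gene or sample ids,
    reporting the offending line number.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "gene":
        raise FormatError(f"{path}:1: header must start with 'gene'")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}:1: duplicate sample id in header")
    gene_ids: List[str] = []
    rows: List[List[int]] = []
    seen = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        gene = fields[0]
        if gene in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        seen.add(gene)
        row = []
        for value in fields[1:]:
            if value == "0":
                row.append(0)
            elif value == "1":
                row.append(1)
            else:
                raise FormatError(f"{path}:{lineno}: cell value {value!r} is not 0/1")
        gene_ids.append(gene)
        rows.append(row)
    dense = (
        np.array(rows, dtype=np.uint8)
        if rows
        else np.zeros((0, len(sample_ids)), dtype=np.uint8)
    )
    return dense, gene_ids, sample_ids


_COMBO_HEADER = ("iteration", "genes", "F", "TP", "TN", "newly_covered")


def write_combinations(path: str | Path, report: Sequence[CombinationReport]) -> None:
    """Write a combination report TSV; F is printed with 6 decimal places and
    genes comma-joined in ascending internal order."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_COMBO_HEADER) + "\n")
        for row in report:
            fh.write(
                f"{row.iteration}\t{','.join(row.gene_ids)}\t{row.f_score:.6f}\t"
                f"{row.tp}\t{row.tn}\t{row.newly_covered}\n"
            )


def read_combinations(path: str | Path) -> List[CombinationReport]:
    """Read a combination report TSV back (F to its printed precision)."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or tuple(lines[0].split("\t")) != _COMBO_HEADER:
        raise FormatError(f"{path}: missing or malformed combination report header")
    out: List[CombinationReport] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(_COMBO_HEADER):
            raise FormatError(f"{path}:{lineno}: expected {len(_COMBO_HEADER)} fields")
        try:
            out.append(
                CombinationReport(
                    iteration=int(fields[0]),
                    gene_ids=tuple(fields[1].split(",")),
                    f_score=float(fields[2]),
                    tp=int(fields[3]),
                    tn=int(fields[4]),
                    newly_covered=int(fields[5]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out
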