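"""Bit-packed gene-sample mutation matrices and the popcount kernels built on them.

A gene-sample mutation matrix is a binary matrix M with M[g][s] = 1 iff gene
``g`` carries a protein-altering somatic mutation in sample ``s``.  These
matrices are sparse (on the order of 2% nonzero), and the multi-hit search
only ever needs two primitives on them: intersect a handful of gene rows and
count the surviving samples.  Packing 64 samples into one 64-bit word turns
both primitives into a word-wise AND followed by a popcount.

Layout: sample index ``w*64 + b`` lives in bit ``b`` (counted from the least
significant bit) of word ``w``; the final partial word is low-bit aligned and
its padding bits are always zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError

WORD_BITS = 64


def _words_per_row(n_samples: int) -> int:
    return (n_samples + WORD_BITS - 1) // WORD_BITS


def _padding_mask(n_samples: int) -> np.ndarray:
    """Word vector with ones in every valid sample bit and zeros in padding."""
    w = _words_per_row(n_samples)
    mask = np.full(w, np.uint64(0xFFFFFFFFFFFFFFFF), dtype=np.uint64)
    tail = n_samples % WORD_BITS
    if tail:
        mask[-1] = np.uint64((1 << tail) - 1)
    return mask


def _pack_dense(dense: np.ndarray, n_samples: int) -> np.ndarray:
    """Pack a (rows, n_samples) 0/1 array into (rows, words) uint64, little-endian bits."""
    rows = dense.shape[0]
    w = _words_per_row(n_samples)
    padded = np.zeros((rows, w * WORD_BITS), dtype=np.uint8)
    padded[:, :n_samples] = dense
    packed_bytes = np.packbits(padded, axis=1, bitorder="little")
    return packed_bytes.view("<u8").astype(np.uint64, copy=False).reshape(rows, w)


def _unpack_words(words: np.ndarray, n_samples: int) -> np.ndarray:
    flat_bytes = np.ascontiguousarray(words, dtype="<u8").view(np.uint8)
    bits = np.unpackbits(flat_bytes.reshape(words.shape[0], -1), axis=1, bitorder="little")
    return bits[:, :n_samples]


def popcount(words: np.ndarray) -> int:
    """Total number of set bits in a word array."""
    return int(np.bitwise_count(words).sum(dtype=np.int64))


@dataclass(frozen=True)
class PackedMatrix:
    """Bit-packed gene × sample mutation matrix.

    ``words`` has shape ``(len(gene_ids), ceil(n_samples/64))`` and dtype
    uint64; padding bits beyond ``n_samples`` are zero in every row.
    """

    gene_ids: Tuple[str, ...]
    sample_ids: Tuple[str, ...]
    words: np.ndarray

    def __post_init__(self) -> None:
        words = np.asarray(self.words, dtype=np.uint64)
        words.setflags(write=False)
        object.__setattr__(self, "words", words)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if words.ndim != 2 or words.shape[0] != len(self.gene_ids):
            raise ValidationError(
                f"words shape {words.shape} inconsistent with {len(self.gene_ids)} genes"
            )
        if words.shape[1] != _words_per_row(self.n_samples):
            raise ValidationError(
                f"expected {_words_per_row(self.n_samples)} words per row, got {words.shape[1]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def words_per_row(self) -> int:
        return self.words.shape[1]


@dataclass(frozen=True)
class SampleMask:
    """Packed inclusion mask over samples: a set bit means the sample is
    still under consideration (not yet excluded from the greedy cover)."""

    n_samples: int
    words: np.ndarray

    def __post_init__(self) -> None:
        words = np.asarray(self.words, dtype=np.uint64)
        words.setflags(write=False)
        object.__setattr__(self, "words", words)
        if words.shape != (_words_per_row(self.n_samples),):
            raise ValidationError(
                f"mask has {words.shape} words for {self.n_samples} samples"
            )
        if np.any(words & ~_padding_mask(self.n_samples)):
            raise ValidationError("mask has nonzero padding bits")

    @classmethod
    def full(cls, n_samples: int) -> "SampleMask":
        """Mask with every sample included."""
        return cls(n_samples, _padding_mask(n_samples))

    @property
    def popcount(self) -> int:
        return popcount(self.words)

    def included_indices(self) -> np.ndarray:
        """Sample indices whose bit is set, ascending."""
        return np.flatnonzero(_unpack_words(self.words[None, :], self.n_samples)[0])


def pack_rows(
    dense: Sequence[Sequence[int]] | np.ndarray,
    gene_ids: Sequence[str],
    sample_ids: Sequence[str],
) -> PackedMatrix:
    """Pack a dense 0/1 genes × samples matrix into 64-bit words.

    Raises :class:`ValidationError` on non-binary entries (naming the
    offending row/column) or on a shape mismatch with the id lists.
    """
    arr = np.asarray(dense)
    if arr.ndim != 2:
        raise ValidationError(f"dense matrix must be 2-D, got ndim={arr.ndim}")
    if arr.shape != (len(gene_ids), len(sample_ids)):
        raise ValidationError(
            f"matrix shape {arr.shape} does not match "
            f"{len(gene_ids)} genes x {len(sample_ids)} samples"
        )
    bad = (arr != 0) & (arr != 1)
    if np.any(bad):
        g, s = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-binary entry {arr[g, s]!r} at gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
        )
    words = _pack_dense(arr.astype(np.uint8, copy=False), len(sample_ids))
    return PackedMatrix(tuple(gene_ids), tuple(sample_ids), words)


def unpack(m: PackedMatrix) -> np.ndarray:
    """Exact inverse of :func:`pack_rows`: a (n_genes, n_samples) uint8 0/1 array.

    Raises :class:`ValidationError` if any padding bit is set.
    """
    pad = _padding_mask(m.n_samples)
    if np.any(m.words & ~pad):
        raise ValidationError("packed matrix has nonzero padding bits")
    return _unpack_words(m.words, m.n_samples)


def _check_indices(m: PackedMatrix, gene_indices: Sequence[int]) -> Tuple[int, ...]:
    idx = tuple(int(i) for i in gene_indices)
    if not idx:
        raise ValidationError("gene_indices must be non-empty")
    if len(set(idx)) != len(idx):
        raise ValidationError(f"gene_indices must be distinct, got {idx}")
    for i in idx:
        if not 0 <= i < m.n_genes:
            raise ValidationError(f"gene index {i} out of range [0, {m.n_genes})")
    return idx


def coverage_vector(m: PackedMatrix, gene_indices: Sequence[int]) -> np.ndarray:
    """Word-wise AND of the named gene rows: a packed bit-vector of the
    samples mutated in *all* the genes."""
    idx = _check_indices(m, gene_indices)
    acc = m.words[idx[0]].copy()
    for i in idx[1:]:
        acc &= m.words[i]
    return acc


def intersect_count(
    m: PackedMatrix,
    gene_indices: Sequence[int],
    mask: Optional[SampleMask] = None,
) -> int:
    """Number of (mask-included) samples mutated in every listed gene.

    Word-wise AND of the rows and the mask, then popcount; padding never
    contributes because padding bits are zero by invariant.
    """
    acc = coverage_vector(m, gene_indices)
    if mask is not None:
        if mask.n_samples != m.n_samples:
            raise ValidationError(
                f"mask covers {mask.n_samples} samples, matrix has {m.n_samples}"
            )
        acc &= mask.words
    return popcount(acc)


def apply_exclusion(mask: SampleMask, covered: np.ndarray) -> SampleMask:
    """New mask with the covered samples removed: ``mask AND NOT covered``.

    The input mask is unchanged (masks are immutable values)."""
    covered = np.asarray(covered, dtype=np.uint64)
    if covered.shape != mask.words.shape:
        raise ValidationError(
            f"covered vector has {covered.shape} words, mask has {mask.words.shape}"
        )
    return SampleMask(mask.n_samples, mask.words & ~covered)
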