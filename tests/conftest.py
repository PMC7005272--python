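"""Shared fixtures and instance generators."""

from __future__ import annotations

import numpy as np
import pytest

from multihit import pack_rows


def random_instance(rng, n_genes=None, n_tumor=None, n_normal=None, density=None):
    """A random dense tumor/normal pair over a shared gene universe.

    Sizes default to small draws that keep exhaustive oracles fast.
    """
    n_genes = n_genes if n_genes is not None else int(rng.integers(5, 19))
    n_tumor = n_tumor if n_tumor is not None else int(rng.integers(4, 65))
    n_normal = n_normal if n_normal is not None else int(rng.integers(4, 65))
    density = density if density is not None else float(rng.uniform(0.1, 0.45))
    tumor = (rng.random((n_genes, n_tumor)) < density).astype(np.uint8)
    normal = (rng.random((n_genes, n_normal)) < density / 2).astype(np.uint8)
    gene_ids = [f"g{i}" for i in range(n_genes)]
    tumor_ids = [f"T{j}" for j in range(n_tumor)]
    normal_ids = [f"N{j}" for j in range(n_normal)]
    return tumor, normal, gene_ids, tumor_ids, normal_ids


def pack_instance(tumor, normal, gene_ids, tumor_ids, normal_ids):
    return (
        pack_rows(tumor, gene_ids, tumor_ids),
        pack_rows(normal, gene_ids, normal_ids),
    )


MAF_FIXTURE = """\
#version gdc-1.0
Hugo_Symbol\tChromosome\tVariant_Classification\tTumor_Sample_Barcode
TP53\tchr17\tMissense_Mutation\tS1
TP53\tchr17\tSilent\tS2
KRAS\tchr12\tFrame_Shift_Del\tS1
BRCA1\tchr17\tNonsense_Mutation\tS2
BRCA1\tchr17\tMissense_Mutation\tS2
EGFR\tchr7\tIn_Frame_Ins\tS3
PTEN\tchr10\tMissense_Mutation\tS4
KRAS\tchr12\tMissense_Mutation\tS3
TP53\tchr17\tNonsense_Mutation\tS4
EGFR\tchr7\tSplice_Site\tS4
PTEN\tchr10\tFrame_Shift_Ins\tS2
"""

# Hand enumeration of the protein-altering records above, genes and samples
# sorted: rows BRCA1, EGFR, KRAS, PTEN, TP53 x columns S1..S4.
MAF_FIXTURE_DENSE = np.array(
    [
        [0, 1, 0, 0],  # BRCA1: S2 (x2 records, deduplicated)
        [0, 0, 1, 0],  # EGFR: S3 (S4 record is Splice_Site, dropped)
        [1, 0, 1, 0],  # KRAS: S1, S3
        [0, 1, 0, 1],  # PTEN: S2, S4
        [1, 0, 0, 1],  # TP53: S1 (S2 Silent dropped), S4
    ],
    dtype=np.uint8,
)
MAF_FIXTURE_GENES = ["BRCA1", "EGFR", "KRAS", "PTEN", "TP53"]
MAF_FIXTURE_SAMPLES = ["S1", "S2", "S3", "S4"]


@pytest.fixture
def maf_file(tmp_path):
    path = tmp_path / "fixture.maf"
    path.write_text(MAF_FIXTURE, encoding="utf-8")
    return path
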