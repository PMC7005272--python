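"""Build a gene-sample mutation matrix from a MAF file and search it.

Writes a tiny MAF, filters it to protein-altering variant classes, builds
the 0/1 gene-sample matrix, and runs an exhaustive 2-hit scan on it.
"""

import tempfile
from pathlib import Path

import numpy as np

from multihit import (
    SampleMask,
    SearchConfig,
    best_combination,
    pack_rows,
    read_maf,
    records_to_dense,
)

MAF = """\
#version demo
Hugo_Symbol\tVariant_Classification\tTumor_Sample_Barcode
TP53\tMissense_Mutation\tS1
KRAS\tFrame_Shift_Del\tS1
TP53\tNonsense_Mutation\tS2
KRAS\tMissense_Mutation\tS2
TP53\tSilent\tS3
BRCA1\tMissense_Mutation\tS3
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.maf"
    path.write_text(MAF)
    records = read_maf(path)  # default protein-altering classes drop the Silent row
    dense, genes, samples = records_to_dense(records)

print("matrix (genes x samples):")
print("      " + " ".join(samples))
for g, row in zip(genes, dense):
    print(f"{g:>5} " + " ".join(map(str, row)))

# tumor matrix only, with an all-zero "normal" cohort of 3 samples
tumor = pack_rows(dense, genes, samples)
normal = pack_rows(np.zeros((len(genes), 3), dtype=np.uint8),
                   genes, ["N1", "N2", "N3"])
best = best_combination(tumor, normal, SampleMask.full(len(samples)),
                        SearchConfig(h=2, alpha=0.1))
print(f"best 2-hit combination: {','.join(genes[g] for g in best.gene_indices)} "
      f"(TP={best.tp} of {len(samples)} tumor samples, F={best.f:.4f})")
print("-> TP53+KRAS co-occur in S1 and S2, so that pair covers the most "
      "tumor samples while no normal sample contains it.")
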