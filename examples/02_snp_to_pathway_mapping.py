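"""Map SNPs to genes by distance and genes to pathways from a GMT file.

Writes a tiny BED annotation and GMT gene-set file, reads them back, and
builds the SNP-level pathway collection used by the model.
"""

import tempfile
from pathlib import Path

import numpy as np

from pathsgl import GenotypeMatrix, build_pathways, map_snps_to_genes
from pathsgl.io import read_annotation, read_gmt

tmp = Path(tempfile.mkdtemp())
# BED is 0-based half-open on disk; internally coordinates are 1-based inclusive
(tmp / "genes.bed").write_text(
    "chr1\t999\t3000\tGENE_A\nchr1\t4999\t8000\tGENE_B\nchr2\t99\t2000\tGENE_C\n"
)
(tmp / "sets.gmt").write_text(
    "lipid_pathway\tdesc\tGENE_A\tGENE_B\nimmune_pathway\tdesc\tGENE_B\tGENE_C\n"
)

positions = np.array([1500, 2500, 9000, 5500, 120_000, 1000])
chroms = ["chr1", "chr1", "chr1", "chr1", "chr1", "chr2"]
genotypes = GenotypeMatrix(
    np.zeros((4, 6)), [f"rs{i}" for i in range(6)], chrom=chroms, pos=positions
)

annotation = read_annotation(tmp / "genes.bed")
gene_sets = read_gmt(tmp / "sets.gmt")
snp_gene = map_snps_to_genes(annotation, genotypes, window_bp=10_000)
collection, summary = build_pathways(snp_gene, gene_sets)

print(summary.to_string())
for name, group in zip(collection.names, collection.groups):
    print(f"{name}: SNP indices {group.tolist()}")
# GENE_B belongs to both sets, so its SNPs appear in both pathways — this
# overlap is what the overlap expansion in the model handles.
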