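"""Rank pathways and SNPs by selection frequency over half-sample refits.

A strong causal SNP is selected in (almost) every subsample; its pathway
tops the pathway ranking. A matched permutation-null run and the Pearson
bias diagnostic show that the empirical signal is not driven by structural
bias.
"""

import numpy as np

from pathsgl import (
    GenotypeMatrix,
    PathwayCollection,
    PhenotypeTable,
    SGLConfig,
    bias_diagnostics,
    null_frequencies,
    selection_frequencies,
)

rng = np.random.default_rng(0)
N, P = 200, 40
maf = rng.uniform(0.2, 0.5, size=P)
G = rng.binomial(2, maf, size=(N, P)).astype(float)
x = (G[:, 7] - G[:, 7].mean()) / G[:, 7].std()
y = 1.2 * x + rng.standard_normal(N)

genotypes = GenotypeMatrix(G, [f"rs{j}" for j in range(P)])
phenotype = PhenotypeTable(y - y.mean())
collection = PathwayCollection(
    [np.arange(0, 10), np.arange(10, 20), np.arange(20, 30), np.arange(30, 40)],
    ["pathway_with_signal", "null_pathway_1", "null_pathway_2", "null_pathway_3"],
)
config = SGLConfig(fraction_of_lambda_max=0.7, alpha=0.9)

emp = selection_frequencies(genotypes, phenotype, collection, config, B=200, seed=1)
nul = null_frequencies(genotypes, phenotype, collection, config, B=200, seed=2)

print("pathway selection frequencies (empirical / null):")
for name, fe, fn in zip(collection.names, emp.pi_path, nul.pi_path):
    print(f"  {name:22s} {fe:.2f} / {fn:.2f}")
top = np.argsort(-emp.pi_snp)[:3]
print("top SNPs by selection frequency:",
      {f"rs{j}": round(emp.pi_snp[j], 2) for j in top})
print(bias_diagnostics(emp, nul).to_string(index=False))
# The causal SNP rs7 reaches frequency ~1 while null frequencies stay low;
# a strong empirical/null correlation would instead signal selection bias.
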