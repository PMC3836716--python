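"""Remove pathway-size selection bias by permutation-based weight tuning.

One 100-SNP pathway among nine 10-SNP pathways: under a permuted (null)
phenotype the big pathway is first-selected far more often than 1/10.
Tuning the weights flattens that distribution.
"""

import numpy as np

from pathsgl import SGLConfig, SGLProblem, PathwayCollection
from pathsgl.weights import null_first_selection, tune_weights

rng = np.random.default_rng(0)
sizes = (100,) + (10,) * 9
P = sum(sizes)
X = rng.standard_normal((200, P))
X = (X - X.mean(0)) / X.std(0)
y = rng.standard_normal(200)
y -= y.mean()

groups, start = [], 0
for s in sizes:
    groups.append(np.arange(start, start + s))
    start += s
collection = PathwayCollection(groups, [f"p{i}" for i in range(10)], np.ones(10))
problem = SGLProblem(X, y, collection)
config = SGLConfig(alpha=0.9)

before = null_first_selection(problem, config, Q=500, seed=1)
state = tune_weights(problem, config, Q=500, eta=0.3, eps=0.02, max_iter=20, seed=2)
after = null_first_selection(problem, config, Q=500, seed=3, weights=state.weights)

print("null first-selection frequency of the 100-SNP pathway:")
print(f"  before tuning: {before.rho[0]:.2f}   (unbiased would be 0.10)")
print(f"  after  tuning: {after.rho[0]:.2f}")
print(f"max deviation from uniform: {before.max_deviation:.3f} -> "
      f"{after.max_deviation:.3f} in {state.n_iter} iterations")
# The large pathway starts with ~10x the chance of entering first purely
# because it contains more SNPs; after tuning every pathway enters first
# with roughly equal probability under the null.
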