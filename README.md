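# pathsgl

Pathways-driven sparse regression for quantitative-trait GWAS.

Genome-wide association studies test SNPs one at a time and struggle with
variants of small effect. When causal variants cluster in biological
pathways, modelling all SNPs jointly with pathway-structured sparsity can
recover signals that per-SNP tests miss. `pathsgl` implements that
approach for quantitative traits: a sparse group lasso over SNPs grouped
into gene pathways, with machinery for overlapping pathways, selection-bias
removal, resampling-based ranking and cross-cohort comparison of the
resulting ranked lists.

## The model

For a centred trait `y` (covariates regressed out) and a column-standardised
genotype matrix `X` of minor-allele counts, with SNPs mapped to `L` pathways
`G_1..G_L`, the estimator solves

```
min_beta  1/2 ||y − X beta||²
          + lambda (1−alpha) Σ_l w_l ||beta_l||₂
          + lambda alpha ||beta||₁
```

The groupwise l2 term switches whole pathways off (pathway-level sparsity);
the l1 term switches individual SNPs off within selected pathways. `alpha`
splits the budget between the two (`alpha=1` is the lasso, `alpha=0` the
group lasso); `lambda` is specified as a fraction of `lambda_max`, the
smallest penalty at which no pathway enters. Overlapping pathways are
handled by duplicating shared SNP columns once per membership so groups
become block-separable.

Two fitting algorithms are provided:

* **SGL-BCGD** — blockwise coordinate descent on the joint objective;
  the exact minimiser (certified by KKT residuals and convex-solver
  equivalence in the test suite).
* **SGL-CGD** — each pathway screened and fitted against the phenotype
  independently. Overlapping pathways then do not compete: a SNP shared by
  two pathways can be selected in both, which is what pathway-level
  inference wants.

Around the estimator:

* **Weight tuning** (`pathsgl.weights`) — iteratively rescales the pathway
  weights `w_l` until, under phenotype permutation, every pathway is the
  first to enter the model with equal probability, removing pathway-size
  and LD-driven selection bias.
* **Subsampling ranking** (`pathsgl.ranking`) — selection frequencies of
  pathways, SNPs, LD-expanded SNPs (full-sample `r² ≥ 0.8` closure) and
  genes over B half-sample refits, plus permutation-null runs and Pearson
  bias diagnostics.
* **Ranked-list comparison** (`pathsgl.rankcompare`) — top-k Canberra
  distance between two cohorts' rankings, normalised by its random-list
  expectation, with permutation p-values, Benjamini-Hochberg q-values and a
  consensus set at the distance-minimising k.
* **Simulation suite** (`pathsgl.simulate`) — HWE and block-LD genotype
  generators, disjoint/ring pathway structures, two phenotype effect models,
  and runners for three comparative studies (SGL vs size-matched lasso;
  SGL-CGD vs SGL-BCGD on overlapping pathways; ranking strategies on LD
  data with causal SNPs removed).

## Worked example

`examples/01_sparse_group_lasso_fit.py` simulates 400 individuals at 400
SNPs in 20 ring pathways (30 SNPs each, adjacent overlap 10), plants 10
causal SNPs in two adjacent pathways, and fits both algorithms at
`lambda = 0.885 lambda_max`, `alpha = 0.835`:

```
causal pathways: [0, 1], causal SNPs: [10, 12, 13, 16, 19, 24, 27, 31, 34, 39]
SGL-CGD : 2 pathways, 10 SNPs selected (8/10 causal SNPs recovered)
SGL-BCGD: 1 pathways, 6 SNPs selected (4/10 causal SNPs recovered)
```

The independence assumption (CGD) keeps both causal pathways and recovers
8 of the 10 causal SNPs; the joint fit explains the shared signal inside
one pathway and drops the other. The other examples walk through SNP→gene→
pathway mapping from BED/GMT files, weight tuning (a 100-SNP pathway's null
first-selection frequency falls from 0.48 to 0.14), subsample ranking with
bias diagnostics, Canberra comparison of two cohort rankings, and
scaled-down runs of the three studies.

A thin CLI mirrors these steps
(`pathsgl simulate | map | tune-weights | rank | null-rank | compare-ranks`);
run `pathsgl --help`.

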