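"""Subsampling-based selection frequencies and bias diagnostics.

Pathway, SNP and gene importance is measured by how often each variable is
selected when the model is refitted on ``B`` half-samples drawn without
replacement (a pointwise stability-selection style procedure).  Selection
frequencies come in four flavours: per pathway, per SNP, per SNP after LD
expansion (any SNP whose full-sample genotype r-squared with a selected SNP
reaches a threshold counts as selected), and per gene (a gene counts as
selected when any of its mapped SNPs is).  Matched null runs permute the
phenotype once per subsample; correlating empirical against null
frequencies is the selection-bias diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix, PhenotypeTable
from .mapping import PathwayCollection, SnpGeneMap
from .sgl import SGLConfig, SGLProblem, fit_sgl_cgd

__all__ = [
    "SelectionFrequencies",
    "subsample_indices",
    "selection_frequencies",
    "null_frequencies",
    "bias_diagnostics",
]


@dataclass
class SelectionFrequencies:
    """Per-variable selection probabilities over B subsamples."""

    pi_path: np.ndarray
    pi_snp: np.ndarray
    pi_snp_ld: np.ndarray
    pi_gene: pd.Series
    B: int
    fraction: float
    seed: int
    fraction_of_lambda_max: float
    alpha: float
    logs: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for arr in (self.pi_path, self.pi_snp, self.pi_snp_ld):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("selection frequencies must lie in [0, 1]")

    def pathway_table(self, names: list[str]) -> pd.DataFrame:
        order = np.argsort(-self.pi_path, kind="stable")
        return pd.DataFrame(
            {
                "variable_id": [names[i] for i in order],
                "selection_frequency": self.pi_path[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )


def subsample_indices(
    N: int, B: int, fraction: float = 0.5, seed: int = 0
) -> list[np.ndarray]:
    """B independent index sets of size round(fraction*N), without replacement.

    Per-subsample RNG streams are derived from ``(seed, b)`` so individual
    subsamples are reproducible regardless of evaluation order.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    size = int(round(fraction * N))
    return [
        np.sort(np.random.default_rng([seed, b]).choice(N, size=size, replace=False))
        for b in range(B)
    ]


def _standardise_rows(
    G: GenotypeMatrix, rows: np.ndarray, pathways: PathwayCollection
) -> tuple[np.ndarray, PathwayCollection, np.ndarray, np.ndarray]:
    """Standardise the row subset; drop zero-variance SNPs and remap groups.

    Returns (X, remapped collection, original SNP index per column,
    original pathway index per group).
    """
    X = G.values[rows].astype(float)
    sd = X.std(axis=0)
    keep = sd > 0
    orig_snp = np.flatnonzero(keep)
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    new_index = -np.ones(G.n_snps, dtype=np.int64)
    new_index[keep] = np.arange(keep.sum())
    groups, names, orig_pw = [], [], []
    for l, (name, g) in enumerate(zip(pathways.names, pathways.groups)):
        gg = new_index[g]
        gg = gg[gg >= 0]
        if gg.size:
            groups.append(gg)
            names.append(name)
            orig_pw.append(l)
    collection = PathwayCollection(groups, names)
    # carry over tuned weights for surviving pathways (rescaled to new sizes
    # only if SNPs were lost; identical sizes keep the weights exactly)
    w = pathways.weights[np.array(orig_pw, dtype=np.int64)]
    collection = collection.with_weights(w)
    return X, collection, orig_snp, np.array(orig_pw, dtype=np.int64)


def _frequencies(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeTable,
    pathways: PathwayCollection,
    config: SGLConfig,
    B: int,
    fraction: float,
    seed: int,
    r2_threshold: float,
    snp_gene_map: SnpGeneMap | None,
    permute: bool,
) -> SelectionFrequencies:
    if B <= 0:
        raise ValueError("B must be positive")
    if config.fraction_of_lambda_max is None:
        raise ValueError(
            "subsampling requires lambda as a fraction of lambda_max "
            "(it is recomputed on each subsample)"
        )
    N, P = genotypes.values.shape
    L = pathways.n_pathways
    subs = subsample_indices(N, B, fraction, seed)

    # full-sample LD matrix for the closure step (stable across subsamples)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2_full = np.nan_to_num(np.corrcoef(genotypes.values, rowvar=False)) ** 2

    y_full = phenotype.y - phenotype.y.mean()
    if phenotype.covariates is not None:
        C = np.column_stack(
            [np.ones(N), np.asarray(phenotype.covariates, dtype=float)]
        )
        coef, *_ = np.linalg.lstsq(C, phenotype.y, rcond=None)
        y_full = phenotype.y - C @ coef
        y_full = y_full - y_full.mean()

    count_path = np.zeros(L)
    count_snp = np.zeros(P)
    count_ld = np.zeros(P)
    gene_names = sorted(snp_gene_map.gene_to_snps) if snp_gene_map else []
    count_gene = np.zeros(len(gene_names))
    gene_snp_sets = (
        [np.fromiter(snp_gene_map.gene_to_snps[g], dtype=np.int64) for g in gene_names]
        if snp_gene_map
        else []
    )
    logs: list[tuple[np.ndarray, np.ndarray]] = []

    for b, rows in enumerate(subs):
        rng = np.random.default_rng([seed, b, 1])
        X, coll, orig_snp, orig_pw = _standardise_rows(genotypes, rows, pathways)
        y = y_full[rows]
        if permute:
            y = y[rng.permutation(rows.size)]
        y = y - y.mean()
        problem = SGLProblem(X, y, coll)
        fit = fit_sgl_cgd(problem, config)
        sel_pw = orig_pw[np.array(fit.selected_pathways, dtype=np.int64)]
        sel_snp = orig_snp[fit.selected_snps]
        logs.append((sel_pw, sel_snp))
        count_path[sel_pw] += 1
        if sel_snp.size:
            count_snp[sel_snp] += 1
            in_ld = (r2_full[:, sel_snp] >= r2_threshold).any(axis=1)
            in_ld[sel_snp] = True  # closure always contains the selected set
            count_ld[in_ld] += 1
            if gene_snp_sets:
                sel_set = set(sel_snp.tolist())
                for gi, snps in enumerate(gene_snp_sets):
                    if not sel_set.isdisjoint(snps.tolist()):
                        count_gene[gi] += 1

    return SelectionFrequencies(
        pi_path=count_path / B,
        pi_snp=count_snp / B,
        pi_snp_ld=count_ld / B,
        pi_gene=pd.Series(count_gene / B, index=gene_names),
        B=B,
        fraction=fraction,
        seed=seed,
        fraction_of_lambda_max=float(config.fraction_of_lambda_max),
        alpha=config.alpha,
        logs=logs,
    )


def selection_frequencies(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeTable,
    pathways: PathwayCollection,
    config: SGLConfig,
    B: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
    r2_threshold: float = 0.8,
    snp_gene_map: SnpGeneMap | None = None,
) -> SelectionFrequencies:
    """Empirical pathway/SNP/LD-SNP/gene selection frequencies.

    At each of ``B`` subsamples (size ``round(fraction * N)``, drawn without
    replacement) the genotypes are re-standardised, ``lambda_max`` is
    recomputed on the subsample, and SGL-CGD is fitted at the configured
    fraction of it.  Frequencies are the per-variable selection rates across
    subsamples; the LD expansion adds every SNP whose full-sample genotype
    ``r^2`` with a selected SNP reaches ``r2_threshold``.
    """
    return _frequencies(
        genotypes,
        phenotype,
        pathways,
        config,
        B,
        fraction,
        seed,
        r2_threshold,
        snp_gene_map,
        permute=False,
    )


def null_frequencies(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeTable,
    pathways: PathwayCollection,
    config: SGLConfig,
    B: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
    r2_threshold: float = 0.8,
    snp_gene_map: SnpGeneMap | None = None,
) -> SelectionFrequencies:
    """Null selection frequencies: phenotype permuted once per subsample."""
    return _frequencies(
        genotypes,
        phenotype,
        pathways,
        config,
        B,
        fraction,
        seed,
        r2_threshold,
        snp_gene_map,
        permute=True,
    )


def bias_diagnostics(
    empirical: SelectionFrequencies, null: SelectionFrequencies
) -> pd.DataFrame:
    """Pearson correlation between empirical and null selection frequencies.

    Computed over all pathways, and over SNPs with nonzero empirical
    frequency only (most SNPs are never selected).  Degenerate (constant)
    vectors yield ``NaN`` with a note instead of a correlation.
    """
    rows = []
    for label, x, y in (
        ("pathways", empirical.pi_path, null.pi_path),
        ("snps_nonzero_empirical", empirical.pi_snp, null.pi_snp),
    ):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if label.startswith("snps"):
            mask = x > 0
            x, y = x[mask], y[mask]
        if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(
                {"variables": label, "n": int(x.size), "r": np.nan, "p_value": np.nan,
                 "note": "not computable (constant or too short)"}
            )
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"variables": label, "n": int(x.size), "r": r, "p_value": p, "note": ""})
    return pd.DataFrame(rows)
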