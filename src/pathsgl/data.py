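"""Core in-memory containers shared across the package.

The containers are deliberately thin: a :class:`GenotypeMatrix` is a numpy
array of minor-allele counts plus SNP metadata, a :class:`PhenotypeTable`
holds one quantitative trait and optional covariates, and the gene-set /
annotation types are light wrappers used by the SNP-to-pathway mapping step.
Statistics live elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "GeneSetCollection",
    "GeneAnnotation",
]


@dataclass
class GenotypeMatrix:
    """N x P matrix of minor-allele counts with per-SNP metadata.

    Parameters
    ----------
    values
        Array of shape (N, P). Entries are 0/1/2 allele counts on load and
        real-valued after column standardisation.
    snp_ids
        P unique SNP identifiers.
    chrom, pos
        Optional per-SNP genomic coordinates (1-based positions).
    sample_ids
        Optional N row labels, aligned with any :class:`PhenotypeTable`.
    standardized
        True once columns have been centred and scaled to unit variance.
        Readers never set this flag.
    """

    values: np.ndarray
    snp_ids: list[str]
    chrom: list[str] | None = None
    pos: np.ndarray | None = None
    sample_ids: list[str] | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        if len(self.snp_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.snp_ids)} SNP ids for {self.values.shape[1]} columns"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("SNP ids must be unique")
        if np.isnan(self.values).any():
            raise ValueError("genotype matrix contains missing values")
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=np.int64)
            if self.chrom is None or len(self.chrom) != len(self.snp_ids):
                raise ValueError("chrom/pos metadata must cover every SNP")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def check_standardized(self, tol: float = 1e-8) -> None:
        """Raise unless every column has mean 0 and variance 1 within ``tol``."""
        mu = self.values.mean(axis=0)
        var = self.values.var(axis=0)
        if np.abs(mu).max(initial=0.0) > tol or np.abs(var - 1).max(initial=0.0) > tol:
            raise ValueError("matrix is not column-standardised")


@dataclass
class PhenotypeTable:
    """Quantitative trait plus optional covariates for N samples."""

    y: np.ndarray
    covariates: pd.DataFrame | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if np.isnan(self.y).any():
            raise ValueError("phenotype contains missing values")
        if self.covariates is not None:
            cov = np.asarray(self.covariates, dtype=float)
            if cov.shape[0] != self.y.shape[0]:
                raise ValueError("covariate rows do not match phenotype length")
            if not np.isfinite(cov).all():
                raise ValueError("covariates contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.y.shape[0]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. one KEGG pathway per set)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class GeneAnnotation:
    """Gene coordinates, 1-based inclusive on both ends."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("gene", "chrom", "start", "end")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"annotation missing column {col!r}")
        if (self.table["start"] > self.table["end"]).any():
            bad = self.table[self.table["start"] > self.table["end"]]
            raise ValueError(f"annotation has start > end for {bad['gene'].tolist()}")

    def __len__(self) -> int:
        return len(self.table)
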