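"""SNP-to-gene and gene-to-pathway mapping.

SNPs are assigned to every gene whose transcribed region, extended by a
symmetric distance window (default 10 kb), covers the SNP position, on the
same chromosome.  Gene sets are then translated into pathways in SNP-index
space; since genes map to multiple pathways, the resulting groups overlap.
The overlap-expansion step duplicates SNP columns once per pathway membership
so that the groups become disjoint in the expanded design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GeneAnnotation, GeneSetCollection, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SnpGeneMap",
    "PathwayCollection",
    "ExpandedIndex",
    "map_snps_to_genes",
    "build_pathways",
    "expand",
]

DEFAULT_WINDOW_BP = 10_000


@dataclass
class SnpGeneMap:
    """Bidirectional SNP <-> gene edges (a SNP may map to 0..many genes)."""

    snp_to_genes: dict[int, set[str]]
    gene_to_snps: dict[str, set[int]]
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        # the two directions must describe the same edge set
        edges_fwd = {(s, g) for s, gs in self.snp_to_genes.items() for g in gs}
        edges_rev = {(s, g) for g, ss in self.gene_to_snps.items() for s in ss}
        if edges_fwd != edges_rev:
            raise ValueError("snp->gene and gene->snp maps are inconsistent")


@dataclass
class PathwayCollection:
    """L named groups of SNP indices, possibly overlapping, with weights w_l.

    Weights default to sqrt(group size), the standard group-lasso size
    normalisation; the bias-reduction loop later rescales them
    multiplicatively.
    """

    groups: list[np.ndarray]
    names: list[str]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.groups = [np.asarray(g, dtype=np.int64) for g in self.groups]
        if len(self.names) != len(self.groups):
            raise ValueError("one name per group required")
        for name, g in zip(self.names, self.groups):
            if g.size == 0:
                raise ValueError(f"pathway {name!r} is empty")
        if self.weights is None:
            self.weights = np.sqrt(self.sizes.astype(float))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.groups),):
                raise ValueError("one weight per group required")
            if not (self.weights > 0).all():
                raise ValueError("pathway weights must be strictly positive")

    @property
    def n_pathways(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([g.size for g in self.groups], dtype=np.int64)

    @property
    def snp_universe(self) -> np.ndarray:
        """Sorted unique SNP indices covered by any pathway."""
        return np.unique(np.concatenate(self.groups))

    def with_weights(self, weights: np.ndarray) -> "PathwayCollection":
        return PathwayCollection(self.groups, self.names, np.asarray(weights, float))


@dataclass
class ExpandedIndex:
    """Column bookkeeping for the overlap expansion.

    ``col_to_snp[c]`` is the original SNP index behind expanded column ``c``
    and ``col_to_pathway[c]`` the pathway it was duplicated for.  Restricting
    the expanded columns to one pathway recovers that pathway's SNP list
    exactly, and the inverse map is total, so collapsing any set of selected
    expanded columns yields the unexpanded selected-SNP set.
    """

    col_to_snp: np.ndarray
    col_to_pathway: np.ndarray
    group_slices: list[slice]

    @property
    def n_expanded(self) -> int:
        return self.col_to_snp.size

    def collapse(self, expanded_cols: np.ndarray) -> np.ndarray:
        """Map expanded column indices back to unique original SNP indices."""
        cols = np.asarray(expanded_cols, dtype=np.int64)
        return np.unique(self.col_to_snp[cols])


def map_snps_to_genes(
    annotation: GeneAnnotation,
    genotypes: GenotypeMatrix,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> SnpGeneMap:
    """Map each SNP to all genes within ``window_bp`` of its position.

    SNP ``s`` maps to gene ``g`` iff ``pos(s)`` lies in the closed interval
    ``[start(g) - window_bp, end(g) + window_bp]`` and both are on the same
    chromosome.  SNPs lacking coordinates are excluded (counted in
    ``n_unmapped`` and logged).
    """
    if window_bp < 0:
        raise ValueError("window_bp must be nonnegative")
    snp_to_genes: dict[int, set[str]] = {}
    gene_to_snps: dict[str, set[int]] = {}
    if genotypes.pos is None:
        raise ValueError("genotype matrix has no SNP coordinates")
    pos = genotypes.pos
    chrom = np.asarray(genotypes.chrom)
    has_coord = pos >= 0
    n_unmapped = int((~has_coord).sum())
    if n_unmapped:
        warnings.warn(f"{n_unmapped} SNPs lack coordinates and were excluded")

    tab = annotation.table
    for c in np.unique(chrom[has_coord]):
        on_c = np.where(has_coord & (chrom == c))[0]
        genes_c = tab[tab["chrom"] == c]
        for _, row in genes_c.iterrows():
            lo = row["start"] - window_bp
            hi = row["end"] + window_bp
            hit = on_c[(pos[on_c] >= lo) & (pos[on_c] <= hi)]
            if hit.size == 0:
                continue
            gene_to_snps.setdefault(row["gene"], set()).update(hit.tolist())
            for s in hit:
                snp_to_genes.setdefault(int(s), set()).add(row["gene"])
    return SnpGeneMap(snp_to_genes, gene_to_snps, n_unmapped)


def build_pathways(
    snp_gene_map: SnpGeneMap,
    gene_sets: GeneSetCollection,
    exclude: list[str] | None = None,
) -> tuple[PathwayCollection, pd.DataFrame]:
    """Translate gene sets into SNP-index pathways.

    Each pathway is the union of the SNP indices of its member genes that
    have at least one mapped SNP.  Gene symbol matching is exact and
    case-sensitive.  Sets named in ``exclude`` (e.g. the largest, highly
    redundant pathway) and sets left with no mapped SNPs are dropped.

    Returns the collection plus a one-column summary table of mapping
    statistics (mapped SNPs/genes/pathways, per-pathway size extremes, and
    the maximum number of pathways any single SNP maps to).
    """
    exclude = set(exclude or [])
    groups: list[np.ndarray] = []
    names: list[str] = []
    for name, genes in gene_sets.sets.items():
        if name in exclude:
            continue
        snps: set[int] = set()
        for g in genes:
            snps.update(snp_gene_map.gene_to_snps.get(g, ()))
        if snps:
            groups.append(np.array(sorted(snps), dtype=np.int64))
            names.append(name)
        else:
            logger.info("pathway %s dropped: no mapped SNPs", name)
    if not groups:
        raise ValueError("no pathway has any mapped SNPs")
    collection = PathwayCollection(groups, names)

    counts = np.zeros(int(max(g.max() for g in groups)) + 1, dtype=int)
    for g in groups:
        counts[g] += 1
    retained = set(names)
    genes_with_snps = {
        g
        for name, genes in gene_sets.sets.items()
        if name in retained
        for g in genes
        if snp_gene_map.gene_to_snps.get(g)
    }
    summary = pd.DataFrame(
        {
            "value": [
                int(collection.snp_universe.size),
                len(genes_with_snps),  # genes contributing SNPs to a retained pathway
                collection.n_pathways,
                int(collection.sizes.min()),
                int(collection.sizes.max()),
                int(counts.max()),
            ]
        },
        index=[
            "total SNPs mapping to pathways",
            "total mapped genes",
            "total mapped pathways",
            "minimum SNPs in a single pathway",
            "maximum SNPs in a single pathway",
            "maximum pathways mapping to a single SNP",
        ],
    )
    return collection, summary


def expand(collection: PathwayCollection) -> ExpandedIndex:
    """Duplicate SNP columns once per pathway membership.

    The expanded design has P' = sum_l P_l columns; group ``l`` occupies the
    contiguous slice ``group_slices[l]``, within which the column order is
    exactly ``collection.groups[l]``.
    """
    col_to_snp = np.concatenate(collection.groups)
    col_to_pathway = np.concatenate(
        [np.full(g.size, l, dtype=np.int64) for l, g in enumerate(collection.groups)]
    )
    slices = []
    start = 0
    for g in collection.groups:
        slices.append(slice(start, start + g.size))
        start += g.size
    return ExpandedIndex(col_to_snp, col_to_pathway, slices)
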