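"""Readers and writers for the external file formats.

Supported formats: delimited genotype/phenotype tables (TSV/CSV with a
header row), the PLINK ``.raw`` text dialect, GMT gene sets, BED gene
annotation (0-based half-open on disk, converted to 1-based inclusive
internally), JSON pathway collections and TSV ranking files.  No statistics
live here; readers never standardise and never set the ``standardized``
flag.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import GeneAnnotation, GeneSetCollection, GenotypeMatrix, PhenotypeTable
from .mapping import PathwayCollection
from .rankcompare import RankedList

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_phenotype",
    "read_gmt",
    "read_annotation",
    "write_ranking",
    "read_ranking",
    "write_pathways",
    "read_pathways",
    "load_config",
    "save_config",
]

PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _detect_sep(path: Path) -> str:
    """Pick the delimiter from the header line (tab, comma or whitespace)."""
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def _validate_counts(
    df: pd.DataFrame, impute_missing: bool, sample_ids: list[str]
) -> np.ndarray:
    values = df.to_numpy(dtype=float)
    missing = np.isnan(values)
    if missing.any() and not impute_missing:
        i, j = np.argwhere(missing)[0]
        raise ValueError(
            f"missing genotype for SNP {df.columns[j]!r}, sample "
            f"{sample_ids[i]!r} (pass impute_missing=True to mean-impute)"
        )
    observed = values[~missing]
    if not np.isin(observed, (0.0, 1.0, 2.0)).all():
        bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][0]
        raise ValueError(f"non-integer or out-of-range allele count: {bad!r}")
    if missing.any():
        col_mean = np.nanmean(values, axis=0)
        values = np.where(missing, np.broadcast_to(col_mean, values.shape), values)
    return values


def read_genotypes(
    path: str | Path,
    format: str = "delimited",
    impute_missing: bool = False,
    sep: str | None = None,
) -> GenotypeMatrix:
    """Read a minor-allele-count matrix.

    ``delimited``: header row of SNP ids; an optional first column named
    ``sample_id`` supplies row labels.  ``plink_raw``: whitespace-separated
    PLINK export with the six standard metadata columns and SNP columns
    named ``<id>_<allele>``.  Missing entries ("NA" or empty) raise unless
    ``impute_missing`` is set, in which case they are replaced by the SNP's
    column mean.
    """
    path = Path(path)
    if format == "delimited":
        df = pd.read_csv(path, sep=sep or _detect_sep(path))
        if df.columns[0].lower() in ("sample_id", "sample", "iid"):
            df = df.set_index(df.columns[0])
            sample_ids = [str(s) for s in df.index]
        else:
            sample_ids = [str(i) for i in range(len(df))]
        values = _validate_counts(df, impute_missing, sample_ids)
        return GenotypeMatrix(
            values, [str(c) for c in df.columns], sample_ids=sample_ids
        )
    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        for col in PLINK_META_COLS:
            if col not in df.columns:
                raise ValueError(f"plink_raw file lacks metadata column {col!r}")
        sample_ids = [str(s) for s in df["IID"]]
        geno = df.drop(columns=PLINK_META_COLS)
        snp_ids = [c.rsplit("_", 1)[0] for c in geno.columns]
        values = _validate_counts(geno, impute_missing, sample_ids)
        return GenotypeMatrix(values, snp_ids, sample_ids=sample_ids)
    raise ValueError(f"unknown genotype format {format!r}")


def read_phenotype(
    path: str | Path,
    trait: str,
    covariates: list[str] | None = None,
    sample_col: str | None = None,
    sep: str | None = None,
) -> PhenotypeTable:
    """Read a quantitative trait (and optional covariates) from a table."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _detect_sep(path))
    sample_ids = (
        [str(s) for s in df[sample_col]] if sample_col else [str(i) for i in df.index]
    )
    cov = df[covariates] if covariates else None
    return PhenotypeTable(
        df[trait].to_numpy(dtype=float), covariates=cov, sample_ids=sample_ids
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT: one set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``; duplicate genes within
    a set are collapsed (first occurrence kept)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
    return GeneSetCollection(sets, source=str(path))


def read_annotation(path: str | Path, sep: str = "\t") -> GeneAnnotation:
    """Read BED-like gene annotation: chrom, start, end, symbol.

    On disk coordinates are 0-based half-open (BED); internally they become
    1-based inclusive: ``start + 1 .. end``.
    """
    df = pd.read_csv(
        Path(path),
        sep=sep,
        header=None,
        names=["chrom", "start", "end", "gene"],
        comment="#",
    )
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64)
    return GeneAnnotation(df[["gene", "chrom", "start", "end"]])


def write_ranking(
    ranked: RankedList,
    path: str | Path,
    frequencies: dict[str, float] | None = None,
) -> None:
    """Write a ranking as TSV (variable_id, selection_frequency, rank).

    Unranked items are written with the sentinel rank ``p*+1`` so the
    round-trip is lossless."""
    rows = [
        {
            "variable_id": u,
            "selection_frequency": (frequencies or {}).get(u, np.nan),
            "rank": int(r),
        }
        for u, r in zip(ranked.universe, ranked.ranks)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ranking(path: str | Path) -> RankedList:
    """Read a ranking TSV written by :func:`write_ranking`."""
    df = pd.read_csv(Path(path), sep="\t")
    return RankedList(
        [str(v) for v in df["variable_id"]], df["rank"].to_numpy(dtype=np.int64)
    )


def write_pathways(collection: PathwayCollection, path: str | Path) -> None:
    """Serialise a pathway collection (SNP index groups + weights) as JSON."""
    payload = {
        "names": collection.names,
        "groups": [g.tolist() for g in collection.groups],
        "weights": collection.weights.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_pathways(path: str | Path) -> PathwayCollection:
    payload = json.loads(Path(path).read_text())
    return PathwayCollection(
        [np.asarray(g, dtype=np.int64) for g in payload["groups"]],
        payload["names"],
        np.asarray(payload["weights"], dtype=float),
    )


def load_config(path: str | Path) -> dict:
    """Load a structured YAML config (SGLConfig / SimScenario fields)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
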