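"""Readers and writers for the package's external text formats.

Two dialects are supported for pooled read counts:

* ``tsv`` -- header line ``chrom  pos  snp_id  <pop>_ref  <pop>_alt ...``,
  one row per SNP;
* ``genobaypass`` -- the layout used by Pool-Seq Bayesian GEA software:
  one line per SNP of space-separated ``ref alt`` pairs in population
  order, no header, with companion files for haploid pool sizes (one line
  of J integers) and covariates (one line per covariate, J values).

Gene models come from GFF3 (``gene`` features only); annotations,
coordinates and scan results are plain TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_CHROM_ORDER,
    AnnotationTable,
    CovariateSet,
    GeneModels,
    PoolSeqMatrix,
    PopulationSet,
    ValidationError,
)


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# pooled read counts
# ---------------------------------------------------------------------------

def read_pool_counts(
    path: str | os.PathLike,
    dialect: str = "tsv",
    pop_ids: list[str] | None = None,
    chrom_order: tuple[str, ...] = DEFAULT_CHROM_ORDER,
) -> PoolSeqMatrix:
    """Read a SNP x population ref/alt count matrix.

    For the ``genobaypass`` dialect, which carries no coordinates, SNPs are
    assigned to chromosome ``"1"`` at consecutive positions (their file
    order *is* their genome order).
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_counts_tsv(path, chrom_order)
    if dialect == "genobaypass":
        return _read_counts_genobaypass(path, pop_ids, chrom_order)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_counts_tsv(path: Path, chrom_order) -> PoolSeqMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    key_cols = ["chrom", "pos", "snp_id"]
    for c in key_cols:
        if c not in df.columns:
            raise ParseError(f"{path}: missing column {c!r}")
    count_cols = [c for c in df.columns if c not in key_cols]
    pops: list[str] = []
    for c in count_cols:
        if c.endswith("_ref"):
            pops.append(c[:-4])
        elif not c.endswith("_alt"):
            raise ParseError(f"{path}: unexpected column {c!r}")
    for p in pops:
        if f"{p}_alt" not in df.columns:
            raise ParseError(f"{path}: missing column {p}_alt")
    ref = df[[f"{p}_ref" for p in pops]].to_numpy()
    alt = df[[f"{p}_alt" for p in pops]].to_numpy()
    if (ref < 0).any() or (alt < 0).any():
        raise ValidationError(f"{path}: negative read count")
    return PoolSeqMatrix(
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(),
        ref_count=ref,
        alt_count=alt,
        pop_ids=pops,
        chrom_order=chrom_order,
    )


def _read_counts_genobaypass(path: Path, pop_ids, chrom_order) -> PoolSeqMatrix:
    refs, alts = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) % 2:
                raise ParseError(
                    f"{path}:{lineno}: odd number of fields "
                    f"({len(fields)}); expected ref/alt pairs"
                )
            try:
                vals = [int(v) for v in fields]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if any(v < 0 for v in vals):
                raise ValidationError(f"{path}:{lineno}: negative read count")
            refs.append(vals[0::2])
            alts.append(vals[1::2])
    ref = np.array(refs, dtype=np.int64) if refs else np.empty((0, 0), np.int64)
    alt = np.array(alts, dtype=np.int64) if alts else np.empty((0, 0), np.int64)
    n, j = ref.shape
    if pop_ids is None:
        pop_ids = [f"pop{i + 1}" for i in range(j)]
    elif len(pop_ids) != j:
        raise ParseError(f"{path}: {j} populations in file, {len(pop_ids)} ids given")
    return PoolSeqMatrix(
        snp_ids=np.array([f"snp{i + 1}" for i in range(n)], dtype=object),
        chrom=np.array(["1"] * n, dtype=object),
        pos=np.arange(1, n + 1, dtype=np.int64),
        ref_count=ref,
        alt_count=alt,
        pop_ids=list(pop_ids),
        chrom_order=chrom_order,
    )


def write_pool_counts(
    matrix: PoolSeqMatrix, path: str | os.PathLike, dialect: str = "tsv"
) -> None:
    path = Path(path)
    if dialect == "tsv":
        data = {
            "chrom": matrix.chrom,
            "pos": matrix.pos,
            "snp_id": matrix.snp_ids,
        }
        for j, p in enumerate(matrix.pop_ids):
            data[f"{p}_ref"] = matrix.ref_count[:, j]
            data[f"{p}_alt"] = matrix.alt_count[:, j]
        pd.DataFrame(data).to_csv(path, sep="\t", index=False)
    elif dialect == "genobaypass":
        with open(path, "w") as fh:
            for i in range(matrix.n_snps):
                pairs = np.empty(2 * matrix.n_pops, dtype=np.int64)
                pairs[0::2] = matrix.ref_count[i]
                pairs[1::2] = matrix.alt_count[i]
                fh.write(" ".join(map(str, pairs)) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# companion tables
# ---------------------------------------------------------------------------

def read_pool_sizes(path: str | os.PathLike, pop_ids=None) -> PopulationSet:
    """Haploid pool sizes: a single line of J integers."""
    sizes = np.loadtxt(path, dtype=np.int64, ndmin=1)
    if sizes.ndim > 1:
        sizes = sizes.ravel()
    if pop_ids is None:
        pop_ids = [f"pop{i + 1}" for i in range(len(sizes))]
    return PopulationSet(pop_ids=pop_ids, haploid_pool_size=sizes)


def write_pool_sizes(pops: PopulationSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(map(str, pops.haploid_pool_size)) + "\n")


def read_covariates_baypass(path: str | os.PathLike, names=None) -> CovariateSet:
    """Covariates in the one-line-per-covariate layout."""
    vals = np.loadtxt(path, ndmin=2)
    if names is None:
        names = [f"cov{i + 1}" for i in range(vals.shape[0])]
    return CovariateSet(names=list(names), values=vals.T)


def write_covariates_baypass(cov: CovariateSet, path: str | os.PathLike) -> None:
    np.savetxt(path, cov.values.T, fmt="%.10g")


def read_covariates_tsv(path: str | os.PathLike) -> CovariateSet:
    """Covariate TSV: first column ``pop_id``, one column per covariate."""
    df = pd.read_csv(path, sep="\t")
    pop_ids = df.iloc[:, 0].astype(str).tolist()
    names = list(df.columns[1:])
    return CovariateSet(names=names, values=df[names].to_numpy(float), pop_ids=pop_ids)


def read_annotation_table(path: str | os.PathLike) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t")
    return AnnotationTable(
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        category=df["category"].to_numpy(dtype=object),
    )


def write_annotation_table(annot: AnnotationTable, path: str | os.PathLike) -> None:
    pd.DataFrame({"snp_id": annot.snp_ids, "category": annot.category}).to_csv(
        path, sep="\t", index=False
    )


def read_coordinates(path: str | os.PathLike) -> PopulationSet:
    """Population coordinate TSV: pop_id, latitude, longitude[, pool_size]."""
    df = pd.read_csv(path, sep="\t")
    sizes = (
        df["haploid_pool_size"].to_numpy()
        if "haploid_pool_size" in df.columns
        else np.full(len(df), 2, dtype=np.int64)
    )
    return PopulationSet(
        pop_ids=df["pop_id"].astype(str).tolist(),
        haploid_pool_size=sizes,
        latitude=df["latitude"].to_numpy(float),
        longitude=df["longitude"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# scan results
# ---------------------------------------------------------------------------

SCAN_COLUMNS = ["chrom", "pos", "snp_id", "beta", "bf_db", "xtx", "pip"]


def write_scan_results(result, path: str | os.PathLike) -> None:
    """Write an association-scan result as a TSV (one row per SNP)."""
    df = result.to_frame()
    df[SCAN_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_scan_results(path: str | os.PathLike):
    from .model.aux import AuxScanResult

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for c in SCAN_COLUMNS:
        if c not in df.columns:
            raise ParseError(f"{path}: missing column {c!r}")
    return AuxScanResult(
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(),
        beta=df["beta"].to_numpy(float),
        bf_db=df["bf_db"].to_numpy(float),
        xtx=df["xtx"].to_numpy(float),
        pip=df["pip"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike) -> GeneModels:
    """Extract ``gene`` features from a GFF3 file.

    Only the gene records are kept (mRNAs, exons etc. are ignored); each
    must carry an ``ID`` attribute.
    """
    gene_ids, chroms, starts, ends, strands = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise ParseError(f"{path}:{lineno}: gene feature without ID attribute")
            gene_ids.append(attrs["ID"])
            chroms.append(fields[0])
            starts.append(int(fields[3]))
            ends.append(int(fields[4]))
            strands.append(fields[6])
    return GeneModels(
        gene_id=np.array(gene_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        strand=np.array(strands, dtype=object),
    )
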