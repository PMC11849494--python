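"""Readers/writers for the tabular formats the pipeline touches.

Expression matrices are plain TSV, genes in rows and samples in columns (or the
transpose, via ``orientation``).  Gene sets are GMT.  TSS annotation is BED6 with
0-based half-open coordinates; the TSS is ``start`` on the + strand and ``end - 1``
on the - strand.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("integrinscore")

__all__ = [
    "FormatError",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_clinical_tsv",
    "write_table_tsv",
    "read_gmt",
    "write_gmt",
    "read_tss_annotation",
]

#: float format for expression matrices -- wide enough to round-trip to 1e-12
MATRIX_FLOAT_FORMAT = "%.12g"
#: float format for derived result tables -- compact, diff-friendly
TABLE_FLOAT_FORMAT = "%.6g"

CLINICAL_REQUIRED = ("sample", "cancer_type", "os_time", "os_event")


class FormatError(ValueError):
    """Raised for malformed input files, naming the offending field."""


def _check_duplicates(index: pd.Index, what: str) -> None:
    dup = index[index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate {what} identifier(s): {sorted(set(dup.astype(str)))}")


def read_matrix_tsv(path: str | Path, orientation: str = "genes_by_samples") -> pd.DataFrame:
    """Read a gene-by-sample abundance matrix from TSV.

    Parameters
    ----------
    path : file with first row sample ids, first column gene ids.
    orientation : ``"genes_by_samples"`` (default) or ``"samples_by_genes"``;
        the returned frame is always genes (rows) by samples (columns).
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "samples_by_genes":
        df = df.T
    _check_duplicates(df.index, "gene")
    _check_duplicates(df.columns, "sample")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & df.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric value {df.iat[gi, si]!r} at gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r}"
        )
    if values.isna().to_numpy().any():
        gi, si = np.argwhere(values.isna().to_numpy())[0]
        raise FormatError(f"missing value at gene {df.index[gi]!r}, sample {df.columns[si]!r}")
    arr = values.to_numpy(float)
    if not np.isfinite(arr).all():
        raise FormatError("matrix contains non-finite values")
    if (arr < 0).any():
        gi, si = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"negative abundance at gene {values.index[gi]!r}, sample {values.columns[si]!r}"
        )
    if values.shape[0] < 1 or values.shape[1] < 2:
        raise FormatError(
            f"matrix must have at least 1 gene and 2 samples, got shape {values.shape}"
        )
    return values.astype(float)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as TSV with enough digits to round-trip to 1e-12."""
    matrix.to_csv(path, sep="\t", float_format=MATRIX_FLOAT_FORMAT, index_label="gene")


def write_table_tsv(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a derived result table with compact 6-significant-digit floats."""
    table.to_csv(path, sep="\t", float_format=TABLE_FLOAT_FORMAT, index=index)


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    """Read a clinical table (sample, cancer_type, os/pfs time and event columns).

    Missing values are encoded as empty fields; rows lacking an endpoint are kept
    here and dropped per analysis downstream with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "cancer_type": str})
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing required column(s): {missing}")
    _check_duplicates(pd.Index(df["sample"]), "sample")
    if df["cancer_type"].isna().any():
        raise FormatError("every sample must have a cancer_type")
    for col in df.columns:
        if col.endswith("_time"):
            t = pd.to_numeric(df[col], errors="raise")
            if (t.dropna() < 0).any():
                raise FormatError(f"negative time in column {col!r}")
            df[col] = t
        elif col.endswith("_event"):
            e = pd.to_numeric(df[col], errors="raise")
            if not e.dropna().isin([0, 1]).all():
                raise FormatError(f"events in column {col!r} must be 0 or 1")
            df[col] = e
    return df


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file into an ordered name -> gene-list mapping.

    Duplicate genes within a set are removed (first occurrence kept); duplicate set
    names are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected name, description and >=1 gene, "
                    f"got {len(fields)} field(s)"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"GMT line {lineno}: set {name!r} is empty")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_tss_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file of gene bodies and derive one TSS per gene.

    BED is 0-based half-open, so the TSS is ``start`` for + strand genes and
    ``end - 1`` for - strand genes.  Returns columns (gene, chrom, tss, strand).
    """
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene", "score", "strand"],
        dtype={"chrom": str, "gene": str, "strand": str},
    )
    bad_strand = ~bed["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(
            f"strand must be '+' or '-', got {bed.loc[bad_strand, 'strand'].iloc[0]!r} "
            f"for gene {bed.loc[bad_strand, 'gene'].iloc[0]!r}"
        )
    bad_coords = bed["start"] >= bed["end"]
    if bad_coords.any():
        g = bed.loc[bad_coords, "gene"].iloc[0]
        raise FormatError(f"start >= end for gene {g!r}")
    _check_duplicates(pd.Index(bed["gene"]), "gene")
    tss = np.where(bed["strand"] == "+", bed["start"], bed["end"] - 1)
    return pd.DataFrame(
        {"gene": bed["gene"], "chrom": bed["chrom"], "tss": tss, "strand": bed["strand"]}
    )
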