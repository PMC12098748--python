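"""Readers and writers for the standard on-disk formats the pipeline touches.

Supported formats:

* MatrixMarket triplet directories (``matrix.mtx[.gz]`` + ``features.tsv`` /
  ``genes.tsv`` + ``barcodes.tsv``, optionally gzipped) — the 10x-style layout.
* GMT gene-set collections (tab-separated: name, description, members...).
* Spot position CSVs in the 10x ``tissue_positions`` dialects, with or without
  a header line.
* BED-like gene position TSVs (chrom, start, end, symbol; 0-based half-open).

Duplicate gene symbols on read are disambiguated deterministically by
appending ``.k`` for the k-th repeat occurrence (``X``, ``X.1``, ``X.2``...).
Gene symbols are case-sensitive throughout: human (upper-case) and mouse
(title-case) symbols must never be silently folded together.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .containers import ExpressionMatrix, GeneAnnotation

__all__ = [
    "FormatError",
    "read_matrix_market_triplet",
    "write_matrix_market_triplet",
    "read_gmt",
    "write_gmt",
    "read_spot_positions",
    "write_spot_positions",
    "read_gene_annotation",
    "write_gene_annotation",
    "make_unique",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def make_unique(symbols: list[str]) -> list[str]:
    """Deterministically disambiguate repeated symbols: X, X.1, X.2, ..."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        k = seen.get(s, 0)
        seen[s] = k + 1
        out.append(s if k == 0 else f"{s}.{k}")
    return out


def _find_file(directory: Path, stems: list[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FormatError(f"none of {stems} found in {directory}")


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").rstrip("\r") for line in fh if line.strip() != ""]


def read_matrix_market_triplet(directory: str | os.PathLike) -> ExpressionMatrix:
    """Read a 10x-style MatrixMarket triplet directory into an ExpressionMatrix.

    The directory must contain ``matrix.mtx(.gz)``, ``features.tsv(.gz)`` or
    ``genes.tsv(.gz)``, and ``barcodes.tsv(.gz)``.  Gene symbols come from the
    second column of the features file when present, else the first.
    """
    directory = Path(directory)
    mtx_path = _find_file(directory, ["matrix.mtx"])
    feat_path = _find_file(directory, ["features.tsv", "genes.tsv"])
    bc_path = _find_file(directory, ["barcodes.tsv"])

    mat = mmread(str(mtx_path))
    mat = sp.csr_matrix(mat)

    feat_lines = _read_lines(feat_path)
    symbols = []
    for line in feat_lines:
        fields = line.split("\t")
        symbols.append(fields[1] if len(fields) >= 2 else fields[0])
    barcodes = [line.split("\t")[0] for line in _read_lines(bc_path)]

    if len(symbols) != mat.shape[0]:
        raise FormatError(
            f"{feat_path.name}: {len(symbols)} features but matrix has {mat.shape[0]} rows"
        )
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"{bc_path.name}: {len(barcodes)} barcodes but matrix has {mat.shape[1]} columns"
        )
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{mtx_path.name}: negative counts")

    return ExpressionMatrix(
        genes=make_unique(symbols),
        observations=make_unique(barcodes),
        counts=mat,
    )


def write_matrix_market_triplet(matrix: ExpressionMatrix, directory: str | os.PathLike) -> None:
    """Write an ExpressionMatrix as matrix.mtx + features.tsv + barcodes.tsv.

    Values are written as integers when all entries are integral, else as
    decimals, so count and normalized matrices share one writer.  The output
    round-trips through :func:`read_matrix_market_triplet`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(matrix.counts)
    if coo.nnz == 0 or np.all(coo.data == np.round(coo.data)):
        coo = sp.coo_matrix(
            (coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape
        )
        mmwrite(str(directory / "matrix.mtx"), coo, field="integer")
    else:
        mmwrite(str(directory / "matrix.mtx"), coo)
    with open(directory / "features.tsv", "w") as fh:
        for g in matrix.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for b in matrix.observations:
            fh.write(b + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file into {set name: ordered unique member list}.

    Descriptions (second field) are discarded.  Within a set the first
    occurrence of a repeated member is kept.  A repeated set name or a line
    with fewer than three fields is a format error.
    """
    collection: dict[str, list[str]] = {}
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if line == "":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path.name}:{lineno}: fewer than 3 tab-separated fields")
            name = fields[0]
            if name in collection:
                raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            for m in fields[2:]:
                if m != "" and m not in seen:
                    members.append(m)
                    seen.add(m)
            if not members:
                raise FormatError(f"{path.name}:{lineno}: set {name!r} has no members")
            collection[name] = members
    return collection


def write_gmt(collection: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write(name + "\t" + name + "\t" + "\t".join(members) + "\n")


_POSITIONS_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pixel_row",
    "pixel_col",
]


def read_spot_positions(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tissue_positions CSV (header or headerless dialect).

    Returns a DataFrame indexed by barcode with columns ``in_tissue``,
    ``array_row``, ``array_col`` (int) and ``pixel_row``, ``pixel_col``
    (float).  Both 10x dialects (with the ``barcode,in_tissue,...`` header and
    without) parse to the identical table.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = first and not first.split(",")[1].strip().lstrip("-").isdigit()
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != 6:
        raise FormatError(f"{path.name}: expected 6 columns, found {df.shape[1]}")
    df.columns = _POSITIONS_COLUMNS
    for col in ("in_tissue", "array_row", "array_col"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals, np.round(vals)):
            raise FormatError(f"{path.name}: non-integer values in column {col}")
        df[col] = vals.astype(int)
    if not df["in_tissue"].isin([0, 1]).all():
        raise FormatError(f"{path.name}: in_tissue must be 0 or 1")
    if (df[["array_row", "array_col"]] < 0).any().any():
        raise FormatError(f"{path.name}: negative array coordinates")
    if df["barcode"].duplicated().any():
        dups = df.loc[df["barcode"].duplicated(), "barcode"].tolist()
        raise FormatError(f"{path.name}: duplicate barcodes {dups[:5]}")
    df[["pixel_row", "pixel_col"]] = df[["pixel_row", "pixel_col"]].astype(float)
    return df.set_index("barcode")


def write_spot_positions(spots: pd.DataFrame, path: str | os.PathLike, header: bool = True) -> None:
    out = spots.reset_index()[_POSITIONS_COLUMNS]
    out.to_csv(path, index=False, header=header)


def read_gene_annotation(path: str | os.PathLike) -> GeneAnnotation:
    """Read a BED-like TSV (chrom, start, end, symbol; 0-based half-open).

    Chromosome order is the order of first appearance in the file.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "symbol"],
        dtype={"chrom": str, "symbol": str},
    )
    if df[["start", "end"]].isna().any().any():
        raise FormatError(f"{path.name}: missing coordinates")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if df["symbol"].duplicated().any():
        dups = df.loc[df["symbol"].duplicated(), "symbol"].tolist()
        raise FormatError(f"{path.name}: duplicate gene symbols {dups[:5]}")
    chrom_order = list(dict.fromkeys(df["chrom"]))
    table = df.set_index("symbol")[["chrom", "start", "end"]]
    return GeneAnnotation(table=table, chrom_order=chrom_order)


def write_gene_annotation(annotation: GeneAnnotation, path: str | os.PathLike) -> None:
    df = annotation.table.reset_index()[["chrom", "start", "end", "symbol"]]
    df.to_csv(path, sep="\t", index=False, header=False)
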