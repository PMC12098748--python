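"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`ExpressionMatrix`, a genes x observations count
matrix with aligned labels and per-observation metadata.  Observations are
cells for single-cell data and spots for spatial data; the downstream modules
do not care which.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "SpatialDataset",
    "log_normalize",
]


@dataclass
class ExpressionMatrix:
    """Genes x observations count matrix with labels and observation metadata.

    Parameters
    ----------
    genes : list of str
        Row labels (gene symbols, case-sensitive, unique).
    observations : list of str
        Column labels (cell/spot barcodes, unique).
    counts : sparse or dense matrix, shape (n_genes, n_obs)
        Non-negative counts (or normalized values downstream).
    obs_meta : DataFrame indexed by barcode
        Free-form per-observation annotation (region, cluster, ...).
    """

    genes: list[str]
    observations: list[str]
    counts: sp.spmatrix | np.ndarray
    obs_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        n_genes, n_obs = self.counts.shape
        if len(self.genes) != n_genes:
            raise ValueError(
                f"{len(self.genes)} gene labels for {n_genes} matrix rows"
            )
        if len(self.observations) != n_obs:
            raise ValueError(
                f"{len(self.observations)} observation labels for {n_obs} matrix columns"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if len(set(self.observations)) != len(self.observations):
            raise ValueError("duplicate observation barcodes")
        if self.obs_meta is None or len(self.obs_meta) == 0:
            self.obs_meta = pd.DataFrame(index=pd.Index(self.observations, name="barcode"))
        else:
            self.obs_meta = self.obs_meta.reindex(self.observations)
            self.obs_meta.index.name = "barcode"
        dmin = self.counts.min() if not sp.issparse(self.counts) else self.counts.data.min(initial=0)
        if self.counts.shape[0] and self.counts.shape[1] and dmin < 0:
            raise ValueError("negative values in count matrix")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_obs(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        """Counts as a dense float array (genes x observations)."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def gene_index(self) -> pd.Index:
        return pd.Index(self.genes)

    def subset_obs(self, barcodes: list[str]) -> "ExpressionMatrix":
        pos = [self.observations.index(b) for b in barcodes]
        counts = self.counts[:, pos] if not sp.issparse(self.counts) else self.counts.tocsc()[:, pos]
        return ExpressionMatrix(
            genes=list(self.genes),
            observations=list(barcodes),
            counts=counts,
            obs_meta=self.obs_meta.loc[barcodes].copy(),
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        if self.genes != other.genes or self.observations != other.observations:
            return False
        a = self.dense()
        b = other.dense()
        return a.shape == b.shape and np.allclose(a, b)


@dataclass
class GeneAnnotation:
    """Gene symbol -> (chromosome, start, end) with a declared chromosome order.

    Intervals are 0-based half-open (BED convention).  Genomic ordering is
    chromosome in declared order, then start coordinate, then symbol for
    stability.
    """

    table: pd.DataFrame  # index: symbol; columns: chrom, start, end
    chrom_order: list[str]

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene symbols in annotation: {dups[:5]}")
        bad = self.table[self.table["start"] >= self.table["end"]]
        if len(bad):
            raise ValueError(f"start >= end for genes: {bad.index.tolist()[:5]}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_order)

    def genes_on(self, chrom: str) -> list[str]:
        """Genes on one chromosome, ordered by start (then symbol)."""
        sub = self.table[self.table["chrom"] == chrom]
        sub = sub.sort_values(["start"], kind="stable")
        return sub.index.tolist()

    def genomic_order(self) -> list[str]:
        out: list[str] = []
        for chrom in self.chrom_order:
            out.extend(self.genes_on(chrom))
        return out


@dataclass
class SpatialDataset:
    """Expression matrix plus per-spot lattice coordinates.

    ``spots`` follows the tissue-positions layout: one row per barcode with
    ``in_tissue``, integer ``array_row``/``array_col`` and float
    ``pixel_row``/``pixel_col`` columns.
    """

    matrix: ExpressionMatrix
    spots: pd.DataFrame  # index barcode

    def __post_init__(self) -> None:
        missing = set(self.matrix.observations) - set(self.spots.index)
        if missing:
            raise ValueError(f"spots table missing barcodes: {sorted(missing)[:5]}")
        self.spots = self.spots.loc[self.matrix.observations]


def log_normalize(matrix: ExpressionMatrix, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalize and log-transform: log1p(count / colsum * target).

    Observations with zero total counts are left all-zero.  Returns a dense
    genes x observations float array.
    """
    x = matrix.dense()
    totals = x.sum(axis=0)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    return np.log1p(x * scale[np.newaxis, :])
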