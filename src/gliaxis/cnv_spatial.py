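"""Expression-inferred CNV, the CNA index, tumor-bed masking and region gating.

Copy number is inferred per chromosome from windowed relative expression:
log-normalized expression is centered by the reference-spot mean per gene,
smoothed along the genomic gene ordering by a centered moving average
(default 51 genes), and the per-chromosome relative copy number is
``1 + clip(mean of smoothed values, +/- clip)``.  The CNA index is the sum
over chromosomes of ``|CN - 1|``, a per-spot copy-number burden.

Region gating reproduces the infiltration-area definition: spots whose
mesenchymal-signature percentile rank falls in the upper 10-30 band and whose
neuronal-signature percentile rank falls in the lower 10-30 band, restricted
to the tumor bed.  Percentile ranks use the midpoint formula
``100 * (rank - 0.5) / n`` with average ranks on ties, computed over all
spots in the dataset by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon

from .containers import ExpressionMatrix, GeneAnnotation, log_normalize

__all__ = [
    "infer_cnv",
    "select_reference_spots",
    "cna_index",
    "tumor_bed_mask",
    "point_in_polygon",
    "infiltration_gate",
    "region_correlation",
    "CorrelationResult",
]


def infer_cnv(
    matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    reference_obs: list[str] | None = None,
    window_genes: int = 51,
    clip: float = 0.5,
) -> pd.DataFrame:
    """Chromosome-level relative copy number per spot (neutral = 1).

    ``reference_obs`` defaults to all spots (self-reference).  Chromosomes
    with fewer than ``window_genes`` annotated genes in the matrix are
    skipped with a warning.  Returns spots x chromosomes, values in
    ``[1 - clip, 1 + clip]``.
    """
    if clip < 0:
        raise ValueError("clip must be non-negative")
    x = log_normalize(matrix)
    genes = pd.Index(matrix.genes)
    obs = pd.Index(matrix.observations)
    if reference_obs is None:
        ref_cols = np.arange(matrix.n_obs)
    else:
        if not reference_obs:
            raise ValueError("reference_obs must be non-empty")
        ref_cols = np.array([obs.get_loc(b) for b in reference_obs])

    centered = x - x[:, ref_cols].mean(axis=1, keepdims=True)

    out: dict[str, np.ndarray] = {}
    for chrom in annotation.chromosomes:
        chrom_genes = [g for g in annotation.genes_on(chrom) if g in genes]
        if len(chrom_genes) < window_genes:
            warnings.warn(
                f"chromosome {chrom}: {len(chrom_genes)} genes < window "
                f"{window_genes}, skipped",
                stacklevel=2,
            )
            continue
        rows = np.array([genes.get_loc(g) for g in chrom_genes])
        block = pd.DataFrame(centered[rows, :])
        smoothed = block.rolling(window_genes, center=True, min_periods=1).mean()
        dev = smoothed.mean(axis=0).to_numpy()
        out[chrom] = 1.0 + np.clip(dev, -clip, clip)
    profile = pd.DataFrame(out, index=obs.rename("barcode"))
    return profile


def select_reference_spots(
    matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    fraction: float = 0.3,
    window_genes: int = 51,
    clip: float = 0.5,
) -> list[str]:
    """Pick putatively copy-number-neutral reference spots by a two-pass rule.

    Pass 1 infers CNV against the all-spot average; the ``fraction`` of spots
    with the lowest CNA index are returned as the diploid reference for a
    second, properly referenced pass.  This mirrors how expression-CNV tools
    are anchored on a normal reference when none is annotated.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rough = cna_index(infer_cnv(matrix, annotation, window_genes=window_genes, clip=clip))
    n_ref = max(int(fraction * len(rough)), 1)
    return rough.nsmallest(n_ref).index.tolist()


def cna_index(profile: pd.DataFrame) -> pd.Series:
    """Per-spot copy-number burden: sum over chromosomes of |CN - 1|."""
    idx = (profile - 1.0).abs().sum(axis=1)
    idx.name = "cna_index"
    return idx


def point_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Boolean containment of points in a simple polygon; boundary counts as inside.

    ``vertices`` is a closed or open ring of (x, y) pairs.  A self-intersecting
    polygon is an error.
    """
    poly = Polygon(vertices)
    if not poly.is_valid:
        raise ValueError("polygon is invalid (self-intersecting?)")
    return np.array([poly.covers(Point(p)) for p in np.asarray(points, dtype=float)])


def tumor_bed_mask(
    spots: pd.DataFrame,
    polygon: np.ndarray | list | None = None,
    cna: pd.Series | None = None,
    cna_cutoff: float | None = None,
) -> pd.Series:
    """Label spots ``tumor_bed`` vs ``outside``.

    Either a polygon (vertices in pixel coordinates, (pixel_row, pixel_col)
    order, boundary inside) or a CNA-index threshold rule
    (``cna_index >= cna_cutoff``) must be given.
    """
    if polygon is not None:
        pts = spots[["pixel_row", "pixel_col"]].to_numpy()
        inside = point_in_polygon(pts, np.asarray(polygon, dtype=float))
    elif cna is not None and cna_cutoff is not None:
        inside = cna.reindex(spots.index).to_numpy() >= cna_cutoff
    else:
        raise ValueError("provide either a polygon or (cna, cna_cutoff)")
    mask = pd.Series(
        np.where(inside, "tumor_bed", "outside"), index=spots.index, name="region"
    )
    return mask


def _percentile_rank(values: np.ndarray) -> np.ndarray:
    """Midpoint percentile rank: 100 * (rank - 0.5) / n, average ranks on ties."""
    ranks = stats.rankdata(values, method="average")
    return 100.0 * (ranks - 0.5) / len(values)


def _in_band(pct: np.ndarray, band: tuple[float, float], inclusive: str) -> np.ndarray:
    lo, hi = band
    if inclusive == "left":
        return (pct >= lo) & (pct < hi)
    if inclusive == "right":
        return (pct > lo) & (pct <= hi)
    if inclusive == "both":
        return (pct >= lo) & (pct <= hi)
    raise ValueError(f"unknown inclusive mode {inclusive!r}")


def infiltration_gate(
    score_mes: pd.Series,
    score_neuro: pd.Series,
    bed: pd.Series,
    upper_band: tuple[float, float] = (70.0, 90.0),
    lower_band: tuple[float, float] = (10.0, 30.0),
    inclusive: str = "left",
) -> pd.Series:
    """Gate putative glioma-neuronal infiltration spots.

    Infiltration = spots inside the tumor bed whose mesenchymal-score
    percentile rank lies in ``upper_band`` (default [70, 90): the upper 10-30
    percentile stratum, excluding the extreme top 10% tumor core) and whose
    neuronal-score percentile rank lies in ``lower_band`` (default [10, 30)).
    Percentile ranks are computed over all spots.  Other spots keep their
    bed/outside label.  The gate is invariant to strictly monotone transforms
    of either score.
    """
    if len(score_mes) < 10:
        raise ValueError("percentile gating needs at least 10 spots")
    index = score_mes.index
    if not index.equals(score_neuro.index) or not index.equals(bed.index):
        raise ValueError("score and mask indexes must align")
    pct_mes = _percentile_rank(score_mes.to_numpy(dtype=float))
    pct_neuro = _percentile_rank(score_neuro.to_numpy(dtype=float))
    in_gate = (
        _in_band(pct_mes, upper_band, inclusive)
        & _in_band(pct_neuro, lower_band, inclusive)
        & (bed.to_numpy() == "tumor_bed")
    )
    out = bed.copy()
    out[in_gate] = "infiltration"
    out.name = "region"
    return out


@dataclass
class CorrelationResult:
    method: str
    r: float
    pval: float
    n: int
    perm_pval: float | None = None


def region_correlation(
    score_a: pd.Series,
    score_b: pd.Series,
    mask: pd.Series,
    region: str = "infiltration",
    method: str = "pearson",
    n_perm: int | None = None,
    seed: int = 0,
) -> CorrelationResult:
    """Correlation between two score vectors within one masked region.

    ``method`` is ``pearson`` or ``spearman`` (average ranks); the analytic
    p-value is two-sided.  With ``n_perm`` set, a permutation p-value is
    added by shuffling one vector (seeded).
    """
    sel = mask == region
    a = score_a[sel].to_numpy(dtype=float)
    b = score_b[sel].to_numpy(dtype=float)
    n = len(a)
    if n < 3:
        raise ValueError(f"region {region!r} has {n} spots; need >= 3")
    for v, s in ((a, score_a), (b, score_b)):
        if np.ptp(v) == 0:
            raise ValueError(f"zero variance in signature {s.name!r} within {region!r}")
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    perm_p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        stat = abs(r)
        count = 0
        for _ in range(n_perm):
            bp = rng.permutation(b)
            rp = (
                stats.pearsonr(a, bp)[0] if method == "pearson" else stats.spearmanr(a, bp)[0]
            )
            if abs(rp) >= stat:
                count += 1
        perm_p = (1 + count) / (1 + n_perm)
    return CorrelationResult(method=method, r=float(r), pval=float(p), n=n, perm_pval=perm_p)
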