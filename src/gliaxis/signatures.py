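"""Gene-signature scoring of cells, spots and pseudo-bulk profiles.

Four scoring methods are implemented:

* :func:`module_score` — mean expression of the set minus the mean of
  expression-bin-matched control genes (the standard single-cell module
  scoring procedure; defaults n_bins=24, n_ctrl=100).
* :func:`auc_score` — AUCell-style area under the set-recovery curve within
  the top fraction of each observation's expression ranking, scaled to [0,1].
* :func:`ssgsea_score` — the ssGSEA running-sum statistic (weighted in-set
  ECDF minus out-of-set ECDF, summed over ranks).
* :func:`jasmine_score` — JASMINE: mean of a min-max-scaled dropout-aware
  rank component and an expression odds-ratio component, in [0,1].

Plus :func:`pseudobulk` aggregation, :func:`znorm` z-normalization of score
tables, and the fixed four-gene AMPAR score.

Scores are returned as observation x signature DataFrames with the method
recorded in ``df.attrs["method"]``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, log_normalize
from .markers import AMPAR_GENES

__all__ = [
    "module_score",
    "auc_score",
    "ssgsea_score",
    "jasmine_score",
    "pseudobulk",
    "znorm",
    "ampar_score",
]


def _present_genes(matrix: ExpressionMatrix, name: str, members: list[str]) -> list[str]:
    gene_set = set(matrix.genes)
    present = [g for g in members if g in gene_set]
    absent = [g for g in members if g not in gene_set]
    if absent:
        warnings.warn(
            f"signature {name!r}: {len(absent)} gene(s) absent from matrix: "
            f"{absent[:10]}",
            stacklevel=3,
        )
    return present


def _scores_frame(matrix: ExpressionMatrix, data: dict[str, np.ndarray], method: str) -> pd.DataFrame:
    df = pd.DataFrame(data, index=pd.Index(matrix.observations, name="barcode"))
    df.attrs["method"] = method
    return df


def module_score(
    matrix: ExpressionMatrix,
    sets: dict[str, list[str]],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Module score: mean set expression minus mean of bin-matched controls.

    Genes are binned by average expression into ``n_bins`` equal-occupancy
    bins; for each set gene, ``n_ctrl`` control genes are sampled (without
    replacement, seeded) from its bin, excluding the set's own genes.  A set
    with zero present genes scores NaN with a warning.

    Set ``normalize=False`` if the matrix already holds log-normalized values.
    """
    x = log_normalize(matrix) if normalize else matrix.dense()
    genes = pd.Index(matrix.genes)
    avg = x.mean(axis=1)
    n_genes = len(genes)
    bins = min(n_bins, max(n_genes, 1))
    order_rank = rankdata(avg, method="ordinal") - 1  # 0..G-1, stable
    bin_id = (order_rank * bins // max(n_genes, 1)).astype(int)

    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        present = _present_genes(matrix, name, members)
        if not present:
            warnings.warn(f"signature {name!r}: no genes present, score undefined", stacklevel=2)
            out[name] = np.full(matrix.n_obs, np.nan)
            continue
        set_ix = np.array([genes.get_loc(g) for g in present])
        set_mask = np.zeros(n_genes, dtype=bool)
        set_mask[set_ix] = True
        ctrl_ix: list[int] = []
        for gi in set_ix:
            pool = np.flatnonzero((bin_id == bin_id[gi]) & ~set_mask)
            if len(pool) == 0:
                continue
            take = min(n_ctrl, len(pool))
            ctrl_ix.extend(rng.choice(pool, size=take, replace=False).tolist())
        ctrl_ix = sorted(set(ctrl_ix))
        set_mean = x[set_ix, :].mean(axis=0)
        ctrl_mean = x[ctrl_ix, :].mean(axis=0) if ctrl_ix else np.zeros(matrix.n_obs)
        out[name] = set_mean - ctrl_mean
    return _scores_frame(matrix, out, "module")


def _descending_order(x: np.ndarray) -> np.ndarray:
    """Indices ordering genes by decreasing value; ties keep input gene order."""
    return np.argsort(-x, kind="stable")


def auc_score(
    matrix: ExpressionMatrix,
    sets: dict[str, list[str]],
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Area under the set-recovery curve within the top expression ranks.

    Per observation, genes are ranked by decreasing expression (stable ties);
    the recovery curve counts set genes among the top ``ceil(top_fraction*G)``
    ranks.  The area is normalized by the maximal achievable area, so scores
    lie in [0, 1] with 1 = the set occupies the very top of the ranking.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    x = matrix.dense()
    genes = pd.Index(matrix.genes)
    n_genes = matrix.n_genes
    window = int(np.ceil(top_fraction * n_genes))

    out: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        present = _present_genes(matrix, name, members)
        if not present:
            raise ValueError(f"signature {name!r}: no genes present in matrix")
        set_mask = np.zeros(n_genes, dtype=bool)
        set_mask[[genes.get_loc(g) for g in present]] = True
        s = len(present)
        max_area = np.minimum(np.arange(1, window + 1), s).sum()
        scores = np.empty(matrix.n_obs)
        for j in range(matrix.n_obs):
            order = _descending_order(x[:, j])
            hits = set_mask[order[:window]]
            scores[j] = np.cumsum(hits).sum() / max_area
        out[name] = scores
    return _scores_frame(matrix, out, "auc")


def ssgsea_score(
    matrix: ExpressionMatrix,
    sets: dict[str, list[str]],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """ssGSEA running-sum score per observation.

    Genes are ranked by expression (average ranks on ties); walking down the
    decreasing ordering, the score is the sum over all positions of the
    weighted in-set ECDF (weights = rank value ** alpha) minus the uniform
    out-of-set ECDF.  A set containing every ranked gene scores 0 by
    convention (the out-of-set ECDF degenerates).
    """
    x = matrix.dense()
    genes = pd.Index(matrix.genes)
    n_genes = matrix.n_genes

    out: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        present = _present_genes(matrix, name, members)
        if not present:
            raise ValueError(f"signature {name!r}: no genes present in matrix")
        set_mask = np.zeros(n_genes, dtype=bool)
        set_mask[[genes.get_loc(g) for g in present]] = True
        s = int(set_mask.sum())
        scores = np.zeros(matrix.n_obs)
        if s == n_genes:
            out[name] = scores  # degenerate: no out-of-set genes
            continue
        for j in range(matrix.n_obs):
            col = x[:, j]
            ranks = rankdata(col, method="average")
            order = _descending_order(col)
            hit = set_mask[order]
            w = np.abs(ranks[order]) ** alpha
            w_in = np.where(hit, w, 0.0)
            denom = w_in.sum()
            p_in = np.cumsum(w_in) / denom if denom > 0 else np.cumsum(hit) / s
            p_out = np.cumsum(~hit) / (n_genes - s)
            scores[j] = float(np.sum(p_in - p_out))
        out[name] = scores
    return _scores_frame(matrix, out, "ssgsea")


def jasmine_score(matrix: ExpressionMatrix, sets: dict[str, list[str]]) -> pd.DataFrame:
    """JASMINE score: dropout-aware mean-rank and odds-ratio components.

    "Expressed" means count > 0.  Component A is the mean rank (ascending,
    among expressed genes) of the expressed set genes divided by the number
    of expressed genes (0 if no set gene is expressed); component B is the
    expression odds ratio of set vs non-set genes (0.5 added to every cell
    when any cell is zero).  Each component is min-max scaled across
    observations (a degenerate scale maps to 0) and the score is their mean.
    """
    x = matrix.dense()
    genes = pd.Index(matrix.genes)
    n_genes = matrix.n_genes

    out: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        present = _present_genes(matrix, name, members)
        if not present:
            raise ValueError(f"signature {name!r}: no genes present in matrix")
        set_mask = np.zeros(n_genes, dtype=bool)
        set_mask[[genes.get_loc(g) for g in present]] = True

        comp_a = np.zeros(matrix.n_obs)
        comp_b = np.zeros(matrix.n_obs)
        for j in range(matrix.n_obs):
            col = x[:, j]
            expressed = col > 0
            n_expr = int(expressed.sum())
            set_expr = expressed & set_mask
            if n_expr and set_expr.any():
                ranks = rankdata(col[expressed], method="average")
                pos_in_expressed = set_expr[expressed]
                comp_a[j] = ranks[pos_in_expressed].mean() / n_expr
            se = int(set_expr.sum())
            sne = int(set_mask.sum()) - se
            nse = n_expr - se
            nsne = (n_genes - int(set_mask.sum())) - nse
            cells = np.array([se, sne, nse, nsne], dtype=float)
            if (cells == 0).any():
                cells = cells + 0.5
            comp_b[j] = (cells[0] / cells[1]) / (cells[2] / cells[3])

        def _minmax(v: np.ndarray) -> np.ndarray:
            lo, hi = v.min(), v.max()
            if hi == lo:
                return np.zeros_like(v)
            return (v - lo) / (hi - lo)

        out[name] = 0.5 * (_minmax(comp_a) + _minmax(comp_b))
    return _scores_frame(matrix, out, "jasmine")


def pseudobulk(matrix: ExpressionMatrix, group_column: str) -> ExpressionMatrix:
    """Sum counts over the cells of each group into one bulk-like column.

    Groups come from ``obs_meta[group_column]``; group order follows first
    appearance.  An unlabeled observation is an error.
    """
    if group_column not in matrix.obs_meta.columns:
        raise ValueError(f"obs_meta has no column {group_column!r}")
    labels = matrix.obs_meta[group_column]
    if labels.isna().any():
        bad = labels.index[labels.isna()].tolist()
        raise ValueError(f"unlabeled observations: {bad[:5]}")
    x = matrix.dense()
    groups = list(dict.fromkeys(labels))
    cols = np.column_stack(
        [x[:, (labels == g).to_numpy()].sum(axis=1) for g in groups]
    )
    return ExpressionMatrix(
        genes=list(matrix.genes),
        observations=[str(g) for g in groups],
        counts=cols,
    )


def znorm(scores: pd.DataFrame) -> pd.DataFrame:
    """Z-normalize each signature across observations (sample sd; sd 0 -> 0)."""
    if len(scores) < 2:
        raise ValueError("z-normalization needs at least 2 observations")
    out = scores.copy()
    for col in out.columns:
        v = out[col].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        out[col] = (v - v.mean()) / sd if sd > 0 else 0.0
    out.attrs["method"] = scores.attrs.get("method", "") + "+znorm"
    return out


def ampar_score(matrix: ExpressionMatrix, alpha: float = 0.25) -> pd.DataFrame:
    """AMPA-receptor score from the fixed four-gene set Gria1-Gria4 (ssGSEA)."""
    df = ssgsea_score(matrix, {"AMPAR": list(AMPAR_GENES)}, alpha=alpha)
    df.attrs["set_size"] = len(AMPAR_GENES)
    return df
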