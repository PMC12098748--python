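"""TAM classification, marker-based cluster labeling and compositional tests.

The ontogeny rule classifies a myeloid cell as Mg-TAM (microglia-derived) or
Mo-TAM (monocyte-derived) when the corresponding signature score is both
greater than 0 and strictly higher than the alternative score; cells failing
both conditions — including exact ties — are ``undetermined``.

Composition differences between groups are tested with a two-sided Fisher's
exact test: exact hypergeometric enumeration for 2x2 tables, and a seeded
Monte Carlo version with fixed margins for 2xK tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, log_normalize
from .markers import DEFAULT_PANELS

__all__ = [
    "classify_mg_mo",
    "label_clusters_by_markers",
    "composition_table",
    "CompositionTable",
    "fisher_exact",
    "FisherResult",
]


def classify_mg_mo(score_mg: pd.Series, score_mo: pd.Series) -> pd.Series:
    """Mg-TAM / Mo-TAM / undetermined per cell from the two signature scores."""
    missing = score_mg.index.symmetric_difference(score_mo.index)
    if len(missing):
        raise ValueError(f"missing scores for barcodes: {missing.tolist()[:5]}")
    mo = score_mo.reindex(score_mg.index)
    mg = score_mg.to_numpy(dtype=float)
    mo = mo.to_numpy(dtype=float)
    if np.isnan(mg).any() or np.isnan(mo).any():
        bad = score_mg.index[np.isnan(mg) | np.isnan(mo)].tolist()
        raise ValueError(f"missing scores for barcodes: {bad[:5]}")
    labels = np.where(
        (mg > 0) & (mg > mo),
        "Mg-TAM",
        np.where((mo > 0) & (mo > mg), "Mo-TAM", "undetermined"),
    )
    return pd.Series(labels, index=score_mg.index, name="tam_class")


def label_clusters_by_markers(
    matrix: ExpressionMatrix,
    cluster_labels: pd.Series,
    panels: dict[str, list[str]] | None = None,
    margin: float = 0.25,
) -> pd.Series:
    """Automated analog of manual cluster curation by marker panels.

    Per cluster and panel, the panel score is the mean log-normalized
    expression of the panel genes averaged over member cells, z-scored across
    clusters per panel.  A cluster is labeled with the argmax panel when its
    z-score exceeds the runner-up by at least ``margin``; otherwise
    ``undetermined``.  Panels with no genes in the matrix are skipped with a
    warning.
    """
    if panels is None:
        panels = {"pro": DEFAULT_PANELS["pro"], "anti": DEFAULT_PANELS["anti"]}
    x = log_normalize(matrix)
    genes = pd.Index(matrix.genes)
    labels = cluster_labels.reindex(matrix.observations)
    if labels.isna().any():
        raise ValueError("every observation needs a cluster label")
    clusters = list(dict.fromkeys(labels))

    panel_scores = {}
    for name, members in panels.items():
        rows = [genes.get_loc(g) for g in members if g in genes]
        if not rows:
            warnings.warn(f"panel {name!r}: no genes present, skipped", stacklevel=2)
            continue
        per_cell = x[rows, :].mean(axis=0)
        panel_scores[name] = np.array(
            [per_cell[(labels == c).to_numpy()].mean() for c in clusters]
        )
    if not panel_scores:
        raise ValueError("no panel has genes in the matrix")

    z = {}
    for name, v in panel_scores.items():
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        z[name] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    zmat = pd.DataFrame(z, index=clusters)

    out = {}
    for c in clusters:
        row = zmat.loc[c].sort_values(ascending=False)
        if len(row) == 1 or row.iloc[0] - row.iloc[1] >= margin:
            out[c] = row.index[0]
        else:
            out[c] = "undetermined"
    return pd.Series(out, name="cluster_label")


@dataclass
class CompositionTable:
    """Group x class counts with derived row percentages."""

    counts: pd.DataFrame
    percentages: pd.DataFrame


def composition_table(classification: pd.Series, group_labels: pd.Series) -> CompositionTable:
    """Cross-tabulate class composition per group, with row percentages."""
    groups = group_labels.reindex(classification.index)
    if groups.isna().any():
        bad = classification.index[groups.isna()].tolist()
        raise ValueError(f"cells without group label: {bad[:5]}")
    counts = pd.crosstab(groups, classification)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("empty group in composition table")
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return CompositionTable(counts=counts, percentages=pct)


@dataclass
class FisherResult:
    pval: float
    method: str
    mc_se: float | None = None


def _table_log_prob(table: np.ndarray) -> float:
    """Log probability of a contingency table under fixed-margins null."""
    table = np.asarray(table)
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    lp = (
        sum(math.lgamma(x + 1) for x in r)
        + sum(math.lgamma(x + 1) for x in c)
        - math.lgamma(n + 1)
        - sum(math.lgamma(x + 1) for x in table.ravel())
    )
    return lp


def fisher_exact(
    table: np.ndarray | pd.DataFrame,
    n_draws: int = 100_000,
    seed: int = 0,
) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 or 2xK contingency table.

    2x2: exact p = sum of hypergeometric probabilities of tables (with the
    observed margins) at most as probable as the observed one.  2xK: the same
    probability-ordering p, estimated by seeded Monte Carlo over
    fixed-margins random tables (Patefield sampler), reported with its
    Monte Carlo standard error.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise ValueError("table must be 2 x K with K >= 2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    arr = np.round(arr).astype(int)
    if arr.shape[1] == 2:
        p = stats.fisher_exact(arr, alternative="two-sided")[1]
        return FisherResult(pval=float(min(p, 1.0)), method="exact")
    rng = np.random.default_rng(seed)
    lp_obs = _table_log_prob(arr)
    dist = stats.random_table(arr.sum(axis=1), arr.sum(axis=0))
    draws = dist.rvs(n_draws, random_state=rng)
    lps = np.array([_table_log_prob(d) for d in draws])
    hits = int((lps <= lp_obs + 1e-9).sum())
    p = (1.0 + hits) / (1.0 + n_draws)
    se = math.sqrt(p * (1.0 - p) / n_draws)
    return FisherResult(pval=p, method="monte-carlo", mc_se=se)
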