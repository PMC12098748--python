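"""Preranked permutation GSEA and a simplified two-part (hurdle) DE test.

The enrichment score is the classic running-sum statistic: walking down the
ranked list, set members ("hits") add ``|stat|^p / sum_set |stat|^p`` and
non-members subtract ``1/(G - |S|)``; the ES is the running-sum value of
maximal absolute deviation, and the leading edge is the set genes at or
before (positive ES) / at or after (negative ES) the extremum.

Significance uses a gene-set permutation null: for each set size, the ES of
``n_perm`` random same-size gene sets drawn without replacement.  The
one-sided permutation p-value is ``(1 + #{null ES at least as extreme, same
sign}) / (1 + #{null same sign})`` — its floor is therefore about
``1/(1 + n_perm)``.  NES = ES / mean(|null ES| of the same sign).
Benjamini-Hochberg correction is applied across all tested sets.

The differential-expression test is a covariate-free two-part analog of the
scRNA-seq hurdle model: a binomial likelihood-ratio test on the detection
rate (count > 0) plus a Gaussian likelihood-ratio test on log-expression
among detected cells; the combined statistic is chi-square with df = number
of testable parts.  It is a simplified analog, not the full shared-regression
hurdle model, and is labeled as such in its output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, log_normalize

__all__ = [
    "rank_genes",
    "enrichment_score",
    "preranked_gsea",
    "hurdle_de",
]


def _two_group_labels(matrix: ExpressionMatrix, group_column: str) -> tuple[np.ndarray, list[str]]:
    if group_column not in matrix.obs_meta.columns:
        raise ValueError(f"obs_meta has no column {group_column!r}")
    labels = matrix.obs_meta[group_column].to_numpy()
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, found {uniq}")
    for g in uniq:
        if (labels == g).sum() == 0:
            raise ValueError(f"group {g!r} is empty")
    return labels, uniq


def rank_genes(
    matrix: ExpressionMatrix,
    group_column: str,
    statistic: str = "log2fc",
) -> pd.Series:
    """Build a ranked gene list (decreasing statistic, stable ties).

    ``log2fc`` = log2((meanA + 1) / (meanB + 1)) on counts-per-million, with
    the 1-CPM pseudocount; ``signed_stat`` = the hurdle combined statistic
    signed by the direction of the CPM mean difference.
    """
    labels, (a, b) = _two_group_labels(matrix, group_column)
    x = matrix.dense()
    totals = x.sum(axis=0)
    cpm = np.divide(x * 1e6, totals[np.newaxis, :], out=np.zeros_like(x), where=totals > 0)
    mean_a = cpm[:, labels == a].mean(axis=1)
    mean_b = cpm[:, labels == b].mean(axis=1)
    if statistic == "log2fc":
        stat = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    elif statistic == "signed_stat":
        de = hurdle_de(matrix, group_column)
        stat = np.sign(mean_a - mean_b) * de["stat"].fillna(0.0).to_numpy()
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    series = pd.Series(stat, index=pd.Index(matrix.genes, name="gene"), name=statistic)
    order = np.argsort(-series.to_numpy(), kind="stable")
    return series.iloc[order]


def enrichment_score(
    ranked: pd.Series,
    gene_set: list[str],
    weight_exponent: float = 1.0,
) -> tuple[float, list[str]]:
    """Running-sum enrichment score and leading-edge genes for one set."""
    if weight_exponent < 0:
        raise ValueError("weight exponent must be >= 0")
    genes = ranked.index
    hit = np.asarray(genes.isin(set(gene_set)))
    s = int(hit.sum())
    g = len(genes)
    if s == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if s == g:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(ranked.to_numpy()) ** weight_exponent
    w_hit = np.where(hit, w, 0.0)
    denom = w_hit.sum()
    inc = w_hit / denom if denom > 0 else hit / s
    running = np.cumsum(np.where(hit, inc, -1.0 / (g - s)))
    extremum = int(np.argmax(np.abs(running)))
    es = float(running[extremum])
    if es >= 0:
        leading = [genes[i] for i in range(extremum + 1) if hit[i]]
    else:
        leading = [genes[i] for i in range(extremum, g) if hit[i]]
    return es, leading


def _es_only(w: np.ndarray, hit: np.ndarray, g: int, s: int) -> float:
    w_hit = np.where(hit, w, 0.0)
    denom = w_hit.sum()
    inc = w_hit / denom if denom > 0 else hit / s
    running = np.cumsum(np.where(hit, inc, -1.0 / (g - s)))
    return float(running[int(np.argmax(np.abs(running)))])


def preranked_gsea(
    ranked: pd.Series,
    collection: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection with a permutation null.

    Returns one row per input set.  Sets outside the size bounds are reported
    with status ``"filtered"`` (never silently dropped); tested sets carry
    ES, NES, the one-sided permutation p and its BH-adjusted value, and the
    leading-edge genes.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    genes = ranked.index
    g = len(genes)
    w = np.abs(ranked.to_numpy()) ** weight_exponent

    rows = []
    tested_sizes: dict[int, np.ndarray] = {}
    for name, members in collection.items():
        present = np.asarray(genes.isin(set(members)))
        size = int(present.sum())
        if size < min_size or size > max_size or size == g or size == 0:
            rows.append(
                dict(set=name, size=size, es=np.nan, nes=np.nan, pval=np.nan,
                     padj=np.nan, leading_edge=[], status="filtered")
            )
            continue
        es, leading = enrichment_score(ranked, members, weight_exponent)
        if size not in tested_sizes:
            null = np.empty(n_perm)
            for i in range(n_perm):
                idx = rng.choice(g, size=size, replace=False)
                hit = np.zeros(g, dtype=bool)
                hit[idx] = True
                null[i] = _es_only(w, hit, g, size)
            tested_sizes[size] = null
        null = tested_sizes[size]
        same_sign = null > 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        n_extreme = int((same_sign & (np.abs(null) >= abs(es))).sum())
        pval = (1.0 + n_extreme) / (1.0 + n_same)
        mean_null = np.abs(null[same_sign]).mean() if n_same else np.nan
        nes = es / mean_null if n_same and mean_null > 0 else np.nan
        rows.append(
            dict(set=name, size=size, es=es, nes=nes, pval=pval, padj=np.nan,
                 leading_edge=leading, status="tested")
        )

    result = pd.DataFrame(rows)
    tested = result["status"] == "tested"
    if tested.any():
        result.loc[tested, "padj"] = multipletests(
            result.loc[tested, "pval"].to_numpy(), method="fdr_bh"
        )[1]
        result.loc[tested, "padj"] = np.maximum(
            result.loc[tested, "padj"], result.loc[tested, "pval"]
        )
    return result


def _binom_ll(k: int, n: int, p: float) -> float:
    if n == 0:
        return 0.0
    ll = 0.0
    if k > 0:
        ll += k * np.log(p)
    if n - k > 0:
        ll += (n - k) * np.log(1.0 - p)
    return ll


def hurdle_de(matrix: ExpressionMatrix, group_column: str) -> pd.DataFrame:
    """Simplified two-part hurdle differential-expression test.

    Per gene: part 1 is a 1-df binomial LRT on the detection rate; part 2 is
    a 1-df Gaussian LRT on log-normalized expression among detected cells
    (requires >= 2 detected cells per group).  Combined statistic ~ chi-square
    with df = number of testable parts.  Genes detected in no cell are
    flagged untestable.  BH correction across testable genes.
    """
    labels, (a, b) = _two_group_labels(matrix, group_column)
    raw = matrix.dense()
    logx = log_normalize(matrix)
    in_a = labels == a
    in_b = labels == b
    n_a, n_b = int(in_a.sum()), int(in_b.sum())

    rows = []
    for gi, gene in enumerate(matrix.genes):
        det = raw[gi, :] > 0
        ka, kb = int(det[in_a].sum()), int(det[in_b].sum())
        if ka + kb == 0:
            rows.append(
                dict(gene=gene, det_rate_diff=0.0, logmean_diff=np.nan,
                     stat=np.nan, df=0, pval=np.nan, untestable=True)
            )
            continue
        stat = 0.0
        df = 0
        # part 1: detection-rate LRT
        k, n = ka + kb, n_a + n_b
        if 0 < k < n:
            p_pool = k / n
            ll0 = _binom_ll(k, n, p_pool)
            ll1 = _binom_ll(ka, n_a, ka / n_a if n_a else 0.5) + _binom_ll(
                kb, n_b, kb / n_b if n_b else 0.5
            )
            stat += 2.0 * (ll1 - ll0)
            df += 1
        # part 2: Gaussian LRT on log-expression among detected cells
        xa = logx[gi, in_a & det]
        xb = logx[gi, in_b & det]
        part2 = 0.0
        if len(xa) >= 2 and len(xb) >= 2:
            pooled = np.concatenate([xa, xb])
            rss1 = ((xa - xa.mean()) ** 2).sum() + ((xb - xb.mean()) ** 2).sum()
            rss0 = ((pooled - pooled.mean()) ** 2).sum()
            if rss1 > 0:
                part2 = len(pooled) * np.log(rss0 / rss1)
                stat += part2
                df += 1
        pval = float(stats.chi2.sf(stat, df)) if df > 0 else np.nan
        rows.append(
            dict(
                gene=gene,
                det_rate_diff=(ka / n_a if n_a else 0.0) - (kb / n_b if n_b else 0.0),
                logmean_diff=(xa.mean() if len(xa) else np.nan)
                - (xb.mean() if len(xb) else np.nan),
                stat=stat,
                df=df,
                pval=pval,
                untestable=df == 0,
            )
        )
    result = pd.DataFrame(rows).set_index("gene")
    testable = result["pval"].notna()
    result["padj"] = np.nan
    if testable.any():
        result.loc[testable, "padj"] = multipletests(
            result.loc[testable, "pval"].to_numpy(), method="fdr_bh"
        )[1]
    result.attrs["model"] = "simplified two-part hurdle analog"
    return result
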