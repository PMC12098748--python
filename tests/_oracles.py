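"""Independent brute-force oracles used to validate the implementations.

Everything here is written as plainly as possible (explicit loops, exact
Fraction arithmetic) and stays independent of the library code paths it
checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def brute_force_enrichment_score(
    stats: np.ndarray, in_set: np.ndarray, p: float
) -> float:
    """O(G * |S|) running-sum recomputation, evaluating the sum from scratch
    at every position of the ranked list."""
    g = len(stats)
    s = int(np.sum(in_set))
    total_w = sum(abs(stats[i]) ** p for i in range(g) if in_set[i])
    best = 0.0
    for pos in range(g):
        running = 0.0
        for i in range(pos + 1):
            if in_set[i]:
                if total_w > 0:
                    running += abs(stats[i]) ** p / total_w
                else:
                    running += 1.0 / s
            else:
                running -= 1.0 / (g - s)
        if abs(running) > abs(best):
            best = running
    return best


def brute_force_auc(values: np.ndarray, in_set: np.ndarray, window: int) -> float:
    """Set-recovery-curve area by explicit step-curve enumeration."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], i))
    hits_cum = 0
    area = 0
    for rank, gene in enumerate(order[:window]):
        if in_set[gene]:
            hits_cum += 1
        area += hits_cum
    s = int(np.sum(in_set))
    max_area = sum(min(i + 1, s) for i in range(window))
    return area / max_area


def fisher_2x2_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by full hypergeometric enumeration, exact Fractions.

    Probability ordering: sum the probabilities of all tables with the same
    margins whose probability is at most the observed table's (with a hair of
    slack for ties, applied by the caller on the float comparison).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        # tiny relative slack for probability ties
        if pk <= p_obs * Fraction(10_000_001, 10_000_000):
            total += pk
    return total


def enumerate_2xk_fisher(table: np.ndarray) -> float:
    """Two-sided probability-ordering Fisher p for a 2xK table by full
    enumeration of all tables with the observed margins."""
    table = np.asarray(table, dtype=int)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    k = table.shape[1]

    def log_prob(top: tuple[int, ...]) -> Fraction:
        # P(table) = prod_j C(c_j, t_j) / C(n, r_1)
        num = 1
        for j in range(k):
            num *= comb(col[j], top[j])
        return Fraction(num, comb(int(row.sum()), int(row[0])))

    p_obs = log_prob(tuple(int(x) for x in table[0]))
    total = Fraction(0)

    def rec(j: int, remaining: int, top: list[int]) -> None:
        nonlocal total
        if j == k - 1:
            if remaining <= col[j]:
                pk = log_prob(tuple(top + [remaining]))
                if pk <= p_obs * Fraction(10_000_001, 10_000_000):
                    total += pk
            return
        for t in range(min(int(col[j]), remaining) + 1):
            rec(j + 1, remaining - t, top + [t])

    rec(0, int(row[0]), [])
    return float(total)


def point_in_convex_polygon_halfplanes(
    points: np.ndarray, vertices: np.ndarray
) -> np.ndarray:
    """Containment in a convex CCW polygon as an intersection of half-planes
    (boundary counts as inside)."""
    verts = np.asarray(vertices, dtype=float)
    out = np.ones(len(points), dtype=bool)
    m = len(verts)
    for i in range(m):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % m]
        cross = (x2 - x1) * (points[:, 1] - y1) - (y2 - y1) * (points[:, 0] - x1)
        out &= cross >= -1e-12
    return out
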