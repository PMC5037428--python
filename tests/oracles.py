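"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (loops, exhaustive enumeration)
and shares no code with the implementation it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def block_mean_loop(values: np.ndarray, factor: int) -> np.ndarray:
    """Per-block mean of non-NaN cells via explicit loops."""
    nr, nc = values.shape
    out_r = -(-nr // factor)
    out_c = -(-nc // factor)
    out = np.full((out_r, out_c), np.nan)
    for bi in range(out_r):
        for bj in range(out_c):
            block = values[bi * factor : (bi + 1) * factor, bj * factor : (bj + 1) * factor]
            vals = block[~np.isnan(block)]
            if vals.size:
                out[bi, bj] = vals.mean()
    return out


def strip_spread_exact(
    s: np.ndarray, origin: int, T: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact accessibility moments on a 1 x n strip by exhaustive
    enumeration of every Bernoulli outcome sequence.

    Dynamics: at each step every cell with an occupied cell within
    distance 1 (including itself) flips a coin with its own suitability;
    the origin is occupied unconditionally throughout. Returns
    (occupancy probability at T, E[a], E[a^2]) with
    a = (T + 1 - t_first) / (T + 1), 0 if never occupied.
    """
    n = s.size
    # state: (occupancy tuple, t_first tuple) -> probability
    occ0 = tuple(i == origin for i in range(n))
    tf0 = tuple(0 if i == origin else None for i in range(n))
    states = {(occ0, tf0): 1.0}
    for t in range(1, T + 1):
        new_states: dict = {}
        for (occ, tf), prob in states.items():
            candidates = [
                any(occ[j] for j in range(max(0, i - 1), min(n, i + 2))) for i in range(n)
            ]
            # enumerate coin outcomes for every candidate cell
            cand_idx = [i for i in range(n) if candidates[i]]
            for draws in product([True, False], repeat=len(cand_idx)):
                p = prob
                occ_new = [False] * n
                for i, success in zip(cand_idx, draws):
                    p *= s[i] if success else (1.0 - s[i])
                    occ_new[i] = success
                if p == 0.0:
                    continue
                occ_new[origin] = True
                tf_new = list(tf)
                for i in range(n):
                    if occ_new[i] and tf_new[i] is None:
                        tf_new[i] = t
                key = (tuple(occ_new), tuple(tf_new))
                new_states[key] = new_states.get(key, 0.0) + p
        states = new_states
    p_occ = np.zeros(n)
    e_a = np.zeros(n)
    e_a2 = np.zeros(n)
    for (occ, tf), prob in states.items():
        for i in range(n):
            if occ[i]:
                p_occ[i] += prob
            if tf[i] is not None:
                a = (T + 1 - tf[i]) / (T + 1)
                e_a[i] += prob * a
                e_a2[i] += prob * a * a
    return p_occ, e_a, e_a2


def quantile_linear(sorted_vals: np.ndarray, q: float) -> float:
    """Linear-interpolation empirical quantile, coded independently."""
    v = np.sort(np.asarray(sorted_vals, dtype=float))
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def morans_i_dense(x: np.ndarray, W: np.ndarray) -> float:
    """Moran's I by the dense double-loop formula."""
    x = np.asarray(x, dtype=float)
    n = x.size
    z = x - x.mean()
    s0 = W.sum()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
    return (n / s0) * num / (z @ z)


def spearman_rank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as Pearson correlation of mid-ranks."""

    def midranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(np.asarray(x, float)), midranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
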