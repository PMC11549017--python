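"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: boolean-matrix transitive
closure, step-up recursion written from the definition, exhaustive
label-permutation enumeration for the two-sample one-sided K-S test,
and the phi coefficient as a plain Pearson correlation of indicator
vectors.
"""

from itertools import combinations

import numpy as np


def reachability_closure(n_nodes: int, edges: list[tuple[int, int]]) -> dict[int, set[int]]:
    """descendants-of via boolean matrix powers (edges are child->parent)."""
    A = np.zeros((n_nodes, n_nodes), dtype=bool)
    for c, p in edges:
        A[c, p] = True
    closure = A.copy()
    for _ in range(n_nodes):
        closure = closure | (closure @ A)
    # descendants of t = nodes that reach t
    return {t: {s for s in range(n_nodes) if closure[s, t]} for t in range(n_nodes)}


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """BH adjusted p-values: sort, scale by m/rank, cumulative min from top."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def ks_greater_stat(set_vals: np.ndarray, bg_vals: np.ndarray) -> float:
    """max over x of (F_bg(x) - F_set(x)): the one-sided statistic."""
    s = np.sort(np.asarray(set_vals, float))
    b = np.sort(np.asarray(bg_vals, float))
    xs = np.concatenate([s, b])
    f_s = np.searchsorted(s, xs, side="right") / s.size
    f_b = np.searchsorted(b, xs, side="right") / b.size
    return float(max(np.max(f_b - f_s), 0.0))


def ks_greater_perm_exact(set_vals, bg_vals) -> tuple[float, float]:
    """Exact permutation p: enumerate every split of the pooled sample."""
    s = np.asarray(set_vals, float)
    b = np.asarray(bg_vals, float)
    pooled = np.concatenate([s, b])
    m, total = s.size, pooled.size
    observed = ks_greater_stat(s, b)
    hits = n_splits = 0
    idx = set(range(total))
    for combo in combinations(range(total), m):
        cs = pooled[list(combo)]
        cb = pooled[list(idx - set(combo))]
        if ks_greater_stat(cs, cb) >= observed - 1e-12:
            hits += 1
        n_splits += 1
    return observed, hits / n_splits


def ks_greater_perm_mc(set_vals, bg_vals, n_perm: int, rng) -> float:
    """Monte Carlo permutation p-value for larger samples."""
    s = np.asarray(set_vals, float)
    b = np.asarray(bg_vals, float)
    pooled = np.concatenate([s, b])
    m = s.size
    observed = ks_greater_stat(s, b)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if ks_greater_stat(pooled[:m], pooled[m:]) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def phi_as_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation of two binary vectors (0 if degenerate)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def random_dag(n_nodes: int, rng, p_edge: float = 0.4) -> list[tuple[int, int]]:
    """Random DAG via a random topological order (edges child->parent)."""
    order = rng.permutation(n_nodes)
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges.append((int(order[j]), int(order[i])))
    return edges


def all_dags(n_nodes: int):
    """Every labeled DAG on n_nodes (only sane for n_nodes <= 3)."""
    pairs = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]
    for mask in range(2 ** len(pairs)):
        edges = [pairs[k] for k in range(len(pairs)) if mask >> k & 1]
        A = np.zeros((n_nodes, n_nodes), dtype=bool)
        for c, p in edges:
            A[c, p] = True
        closure = A.copy()
        for _ in range(n_nodes):
            closure = closure | (closure @ A)
        if not closure.diagonal().any():
            yield edges
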