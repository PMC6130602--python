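"""Independent brute-force oracles used to validate the fast paths.

Everything here deliberately avoids the package's pruning/eigen code:
likelihoods are computed by enumerating internal-state assignments with
per-branch scipy matrix exponentials, and the matrix exponential itself
has a truncated-series check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

LENGTH_FLOOR = 1e-9


def enum_loglik(tree, tip_states: dict, Q: np.ndarray, prior: np.ndarray,
                length_floor: float = LENGTH_FLOOR) -> float:
    """Likelihood by summation over all internal-state assignments."""
    dt = tree.dendropy_tree
    nodes = list(dt.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    k = Q.shape[0]
    pmat = {}
    for n in nodes:
        if n.parent_node is not None:
            t = max(n.edge.length or 0.0, length_floor)
            pmat[id(n)] = expm(Q * t)
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        p = prior[amap[id(dt.seed_node)]]
        for n in nodes:
            if n.parent_node is None:
                continue
            s_par = amap[id(n.parent_node)]
            s = tip_states[n.taxon.label] if n.is_leaf() else amap[id(n)]
            p *= pmat[id(n)][s_par, s]
        total += p
    return np.log(total)


def series_expm(Q: np.ndarray, t: float, terms: int = 60) -> np.ndarray:
    """Truncated Taylor series for expm(Q t) with scaling and squaring."""
    A = Q * t
    s = max(0, int(np.ceil(np.log2(max(np.abs(A).max(), 1e-300)))) + 1)
    A = A / (2 ** s)
    out = np.eye(Q.shape[0])
    term = np.eye(Q.shape[0])
    for k in range(1, terms):
        term = term @ A / k
        out = out + term
    for _ in range(s):
        out = out @ out
    return out


def random_tree_newick(rng: np.random.Generator, n_tips: int,
                       min_len: float = 0.05, max_len: float = 2.0) -> str:
    """Random binary topology with uniform branch lengths."""
    parts = [f"t{i}:{rng.uniform(min_len, max_len):.6f}" for i in range(n_tips)]
    while len(parts) > 2:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):{rng.uniform(min_len, max_len):.6f}")
    return f"({parts[0]},{parts[1]});"


def upgma_by_hand(d: dict) -> list:
    """Naive UPGMA on {frozenset({a, b}): distance}: list of
    (members_a, members_b, height) merges, smallest pair first."""
    clusters = sorted({x for pair in d for x in pair})
    clusters = [frozenset([c]) for c in clusters]
    dist = {frozenset([a, b]): d[frozenset([next(iter(a)), next(iter(b))])]
            for a in clusters for b in clusters if a != b}
    merges = []
    while len(clusters) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], sorted(map(sorted, kv[0]))))
        (a, b), h = best
        merged = a | b
        merges.append((a, b, h))
        clusters = [c for c in clusters if c not in (a, b)] + [merged]
        new = {}
        for c in clusters[:-1]:
            da = dist[frozenset([a, c])]
            db = dist[frozenset([b, c])]
            new[frozenset([merged, c])] = (len(a) * da + len(b) * db) / len(merged)
        dist = {k: v for k, v in dist.items() if not (k & {a, b})}
        dist.update(new)
    return merges
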