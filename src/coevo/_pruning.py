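"""Low-level likelihood machinery shared by the trait models.

A tree is flattened once into a :class:`TreeTable` of index arrays; the
post-order pruning pass over those arrays is JIT-compiled.  Transition
matrices are computed per call: the 2-state chain in closed form, the
4-state chain by eigendecomposition with a matrix-exponential fallback
when the eigenvector basis is ill-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.linalg import expm


@dataclass
class TreeTable:
    """Flattened rooted tree for fast post-order traversal.

    Nodes ``0..n_tips-1`` are tips in sorted-label order; internal nodes
    follow in post-order, the root last.  ``edge_len`` holds the length of
    the branch above each node (root entry unused).  Branch lengths are
    floored at ``length_floor`` and jointly rescaled so that the mean
    root-to-tip depth is 1; ``scale`` records the factor applied
    (likelihood-ratio statistics are invariant to this joint rescaling).
    """

    n_nodes: int
    n_tips: int
    tip_labels: list
    edge_len: np.ndarray
    postorder: np.ndarray  # internal nodes in post-order (root last)
    children_flat: np.ndarray
    children_ptr: np.ndarray
    scale: float

    @classmethod
    def from_phylo(cls, tree, length_floor: float = 1e-9, rescale: bool = True):
        dtree = tree.dendropy_tree
        leaves = sorted(dtree.leaf_node_iter(), key=lambda n: n.taxon.label)
        index = {id(n): i for i, n in enumerate(leaves)}
        post_internal = []
        for node in dtree.postorder_node_iter():
            if not node.is_leaf():
                index[id(node)] = len(index)
                post_internal.append(node)
        n_nodes = len(index)
        n_tips = len(leaves)
        edge_len = np.zeros(n_nodes)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        for node in dtree.postorder_node_iter():
            i = index[id(node)]
            if node.parent_node is not None:
                edge_len[i] = max(node.edge.length or 0.0, length_floor)
                children[index[id(node.parent_node)]].append(i)
        scale = 1.0
        if rescale:
            depths = _tip_depths(dtree)
            mean_depth = float(np.mean(depths))
            if mean_depth > 0:
                scale = 1.0 / mean_depth
                edge_len *= scale
        ptr = np.zeros(n_nodes + 1, dtype=np.int64)
        flat: list[int] = []
        for i in range(n_nodes):
            ptr[i] = len(flat)
            flat.extend(children[i])
        ptr[n_nodes] = len(flat)
        return cls(
            n_nodes=n_nodes,
            n_tips=n_tips,
            tip_labels=[n.taxon.label for n in leaves],
            edge_len=edge_len,
            postorder=np.array([index[id(n)] for n in post_internal], dtype=np.int64),
            children_flat=np.array(flat, dtype=np.int64),
            children_ptr=ptr,
            scale=scale,
        )

    def tip_state_array(self, states) -> np.ndarray:
        """Map {label: 0/1} (or a pandas Series) to the tip index order.

        Missing labels become -1 (ambiguous: partial likelihood 1 in
        every state)."""
        out = np.full(self.n_tips, -1, dtype=np.int64)
        get = states.get if hasattr(states, "get") else states.__getitem__
        for i, lab in enumerate(self.tip_labels):
            try:
                v = get(lab)
            except KeyError:
                v = None
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            v = int(v)
            if v not in (0, 1):
                raise ValueError(f"tip state for {lab!r} must be 0/1, got {v}")
            out[i] = v
        return out


def _tip_depths(dtree):
    depth = {}
    out = []
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
        if node.is_leaf():
            out.append(depth[id(node)])
    return np.array(out)


# ---------------------------------------------------------------------
# Transition matrices
# ---------------------------------------------------------------------


def transition_matrices_2state(alpha: float, beta: float, t: np.ndarray) -> np.ndarray:
    """Closed-form P(t) = expm(Q t) for Q = [[-a, a], [b, -b]], batched."""
    n = t.shape[0]
    P = np.empty((n, 2, 2))
    s = alpha + beta
    if s <= 0.0:
        P[:] = np.eye(2)
        return P
    e = np.exp(-s * t)
    P[:, 0, 0] = (beta + alpha * e) / s
    P[:, 0, 1] = alpha * (1.0 - e) / s
    P[:, 1, 0] = beta * (1.0 - e) / s
    P[:, 1, 1] = (alpha + beta * e) / s
    return P


def transition_matrices_general(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Batched expm(Q t) via eigendecomposition, expm fallback.

    The eigen route is exact for diagonalisable Q and an order of
    magnitude faster than per-branch Pade exponentials; when the
    eigenvector matrix is ill-conditioned (nearly defective Q) each
    branch falls back to ``scipy.linalg.expm``.
    """
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.norm(V, 2) * np.linalg.norm(Vinv, 2)
        if not np.isfinite(cond) or cond > 1e8:
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        ewt = np.exp(np.multiply.outer(t, w))  # (n, k)
        P = np.einsum("ij,nj,jk->nik", V, ewt, Vinv)
        P = P.real
    except np.linalg.LinAlgError:
        P = np.stack([expm(Q * ti) for ti in t])
    np.clip(P, 0.0, 1.0, out=P)
    # renormalise rows (guards rounding from the eigen route)
    P /= P.sum(axis=2, keepdims=True)
    return P


# ---------------------------------------------------------------------
# Pruning kernel
# ---------------------------------------------------------------------


@njit(cache=True)
def _prune(postorder, children_flat, children_ptr, P, tip_states, prior):  # pragma: no cover - jit
    k = prior.shape[0]
    n_tips = tip_states.shape[0]
    n_nodes = children_ptr.shape[0] - 1
    L = np.empty((n_nodes, k))
    for i in range(n_tips):
        s = tip_states[i]
        if s < 0:
            for j in range(k):
                L[i, j] = 1.0
        else:
            for j in range(k):
                L[i, j] = 0.0
            L[i, s] = 1.0
    logscale = 0.0
    for pi in range(postorder.shape[0]):
        v = postorder[pi]
        w0 = np.ones(k)
        for ci in range(children_ptr[v], children_ptr[v + 1]):
            c = children_flat[ci]
            for i in range(k):
                acc = 0.0
                for j in range(k):
                    acc += P[c, i, j] * L[c, j]
                w0[i] *= acc
        m = 0.0
        for i in range(k):
            if w0[i] > m:
                m = w0[i]
        if m <= 0.0:
            return -np.inf
        inv = 1.0 / m
        for i in range(k):
            L[v, i] = w0[i] * inv
        logscale += np.log(m)
    root = postorder[postorder.shape[0] - 1]
    tot = 0.0
    for i in range(k):
        tot += prior[i] * L[root, i]
    if tot <= 0.0:
        return -np.inf
    return np.log(tot) + logscale


def prune_loglik(table: TreeTable, P: np.ndarray, tip_states: np.ndarray,
                 prior: np.ndarray) -> float:
    """Log-likelihood of tip data by post-order pruning with rescaling."""
    return float(
        _prune(table.postorder, table.children_flat, table.children_ptr,
               P, tip_states, prior)
    )


# ---------------------------------------------------------------------
# Fused kernels (transition matrices + pruning in one JIT call).
# These are the hot path of the ML fits; the separate numpy routines
# above remain as the reference path and as the fallback for rate
# matrices whose eigenbasis is numerically defective.
# ---------------------------------------------------------------------


@njit(cache=True)
def loglik_2state_kernel(alpha, beta, edge_len, postorder, children_flat,
                         children_ptr, tip_states, prior):  # pragma: no cover - jit
    n = edge_len.shape[0]
    P = np.empty((n, 2, 2))
    s = alpha + beta
    if s <= 0.0:
        for b in range(n):
            P[b, 0, 0] = 1.0
            P[b, 0, 1] = 0.0
            P[b, 1, 0] = 0.0
            P[b, 1, 1] = 1.0
    else:
        for b in range(n):
            e = np.exp(-s * edge_len[b])
            P[b, 0, 0] = (beta + alpha * e) / s
            P[b, 0, 1] = alpha * (1.0 - e) / s
            P[b, 1, 0] = beta * (1.0 - e) / s
            P[b, 1, 1] = (alpha + beta * e) / s
    return _prune(postorder, children_flat, children_ptr, P, tip_states, prior)


@njit(cache=True)
def loglik_4state_kernel(q, edge_len, postorder, children_flat, children_ptr,
                         tip_states, prior):  # pragma: no cover - jit
    """Joint-chain log-likelihood from the 8 free rates.

    Returns NaN when the eigendecomposition of Q does not reconstruct it
    accurately (caller falls back to the scipy matrix exponential).
    """
    Q = np.zeros((4, 4))
    Q[0, 1], Q[0, 2] = q[0], q[1]
    Q[1, 0], Q[1, 3] = q[2], q[3]
    Q[2, 0], Q[2, 3] = q[4], q[5]
    Q[3, 1], Q[3, 2] = q[6], q[7]
    for i in range(4):
        Q[i, i] = -(Q[i, 0] + Q[i, 1] + Q[i, 2] + Q[i, 3])
    Qc = Q.astype(np.complex128)
    w, V = np.linalg.eig(Qc)
    Vinv = np.linalg.inv(V)
    # reconstruction check guards nearly defective eigenbases
    R = np.dot(np.dot(V, np.diag(w)), Vinv)
    scale = 1.0
    for i in range(4):
        for j in range(4):
            a = abs(Q[i, j])
            if a > scale:
                scale = a
    err = 0.0
    for i in range(4):
        for j in range(4):
            d = abs(R[i, j] - Q[i, j])
            if d > err:
                err = d
    if err > 1e-9 * scale:
        return np.nan
    # expm(Q t) = sum_k exp(w_k t) * outer(V[:, k], Vinv[k, :])
    outer = np.empty((4, 4, 4), dtype=np.complex128)
    for k in range(4):
        for i in range(4):
            for j in range(4):
                outer[k, i, j] = V[i, k] * Vinv[k, j]
    n = edge_len.shape[0]
    P = np.empty((n, 4, 4))
    for b in range(n):
        for i in range(4):
            for j in range(4):
                P[b, i, j] = 0.0
        for k in range(4):
            e = np.exp(w[k] * edge_len[b]).real if w[k].imag == 0.0 else 0.0
            if w[k].imag == 0.0:
                for i in range(4):
                    for j in range(4):
                        P[b, i, j] += e * outer[k, i, j].real
            else:
                ec = np.exp(w[k] * edge_len[b])
                for i in range(4):
                    for j in range(4):
                        P[b, i, j] += (ec * outer[k, i, j]).real
        for i in range(4):
            rs = 0.0
            for j in range(4):
                if P[b, i, j] < 0.0:
                    P[b, i, j] = 0.0
                rs += P[b, i, j]
            if rs <= 0.0:
                return np.nan
            for j in range(4):
                P[b, i, j] /= rs
    return _prune(postorder, children_flat, children_ptr, P, tip_states, prior)
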