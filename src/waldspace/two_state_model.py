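"""Two-state symmetric substitution model on forests.

Each edge of length ``l`` transmits a binary state unchanged with
probability ``(1 + exp(-l))/2`` and flips it with probability
``(1 - exp(-l))/2``; the chain is stationary with marginal Bern(1/2).
A forest therefore induces a strictly positive probability mass function
over the ``2^N`` binary characters at the leaves, with independent blocks
across connected components.

Because each edge's transition enters the pruning product exactly once,
the pmf is multilinear in the per-edge quantities ``exp(-l^e)``; exact
first and second derivatives with respect to the edge lengths follow by
replacing an edge's transition matrix with its derivative inside the
recursion.  These exact derivatives feed the Fisher information matrix,
its Christoffel symbols and the geodesic ODE.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .forest_core import Forest

__all__ = [
    "transition_same_prob",
    "character_pmf",
    "character_pmf_derivatives",
    "leaf_covariance",
    "simulate_characters",
    "f_divergence",
    "kl_divergence",
    "js_metric",
    "hellinger_metric",
    "fisher_information_two_state",
    "christoffel_two_state",
]

MAX_PMF_LEAVES = 16


def transition_same_prob(length: float) -> float:
    """P(state preserved) across a path of length ``l``: (1 + e^-l)/2."""
    if length < 0:
        raise ValueError("path length must be >= 0")
    return 0.5 * (1.0 + math.exp(-length))


def _trans(theta: float, order: int) -> np.ndarray:
    """Transition matrix in theta = exp(-l), or its l-derivative of given
    order.  d(theta)/dl = -theta, and the matrix is affine in theta."""
    base = 0.5 * np.array([[1.0 + theta, 1.0 - theta],
                           [1.0 - theta, 1.0 + theta]])
    if order == 0:
        return base
    sgn = -1.0 if order % 2 else 1.0
    return sgn * 0.5 * theta * np.array([[1.0, -1.0], [-1.0, 1.0]])


def _component_pmf(forest: Forest, comp: set, marks: dict | None = None) -> tuple[list[int], np.ndarray]:
    """PMF over the binary characters of one component's leaves.

    ``marks`` maps an edge (frozenset pair) to a derivative order; the
    corresponding transition matrix is differentiated that many times with
    respect to its edge length.  Returns (sorted leaf labels, array of
    length 2**n indexed with the first leaf as the most significant bit).
    """
    marks = marks or {}
    g = forest.graph.subgraph(comp)
    leaves = sorted(v for v in comp if isinstance(v, int))
    if len(leaves) == 1:
        if marks:
            return leaves, np.zeros(2)
        return leaves, np.array([0.5, 0.5])
    internal = [v for v in comp if not isinstance(v, int)]
    root = internal[0] if internal else leaves[0]

    def matrix(u, v) -> np.ndarray:
        order = marks.get(frozenset((u, v)), 0)
        return _trans(math.exp(-g.edges[u, v]["length"]), order)

    def below(v, parent) -> tuple[list[int], np.ndarray]:
        """Return (leaf list, L) with L[x, s] = P(chars s below v | X_v = x);
        if v is a leaf treated as its own subtree, L[x, s] = delta(x = s)."""
        if isinstance(v, int):
            return [v], np.eye(2)
        lv: list[int] = []
        table = np.ones((2, 1))
        for nb in g.neighbors(v):
            if nb == parent:
                continue
            sub_leaves, L = below(nb, v)
            M = matrix(v, nb) @ L  # M[x, s_sub]
            table = np.einsum("xa,xb->xab", table, M).reshape(2, -1)
            lv.extend(sub_leaves)
        return lv, table

    if isinstance(root, int):
        # 2-leaf component: root at leaf
        other = leaves[1] if root == leaves[0] else leaves[0]
        M = matrix(root, other)
        p = 0.5 * M  # p[s_root, s_other]
        return [root, other], p.reshape(-1)
    lv, table = below(root, None)
    p = 0.5 * table.sum(axis=0)
    # reorder leaf axes into ascending label order
    order = np.argsort(lv)
    p = p.reshape((2,) * len(lv)).transpose(order).reshape(-1)
    return sorted(lv), p


def _assemble(forest: Forest, comp_pmfs: list[tuple[list[int], np.ndarray]]) -> np.ndarray:
    """Tensor the per-component pmfs into the full 2^N vector (leaf 1 is
    the most significant bit)."""
    n = forest.n_leaves
    full = np.ones((2,) * n)
    for leaves, p in comp_pmfs:
        shape = [2 if (i + 1) in leaves else 1 for i in range(n)]
        full = full * p.reshape((2,) * len(leaves)).reshape(shape)
    return full.reshape(-1)


def character_pmf(forest: Forest) -> np.ndarray:
    """Exact pmf over all 2^N binary characters induced by the forest."""
    if forest.n_leaves > MAX_PMF_LEAVES:
        raise ValueError(f"character pmf guarded at N <= {MAX_PMF_LEAVES}")
    comps = forest.components()
    return _assemble(forest, [_component_pmf(forest, c) for c in comps])


def _pmf_marked(forest: Forest, marks: dict) -> np.ndarray:
    """PMF with some edges' transition matrices differentiated in length."""
    comps = forest.components()
    parts = []
    for c in comps:
        local = {e: o for e, o in marks.items()
                 if all(x in c for x in e)}
        parts.append(_component_pmf(forest, c, local))
    return _assemble(forest, parts)


def character_pmf_derivatives(tree: Forest) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact pmf plus its first and second edge-length derivatives.

    Returns ``(p, grad, hess)`` with shapes ``(2^N,)``, ``(E, 2^N)`` and
    ``(E, E, 2^N)``, edges in :meth:`Forest.edge_order` order.
    """
    edges = [frozenset(e) for e in tree.edge_order()]
    E = len(edges)
    p = character_pmf(tree)
    grad = np.array([_pmf_marked(tree, {e: 1}) for e in edges])
    hess = np.empty((E, E, p.size))
    for i in range(E):
        hess[i, i] = _pmf_marked(tree, {edges[i]: 2})
        for j in range(i + 1, E):
            hij = _pmf_marked(tree, {edges[i]: 1, edges[j]: 1})
            hess[i, j] = hess[j, i] = hij
    return p, grad, hess


def leaf_covariance(forest: Forest, u: int, v: int) -> float:
    """Cov(X_u, X_v) = exp(-l_uv)/4; zero across components, 1/4 if u=v."""
    from .forest_core import leaf_distance_matrix

    d = leaf_distance_matrix(forest)[u - 1, v - 1]
    return 0.25 * math.exp(-d)


def simulate_characters(forest: Forest, n_sites: int, seed: int | None = None) -> np.ndarray:
    """Draw i.i.d. binary characters at the leaves (rows: sites).

    Simulated by rooting each component arbitrarily, drawing the root from
    Bern(1/2) and flipping along each edge with probability
    ``(1 - exp(-l))/2``; an infinite edge decouples its two sides.
    """
    rng = np.random.default_rng(seed)
    n = forest.n_leaves
    out = np.zeros((n_sites, n), dtype=np.int8)
    for comp in forest.components():
        g = forest.graph.subgraph(comp)
        nodes = list(comp)
        root = nodes[0]
        state = {root: rng.integers(0, 2, size=n_sites)}
        for u, v in nx_bfs_edges(g, root):
            pflip = 0.5 * (1.0 - math.exp(-g.edges[u, v]["length"]))
            flips = rng.random(n_sites) < pflip
            state[v] = np.where(flips, 1 - state[u], state[u])
        for v in comp:
            if isinstance(v, int):
                out[:, v - 1] = state[v]
    return out


def nx_bfs_edges(g, root):
    import networkx as nx

    return nx.bfs_edges(g, root)


# ---------------------------------------------------------------------------
# divergences
# ---------------------------------------------------------------------------

def f_divergence(p: np.ndarray, q: np.ndarray, f: Callable[[np.ndarray], np.ndarray]) -> float:
    """D_f(p; q) = sum_s q(s) f(p(s)/q(s)) for convex f with f(1) = 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("f-divergence requires strictly positive q")
    return float(np.sum(q * f(p / q)))


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback-Leibler divergence, f(t) = t log t."""
    return f_divergence(p, q, lambda t: np.where(t > 0, t * np.log(
        np.where(t > 0, t, 1.0)), 0.0))


def js_metric(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon metric: sqrt of the symmetrized KL to the mixture."""
    m = 0.5 * (np.asarray(p, float) + np.asarray(q, float))
    return math.sqrt(0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m))


def hellinger_metric(p: np.ndarray, q: np.ndarray) -> float:
    """Hellinger metric: sqrt of sum (sqrt p - sqrt q)^2."""
    return float(np.sqrt(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2)))


# ---------------------------------------------------------------------------
# Fisher information and Christoffel symbols
# ---------------------------------------------------------------------------

def fisher_information_two_state(tree: Forest, _cache: dict | None = None) -> np.ndarray:
    """Fisher information matrix g_ij = sum_s p (d_i log p)(d_j log p)
    over the tree's edge-length coordinates."""
    _require_resolved(tree)
    p, grad, _ = _derivs_first_only(tree)
    if np.any(p <= 0):
        raise ValueError("character pmf has a non-positive entry")
    return (grad / p) @ grad.T


def _derivs_first_only(tree: Forest):
    edges = [frozenset(e) for e in tree.edge_order()]
    p = character_pmf(tree)
    grad = np.array([_pmf_marked(tree, {e: 1}) for e in edges])
    return p, grad, edges


def metric_and_derivative_two_state(tree: Forest) -> tuple[np.ndarray, np.ndarray]:
    """Return (g, dg) with dg[k, i, j] = d g_ij / d l^k, both exact."""
    _require_resolved(tree)
    p, grad, hess = character_pmf_derivatives(tree)
    if np.any(p <= 0):
        raise ValueError("character pmf has a non-positive entry")
    E = grad.shape[0]
    w = grad / p  # w[i, s] = (d_i p) / p
    g = w @ grad.T
    g = (g + g.T) / 2
    # d_k g_ij = sum_s [ (d_k d_i p)(d_j p)/p + (d_i p)(d_k d_j p)/p
    #                    - (d_i p)(d_j p)(d_k p)/p^2 ]
    dg = np.empty((E, E, E))
    for k in range(E):
        cross = hess[k] @ w.T  # [i, j] = sum_s (d_k d_i p)(d_j p)/p
        corr = (w * (grad[k] / p)) @ grad.T
        dg[k] = cross + cross.T - corr
        dg[k] = (dg[k] + dg[k].T) / 2
    return g, dg


def christoffel_from_metric(g: np.ndarray, dg: np.ndarray) -> np.ndarray:
    """Gamma^k_ij = (1/2) g^{kl} (d_i g_lj + d_j g_li - d_l g_ij)."""
    ginv = np.linalg.inv(g)
    # dg indexed [k, i, j] = d_k g_ij
    term = (np.einsum("ilj->lij", dg)
            + np.einsum("jli->lij", dg)
            - dg)  # [l, i, j]
    return 0.5 * np.einsum("kl,lij->kij", ginv, term)


def christoffel_two_state(tree: Forest) -> np.ndarray:
    """Christoffel symbols Gamma[k, i, j] of the two-state Fisher metric."""
    g, dg = metric_and_derivative_two_state(tree)
    return christoffel_from_metric(g, dg)


def _require_resolved(tree: Forest) -> None:
    if not tree.is_single_tree():
        raise ValueError("metric coordinates require a single tree")
    lv = tree.length_vector()
    if np.any(np.isinf(lv)):
        raise ValueError("metric coordinates require finite edge lengths")
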