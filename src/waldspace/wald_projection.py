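"""Projection from the ambient SPD space onto (embedded) wald space.

Given an ambient covariance matrix ``S0``, find a forest ``F`` minimizing
the affine-invariant distance ``d_cov(S0, S_F)``.  The squared distance
has an analytic gradient over the edge lengths of a resolved tree,

    d_i d^2 = tr( log(S0^-1/2 S_F S0^-1/2) S0^1/2 S_F^-1 (d_i S_F) S0^-1/2 )

with ``d_i S_F = -(S_F o sigma^i)``, which drives a Barzilai-Borwein
gradient descent.  Three variants are provided:

* :func:`project_within_orthant` halts when an internal edge is assigned a
  negative length (the iterate has reached that orthant's BHV boundary);
* :func:`project_crossing` instead re-reads the offending iterate in the
  two NNI-neighbour orthants (taking absolute values of the proposed
  lengths) and continues from whichever reinterpretation is closer to
  ``S0``;
* :func:`project_global` restarts the orthant-constrained descent once in
  every maximal orthant and keeps the best.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .forest_core import (
    Forest,
    Topology,
    enumerate_topologies,
    nni_neighbors,
    split_matrices,
)
from .gaussian_model import covariance_matrix
from .spd_geometry import matrix_sqrt_log, spd_distance

__all__ = ["ProjectionResult", "grad_sq_dist", "project_within_orthant",
           "project_crossing", "project_global"]

logger = logging.getLogger(__name__)

GRAD_TOL = 1e-8
MAX_ITER = 5000
ALPHA_MIN, ALPHA_MAX = 1e-8, 1e2
ALPHA_INIT = 1e-2
LENGTH_CAP = 50.0       # lam within ~2e-22 of 1; genuine optima at infinity
PENDANT_FLOOR = 1e-10   # negative pendant proposals are clamped here
BOUNDARY_EPS = 1e-8     # an internal length this small counts as the boundary
MAX_GLOBAL_LEAVES = 6


@dataclass
class ProjectionResult:
    """Outcome of a gradient-descent projection run."""

    forest: Forest
    objective: float              # squared d_cov at the returned forest
    status: str                   # converged | boundary_halt | max_iter
    n_iter: int
    trace: list[tuple[np.ndarray, float, float]] = field(default_factory=list)
    topology: Topology | None = None
    runs: list["ProjectionResult"] | None = None  # populated by project_global

    @property
    def distance(self) -> float:
        return math.sqrt(max(self.objective, 0.0))


class _OrthantObjective:
    """Squared d_cov to S0 and its gradient over one orthant's lengths."""

    def __init__(self, s0: np.ndarray, tree: Forest):
        self.tree = tree
        self.sigmas = np.array(split_matrices(tree))
        self.s0_sqrt, self.s0_isqrt, _ = matrix_sqrt_log(s0)
        order = tree.edge_order()
        self.pendant = np.array(
            [tree.split_of_edge(e).is_pendant for e in order])

    def covariance(self, lengths: np.ndarray) -> np.ndarray:
        # S = exp(-sum_e l^e sigma^e) entrywise
        expo = np.einsum("e,eab->ab", lengths, self.sigmas)
        return np.exp(-expo)

    def value_grad(self, lengths: np.ndarray) -> tuple[float, np.ndarray]:
        s = self.covariance(lengths)
        m = self.s0_isqrt @ s @ self.s0_isqrt
        w, v = np.linalg.eigh((m + m.T) / 2)
        if w[0] <= 0:
            raise ValueError("candidate covariance matrix lost definiteness")
        logm = (v * np.log(w)) @ v.T
        val = 0.5 * float(np.sum(np.log(w) ** 2))
        sinv = np.linalg.inv(s)
        core = logm @ self.s0_sqrt @ sinv
        ds = -(self.sigmas * s)  # [e, N, N]
        grad = np.einsum("ab,ebc,ca->e", core, ds, self.s0_isqrt)
        return val, grad

    def value(self, lengths: np.ndarray) -> float:
        s = self.covariance(lengths)
        m = self.s0_isqrt @ s @ self.s0_isqrt
        w = np.linalg.eigvalsh((m + m.T) / 2)
        if w[0] <= 0:
            raise ValueError("candidate covariance matrix lost definiteness")
        return 0.5 * float(np.sum(np.log(w) ** 2))


def grad_sq_dist(s0: np.ndarray, tree: Forest) -> np.ndarray:
    """Gradient of d_cov(S0, S_F)^2 over the tree's edge lengths
    (edge_order coordinates)."""
    obj = _OrthantObjective(np.asarray(s0, float), tree)
    _, g = obj.value_grad(tree.length_vector())
    return g


def _bb_descent(obj: _OrthantObjective, l0: np.ndarray, *,
                crossing: bool, s0: np.ndarray,
                grad_tol: float, max_iter: int, keep_trace: bool):
    """Shared BB1 descent loop; returns (lengths, tree, val, status, trace, n)."""
    tree = obj.tree
    l = np.asarray(l0, float).copy()
    val, grad = obj.value_grad(l)
    trace: list[tuple[np.ndarray, float, float]] = []
    alpha = ALPHA_INIT
    prev_l = prev_grad = None
    status = "max_iter"
    it = 0
    stalled = 0
    backtracked = False
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < grad_tol:
            status = "converged"
            break
        if stalled >= 5:  # objective flat (e.g. deep saturation): accept
            status = "converged"
            break
        val_before = val
        if prev_l is not None:
            s_vec = l - prev_l
            y_vec = grad - prev_grad
            sy = float(s_vec @ y_vec)
            if sy > 0:
                alpha = float(s_vec @ s_vec) / sy
            elif not backtracked:
                alpha *= 2  # flat objective: no curvature signal, open up
            alpha = min(max(alpha, ALPHA_MIN), ALPHA_MAX)
        accepted = False
        a = alpha
        backtracked = False
        for _ in range(60):  # halving backtrack on objective increase
            prop = l - a * grad
            prop[obj.pendant & (prop <= 0)] = PENDANT_FLOOR
            np.clip(prop, None, LENGTH_CAP, out=prop)
            neg_internal = (~obj.pendant) & (prop < 0)
            if np.any(neg_internal):
                if not crossing:
                    # halt only when the iterate is pinned to the boundary
                    # (a shorter step cannot stay in the orthant's interior)
                    if np.min(l[neg_internal]) <= BOUNDARY_EPS:
                        status = "boundary_halt"
                        break
                    a /= 2
                    backtracked = True
                    continue
                new_tree, new_l, new_val = _cross_boundary(
                    s0, tree, prop, neg_internal)
                # candidate of staying on this side of the boundary: the
                # optimum may sit on the shared stratum itself, in which
                # case crossing back and forth would never terminate
                clamp = prop.copy()
                clamp[neg_internal] = BOUNDARY_EPS
                try:
                    clamp_val, clamp_grad = obj.value_grad(clamp)
                except ValueError:
                    clamp_val, clamp_grad = math.inf, None
                if new_val < clamp_val - 1e-14 * max(1.0, clamp_val):
                    if new_val > val and a > ALPHA_MIN:
                        a /= 2  # prefer crossings that do not increase d^2
                        backtracked = True
                        continue
                    obj = _OrthantObjective(s0, new_tree)
                    tree = new_tree
                    prev_l = prev_grad = None
                    l = new_l
                    val, grad = obj.value_grad(l)
                    alpha = ALPHA_INIT
                    accepted = True
                    break
                if clamp_val <= val or a <= ALPHA_MIN:
                    prev_l, prev_grad = l, grad
                    l, val, grad = clamp, clamp_val, clamp_grad
                    accepted = True
                    break
                a /= 2
                backtracked = True
                continue
            try:
                new_val, new_grad = obj.value_grad(prop)
            except ValueError:
                a /= 2
                backtracked = True
                continue
            if new_val <= val or a <= ALPHA_MIN:
                prev_l, prev_grad = l, grad
                l, val, grad = prop, new_val, new_grad
                accepted = True
                break
            a /= 2
            backtracked = True
        if keep_trace:
            trace.append((l.copy(), val, a))
        if status in ("boundary_halt",):
            break
        if not accepted:
            status = "converged"  # step underflow: cannot improve further
            break
        if val_before - val <= 1e-14 * max(1.0, val):
            stalled += 1
        else:
            stalled = 0
    return obj, l, val, grad, status, trace, it


def _cross_boundary(s0: np.ndarray, tree: Forest, prop: np.ndarray,
                    neg_internal: np.ndarray):
    """Reinterpret a negative-internal-length proposal in the two NNI
    neighbour orthants (absolute values as lengths); pick the closer."""
    order = tree.edge_order()
    idx = int(np.argmin(np.where(neg_internal, prop, np.inf)))
    bad_split = tree.split_of_edge(order[idx])
    topo = tree.topology()
    abs_prop = np.abs(prop)
    abs_prop[abs_prop == 0] = PENDANT_FLOOR
    lengths_by_split = {tree.split_of_edge(e): abs_prop[k]
                        for k, e in enumerate(order)}
    n1, n2 = nni_neighbors(topo, bad_split)
    candidates = []
    for nb in (n1, n2):
        (new_split,) = nb.splits - topo.splits
        lg = {s: lengths_by_split[s] for s in nb.splits if s != new_split}
        lg[new_split] = abs_prop[idx]
        cand = nb.to_tree(lg)
        d2 = spd_distance(s0, covariance_matrix(cand)) ** 2
        candidates.append((d2, nb.sort_key(), cand))
    candidates.sort(key=lambda c: (c[0], c[1]))
    if abs(candidates[0][0] - candidates[1][0]) < 1e-14:
        logger.info("boundary crossing tie at split %s; choosing "
                    "lexicographically smaller topology", bad_split)
    d2, _, best = candidates[0]
    return best, best.length_vector(), d2


def project_within_orthant(s0: np.ndarray, topology: Topology | Forest,
                           l_init: np.ndarray | None = None, *,
                           grad_tol: float = GRAD_TOL,
                           max_iter: int = MAX_ITER,
                           keep_trace: bool = False) -> ProjectionResult:
    """Barzilai-Borwein descent constrained to one maximal orthant.

    Halts with status ``boundary_halt`` as soon as an internal edge is
    assigned a negative length.
    """
    s0 = np.asarray(s0, float)
    tree = _initial_tree(topology, l_init)
    obj = _OrthantObjective(s0, tree)
    obj, l, val, grad, status, trace, it = _bb_descent(
        obj, tree.length_vector(), crossing=False, s0=s0,
        grad_tol=grad_tol, max_iter=max_iter, keep_trace=keep_trace)
    out = obj.tree.with_lengths(l)
    return ProjectionResult(forest=out, objective=val, status=status,
                            n_iter=it, trace=trace, topology=out.topology())


def project_crossing(s0: np.ndarray, tree_init: Forest | Topology,
                     l_init: np.ndarray | None = None, *,
                     grad_tol: float = GRAD_TOL,
                     max_iter: int = MAX_ITER,
                     keep_trace: bool = False) -> ProjectionResult:
    """BB descent allowed to cross codimension-1 BHV boundaries via NNI
    reinterpretation of negative internal lengths."""
    s0 = np.asarray(s0, float)
    tree = _initial_tree(tree_init, l_init)
    obj = _OrthantObjective(s0, tree)
    obj, l, val, grad, status, trace, it = _bb_descent(
        obj, tree.length_vector(), crossing=True, s0=s0,
        grad_tol=grad_tol, max_iter=max_iter, keep_trace=keep_trace)
    out = obj.tree.with_lengths(l)
    return ProjectionResult(forest=out, objective=val, status=status,
                            n_iter=it, trace=trace, topology=out.topology())


def project_global(s0: np.ndarray, n_leaves: int, *,
                   l_init_value: float = 0.5,
                   grad_tol: float = GRAD_TOL,
                   max_iter: int = MAX_ITER) -> ProjectionResult:
    """Best orthant-constrained projection over all (2N-5)!! orthants."""
    if n_leaves > MAX_GLOBAL_LEAVES:
        raise ValueError(f"global projection guarded at N <= {MAX_GLOBAL_LEAVES}")
    s0 = np.asarray(s0, float)
    runs = []
    for topo in enumerate_topologies(n_leaves):
        l0 = np.full(2 * n_leaves - 3, l_init_value)
        runs.append(project_within_orthant(
            s0, topo, l0, grad_tol=grad_tol, max_iter=max_iter))
    best = min(runs, key=lambda r: r.objective)
    best.runs = runs
    return best


def _initial_tree(topology: Topology | Forest,
                  l_init: np.ndarray | None) -> Forest:
    if isinstance(topology, Forest):
        tree = topology if l_init is None else topology.with_lengths(l_init)
    else:
        if l_init is None:
            raise ValueError("l_init is required with a Topology input")
        tree = topology.to_tree(np.asarray(l_init, float))
    if not tree.is_resolved():
        raise ValueError("projection requires a fully resolved initial tree")
    return tree
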