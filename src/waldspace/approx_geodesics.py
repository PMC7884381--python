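"""Approximate boundary-value geodesics in wald space via the SPD embedding.

Shooting solves only the initial-value problem inside one orthant.  To
connect two given forests — possibly with different topologies — the
ambient space is used instead: geodesics between covariance matrices are
closed-form, and each ambient point can be projected back onto the
embedded wald space.  Two constructions are provided:

* the **recursive algorithm**: walk from the start forest towards the
  (fixed) end forest, at iteration i stepping a proportion 1/(k-i+1)
  along the ambient geodesic to the destination and projecting;
* the **symmetrized algorithm**: grow the path simultaneously from both
  ends, projecting the points at proportions 1/(k-i+1) and 1-1/(k-i+1)
  along the ambient geodesic between the current end segments.

The recursive construction is not symmetric under swapping the end
points; the symmetrized one is (exactly, by reversal of the ambient
geodesic).  Path length is approximated by summing the ambient distance
d_cov between successive output forests; this always dominates the
single ambient chord and, empirically, the symmetrized paths are the
shorter ones.

The module also contains the star-stratum experiment: approximate
intrinsic distances from a resolved 4-leaf tree with all weights lam0 to
the star trees F(lam), traced over a grid of lam.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .forest_core import Forest, Topology
from .gaussian_model import covariance_matrix
from .spd_geometry import spd_distance, spd_geodesic
from .wald_projection import project_crossing

__all__ = ["DiscretePath", "recursive_path", "symmetrized_path",
           "discrete_length", "star_stratum_curve",
           "resolved_representative"]

DEFAULT_K = 64


@dataclass
class DiscretePath:
    """Ordered forests sampled along an approximate geodesic."""

    forests: list[Forest]
    k: int
    method: str  # recursive | symmetrized

    @property
    def n_points(self) -> int:
        return len(self.forests)

    def covariances(self) -> list[np.ndarray]:
        return [covariance_matrix(f) for f in self.forests]

    def segment_lengths(self) -> np.ndarray:
        covs = self.covariances()
        return np.array([spd_distance(covs[i], covs[i + 1])
                         for i in range(len(covs) - 1)])

    def coordinates(self, template: Forest) -> np.ndarray:
        """Length vectors of the sampled forests in ``template``'s
        coordinate order (only valid while topologies match)."""
        return np.array([f.length_vector() for f in self.forests])


def resolved_representative(forest: Forest, eps: float = 1e-8,
                            prefer: Topology | None = None) -> Forest:
    """A fully resolved tree representing (a point near) ``forest``.

    Unresolved vertices are expanded with internal edges of length
    ``eps``; if ``prefer`` is given, its internal splits are used for the
    expansion.  Needed to seed gradient-descent projections at boundary
    points such as star trees.
    """
    if forest.is_resolved():
        return forest
    if not forest.is_single_tree():
        raise ValueError("resolved representative requires a single tree")
    topo = forest.topology()
    lengths = {s: forest.edge_length(e)
               for s, e in zip([forest.split_of_edge(e) for e in forest.edges()],
                               forest.edges())}
    if prefer is None:
        # deterministic resolution: greedily add compatible internal splits
        from .forest_core import enumerate_topologies
        n = forest.n_leaves
        for cand in enumerate_topologies(n):
            if topo.splits <= cand.splits:
                prefer = cand
                break
        if prefer is None:
            raise ValueError("no resolving topology found")
    if not topo.splits <= prefer.splits:
        raise ValueError("prefer topology does not refine the forest")
    full = {s: lengths.get(s, eps) for s in prefer.splits}
    return prefer.to_tree(full)


def _project_step(s: np.ndarray, init: Forest) -> Forest:
    init = resolved_representative(init)
    res = project_crossing(s, init)
    return res.forest


def recursive_path(f1: Forest, f2: Forest, k: int = DEFAULT_K) -> DiscretePath:
    """One-ended recursive construction of an approximate geodesic.

    At iteration i the ambient geodesic from the current forest's
    covariance to the destination's is followed a proportion
    ``1/(k-i+1)`` and the point projected into wald space, the descent
    initialized from the previous forest.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    s_end = covariance_matrix(f2)
    forests = [f1]
    for i in range(1, k):
        cur = forests[-1]
        s_cur = covariance_matrix(cur)
        gamma = spd_geodesic(s_cur, s_end)
        s = gamma(1.0 / (k - i + 1))
        forests.append(_project_step(s, cur))
    forests.append(f2)
    return DiscretePath(forests=forests, k=k, method="recursive")


def symmetrized_path(f1: Forest, f2: Forest, k: int = DEFAULT_K) -> DiscretePath:
    """Two-ended symmetrized construction.

    Grows sequences G (from f1) and H (from f2); iteration i projects the
    ambient-geodesic points at proportions ``1/(k-i+1)`` and
    ``1 - 1/(k-i+1)`` between the current G and H heads.  The output is
    ``[G_0 .. G_{k-1}, H_{k-1} .. H_0]``; the seam segment between the
    two half-sequences is part of the path.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    gs = [f1]
    hs = [f2]
    for i in range(1, k):
        s_g = covariance_matrix(gs[-1])
        s_h = covariance_matrix(hs[-1])
        gamma = spd_geodesic(s_g, s_h)
        t = 1.0 / (k - i + 1)
        r = gamma(t)
        s = gamma(1.0 - t)
        gs.append(_project_step(r, gs[-1]))
        hs.append(_project_step(s, hs[-1]))
    return DiscretePath(forests=gs + hs[::-1], k=k, method="symmetrized")


def discrete_length(path: DiscretePath) -> float:
    """Sum of d_cov over successive path points (>= the ambient chord)."""
    return float(path.segment_lengths().sum())


def star_stratum_curve(lambda0: float, lambda_grid: Sequence[float],
                       k: int = DEFAULT_K) -> pd.DataFrame:
    """Approximate intrinsic distances from G(lambda0) to star trees.

    ``G(lambda0)`` is the resolved 4-leaf tree with every edge weight
    lambda0 (split {1,2}|{3,4}); ``F(lambda)`` is the 4-leaf star with
    all pendant weights lambda.  For each grid value the symmetrized
    algorithm is run and the summed d_cov recorded.  Returns a DataFrame
    with columns ``lam`` and ``distance``.
    """
    from .cli_fixtures import fixture

    if not 0 < lambda0 <= 1:
        raise ValueError("lambda0 must lie in (0, 1]")
    g1 = fixture("G_lambda0", lam=lambda0)
    rows = []
    for lam in lambda_grid:
        if not 0 < lam <= 1:
            raise ValueError("lambda grid values must lie in (0, 1]; "
                             "lam = 0 is rank-deficient")
        star = fixture("F_star_lambda", lam=lam)
        path = symmetrized_path(g1, star, k=k)
        rows.append({"lam": float(lam), "distance": discrete_length(path)})
    return pd.DataFrame(rows)
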