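"""Gaussian (Ornstein-Uhlenbeck) process geometry on forests.

A stationary OU process with unit stationary variance run over a forest
induces a zero-mean multivariate normal at the leaves with covariance
``S_F = (exp(-l_uv))``, where ``l_uv`` is the leaf path length (infinite
across components, so cross-component entries vanish).  The Fisher
information metric of zero-mean Gaussians is the trace form

    <X, Y>_S = tr(S^-1 X S^-1 Y) / 2,

and pulling it back through the embedding ``l -> S_l`` gives a closed-form
metric tensor on each orthant of wald space:

    g_ij = tr(S^-1 (S o sigma^i) S^-1 (S o sigma^j)) / 2,

with ``sigma^e`` the 0/1 split matrix of edge ``e`` and ``o`` the Hadamard
product.  First and second derivatives of ``S`` in the edge lengths are
again Hadamard products (``d_i S = -(S o sigma^i)``), so metric
derivatives, Christoffel symbols and the full curvature tensor are exact.
"""

from __future__ import annotations

import numpy as np

from .forest_core import Forest, leaf_distance_matrix, split_matrices
from .two_state_model import christoffel_from_metric

__all__ = [
    "covariance_matrix",
    "covariance_derivative",
    "gaussian_inner_product",
    "fisher_information_gaussian",
    "christoffel_gaussian",
    "riemann_tensor",
    "sectional_curvature",
]

#: relative eigenvalue floor below which a matrix is treated as singular
EIG_FLOOR = 1e-12


def covariance_matrix(forest: Forest) -> np.ndarray:
    """Leaf covariance S_F with entries exp(-l_uv); unit diagonal."""
    d = leaf_distance_matrix(forest)
    with np.errstate(under="ignore"):
        return np.exp(-d)


def _check_pd(s: np.ndarray, what: str = "matrix") -> None:
    s = np.asarray(s, float)
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError(f"{what} is not symmetric")
    w = np.linalg.eigvalsh(s)
    if w[0] <= EIG_FLOOR * max(w[-1], 1.0):
        raise ValueError(f"{what} is not positive definite "
                         f"(min eigenvalue {w[0]:.3e})")


def covariance_derivative(tree: Forest, edge) -> np.ndarray:
    """d S_l / d l^e = -(S_l o sigma^e), from differentiating the
    product-over-edges form of S."""
    from .forest_core import split_matrix

    s = covariance_matrix(tree)
    return -(split_matrix(tree, edge) * s)


def gaussian_inner_product(s: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    """Fisher metric of zero-mean Gaussians: tr(S^-1 X S^-1 Y) / 2."""
    _check_pd(s, "S")
    sinv = np.linalg.inv(s)
    return 0.5 * float(np.trace(sinv @ x @ sinv @ y))


class _OrthantGeometry:
    """Shared workspace for the Gaussian metric on one resolved tree:
    S, its inverse, split matrices and the Hadamard derivative stacks."""

    def __init__(self, tree: Forest):
        if not tree.is_resolved():
            raise ValueError("Gaussian metric coordinates require a "
                             "fully resolved tree")
        lv = tree.length_vector()
        if np.any(np.isinf(lv)):
            raise ValueError("edge lengths must be finite")
        self.tree = tree
        self.sigmas = np.array(split_matrices(tree))  # [E, N, N]
        self.S = covariance_matrix(tree)
        _check_pd(self.S, "covariance matrix")
        self.Sinv = np.linalg.inv(self.S)
        self.E = self.sigmas.shape[0]
        # D[i] = d_i S = -(S o sigma^i); A[i] = S^-1 D[i]
        self.D = -(self.sigmas * self.S)
        self.A = np.einsum("ab,ibc->iac", self.Sinv, self.D)
        # H[i, k] = d_k d_i S = sigma^i o sigma^k o S
        self.H = np.einsum("iab,kab,ab->ikab", self.sigmas, self.sigmas, self.S)

    def metric(self) -> np.ndarray:
        g = 0.5 * np.einsum("iab,jba->ij", self.A, self.A)
        return (g + g.T) / 2

    def dA(self) -> np.ndarray:
        """dA[k, i] = d_k A_i = -A_k A_i + S^-1 H_ik."""
        out = -np.einsum("kab,ibc->kiac", self.A, self.A)
        out += np.einsum("ab,ikbc->kiac", self.Sinv, self.H)
        return out

    def metric_derivative(self) -> np.ndarray:
        """dg[k, i, j] = d_k g_ij (exact)."""
        dA = self.dA()
        dg = 0.5 * (np.einsum("kiab,jba->kij", dA, self.A)
                    + np.einsum("iab,kjba->kij", self.A, dA))
        return (dg + dg.transpose(0, 2, 1)) / 2

    def metric_second_derivative(self) -> np.ndarray:
        """d2g[l, k, i, j] = d_l d_k g_ij (exact).

        Uses d_l d_k A_i = -(d_l A_k) A_i - A_k (d_l A_i)
                           - A_l S^-1 H_ik - S^-1 (sigma^i o sigma^k o sigma^l o S).
        """
        dA = self.dA()
        SinvH = np.einsum("ab,ikbc->ikac", self.Sinv, self.H)  # [i,k]
        # M[i,k,l] = sigma^i o sigma^k o sigma^l o S
        M = np.einsum("iab,kab,lab,ab->iklab", self.sigmas, self.sigmas,
                      self.sigmas, self.S)
        d2A = (-np.einsum("lkab,ibc->lkiac", dA, self.A)
               - np.einsum("kab,libc->lkiac", self.A, dA)
               - np.einsum("lab,ikbc->lkiac", self.A, SinvH)
               - np.einsum("ab,iklbc->lkiac", self.Sinv, M))
        d2g = 0.5 * (np.einsum("lkiab,jba->lkij", d2A, self.A)
                     + np.einsum("kiab,ljba->lkij", dA, dA)
                     + np.einsum("liab,kjba->lkij", dA, dA)
                     + np.einsum("iab,lkjba->lkij", self.A, d2A))
        return d2g


def fisher_information_gaussian(tree: Forest) -> np.ndarray:
    """Metric tensor g_ij = tr(S^-1 (S o sigma^i) S^-1 (S o sigma^j))/2."""
    return _OrthantGeometry(tree).metric()


def metric_and_derivative_gaussian(tree: Forest) -> tuple[np.ndarray, np.ndarray]:
    geo = _OrthantGeometry(tree)
    return geo.metric(), geo.metric_derivative()


def christoffel_gaussian(tree: Forest) -> np.ndarray:
    """Christoffel symbols Gamma[k, i, j] of the Gaussian orthant metric."""
    g, dg = metric_and_derivative_gaussian(tree)
    return christoffel_from_metric(g, dg)


def riemann_tensor(tree: Forest) -> np.ndarray:
    """Fully covariant curvature tensor R[i, j, k, l] = R_ijkl.

    Assembled from the coordinate formula
    R^r_{sij} = d_i Gamma^r_{js} - d_j Gamma^r_{is}
                + Gamma^r_{ia} Gamma^a_{js} - Gamma^r_{ja} Gamma^a_{is},
    lowered with g.  All metric derivatives are analytic.
    """
    geo = _OrthantGeometry(tree)
    g = geo.metric()
    dg = geo.metric_derivative()
    d2g = geo.metric_second_derivative()
    ginv = np.linalg.inv(g)
    gamma = christoffel_from_metric(g, dg)
    # dGamma[m, k, i, j] = d_m Gamma^k_ij
    dginv = -np.einsum("ka,mab,bl->mkl", ginv, dg, ginv)
    term = (np.einsum("ilj->lij", dg) + np.einsum("jli->lij", dg) - dg)
    dterm = (np.einsum("milj->mlij", d2g) + np.einsum("mjli->mlij", d2g)
             - d2g)
    dgamma = 0.5 * (np.einsum("mkl,lij->mkij", dginv, term)
                    + np.einsum("kl,mlij->mkij", ginv, dterm))
    # R^r_{s i j}
    riem_up = (np.einsum("irjs->rsij", dgamma)
               - np.einsum("jris->rsij", dgamma)
               + np.einsum("ria,ajs->rsij", gamma, gamma)
               - np.einsum("rja,ais->rsij", gamma, gamma))
    return np.einsum("mr,rsij->msij", g, riem_up)  # R_{m s i j}


def sectional_curvature(tree: Forest, plane: tuple[int, int],
                        riem: np.ndarray | None = None,
                        g: np.ndarray | None = None) -> float:
    """Sectional curvature of the coordinate plane spanned by edges i, j.

    K(i, j) = R_ijji / (g_ii g_jj - g_ij^2), indices in edge_order().
    """
    i, j = plane
    if i == j:
        raise ValueError("sectional curvature needs two distinct directions")
    if riem is None:
        riem = riemann_tensor(tree)
    if g is None:
        g = fisher_information_gaussian(tree)
    denom = g[i, i] * g[j, j] - g[i, j] ** 2
    if denom <= 0:
        raise ValueError("degenerate coordinate plane")
    return float(riem[i, j, j, i] / denom)
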