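"""Affine-invariant (Fisher-Rao) geometry on symmetric positive definite
matrices.

This is the ambient geometry into which wald space embeds via the leaf
covariance map.  Distance and geodesics are closed-form:

    d(S1, S2)^2 = tr(log(S1^-1/2 S2 S1^-1/2)^2) / 2
    Gamma(t)    = S1^1/2 exp(t U) S1^1/2,   U = log(S1^-1/2 S2 S1^-1/2)

All matrix functions go through one symmetric eigendecomposition per
matrix; a matrix whose smallest eigenvalue falls below a relative floor is
rejected rather than regularized, since rank deficiency of a candidate
covariance matrix signals a degenerate forest.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "spd_distance",
    "spd_geodesic_point",
    "spd_geodesic",
    "matrix_sqrt_log",
    "read_spd_matrix",
    "write_spd_matrix",
]

EIG_FLOOR = 1e-12


def _eigh_checked(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("matrix is not symmetric")
    w, v = np.linalg.eigh((s + s.T) / 2)
    if w[0] <= EIG_FLOOR * max(w[-1], 1.0):
        raise ValueError(
            f"matrix is not positive definite (min eigenvalue {w[0]:.3e})")
    return w, v


def matrix_sqrt_log(s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (S^1/2, S^-1/2, log S) from one eigendecomposition."""
    w, v = _eigh_checked(s)
    sq = (v * np.sqrt(w)) @ v.T
    isq = (v / np.sqrt(w)) @ v.T
    lg = (v * np.log(w)) @ v.T
    return sq, isq, lg


def spd_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """Affine-invariant distance d with d^2 = tr(log(S1^-1/2 S2 S1^-1/2)^2)/2."""
    _, isq, _ = matrix_sqrt_log(s1)
    m = isq @ np.asarray(s2, float) @ isq
    w, _ = _eigh_checked(m)
    return float(np.sqrt(0.5 * np.sum(np.log(w) ** 2)))


def spd_geodesic_point(s1: np.ndarray, s2: np.ndarray, t: float) -> np.ndarray:
    """Point at proportion t in [0, 1] along the unique geodesic S1 -> S2."""
    return spd_geodesic(s1, s2)(t)


def spd_geodesic(s1: np.ndarray, s2: np.ndarray):
    """Return the geodesic evaluator t -> S1^1/2 exp(t U) S1^1/2.

    Factorizes the endpoints once so repeated evaluation is cheap.
    """
    sq, isq, _ = matrix_sqrt_log(s1)
    m = isq @ np.asarray(s2, float) @ isq
    w, v = _eigh_checked(m)
    logw = np.log(w)

    def evaluator(t: float) -> np.ndarray:
        expm = (v * np.exp(t * logw)) @ v.T
        out = sq @ expm @ sq
        return (out + out.T) / 2

    return evaluator


def read_spd_matrix(path) -> np.ndarray:
    """Read a whitespace-delimited symmetric positive definite matrix."""
    m = np.loadtxt(path)
    if m.ndim == 0:
        m = m.reshape(1, 1)
    _eigh_checked(m)
    return m


def write_spd_matrix(path, s: np.ndarray) -> None:
    np.savetxt(path, np.asarray(s, float), fmt="%.12g")
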