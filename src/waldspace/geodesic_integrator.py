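"""Geodesic shooting within a maximal orthant of wald space.

Solves the geodesic ODE

    d2 l^k/dt2 + Gamma^k_ij(l) dl^i/dt dl^j/dt = 0

with classical RK4, using the exact Christoffel symbols of either the
two-state Fisher metric or the Gaussian covariance metric.  Boundary
handling follows the stratified structure of the space:

* an *internal* coordinate reaching 0 is a codimension-1 BHV boundary;
  integration stops there (the crossing time is refined by bisection);
* a *pendant* coordinate reaching 0 is clamped to 0, its velocity zeroed,
  and integration continues;
* in weight coordinates ``lam = 1 - exp(-l)`` a coordinate reaching 1 is
  the boundary at infinity; integration stops there.

Integration can be carried out in length (``l``) or weight (``lam``)
coordinates; the Christoffel symbols are transformed analytically under
the diagonal change of coordinates, so the loci agree where both charts
are valid, while only the weight chart can reach the boundary at infinity
at finite parameter time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .forest_core import Forest
from .gaussian_model import (
    fisher_information_gaussian,
    metric_and_derivative_gaussian,
)
from .two_state_model import (
    christoffel_from_metric,
    fisher_information_two_state,
    metric_and_derivative_two_state,
)

__all__ = ["GeodesicState", "PiecewisePath", "shoot_geodesic",
           "distance_field", "riemannian_path_length"]

DEFAULT_STEP = 5e-3
BISECT_TOL = 1e-10
#: a weight within this margin of 1 counts as the boundary at infinity;
#: the orthant metric degenerates on that face (directions inside freshly
#: disconnected components stop affecting the distribution), so arrival is
#: declared just before it
INF_TOL = 1e-5


@dataclass
class GeodesicState:
    """A point of the geodesic flow: coordinates, velocity and time."""

    coords: np.ndarray
    velocity: np.ndarray
    t: float


@dataclass
class PiecewisePath:
    """Sampled geodesic trajectory within one orthant (closure).

    ``coords[k]`` holds the coordinate vector at ``times[k]`` in the given
    parametrization, ordered as :meth:`Forest.edge_order` of ``template``.
    """

    template: Forest
    times: np.ndarray
    coords: np.ndarray
    velocities: np.ndarray
    model: str
    parametrization: str = "length"
    status: str = "completed"
    clamped: list[int] = field(default_factory=list)

    def lengths(self) -> np.ndarray:
        """Coordinate samples converted to the length parametrization."""
        if self.parametrization == "length":
            return self.coords
        with np.errstate(divide="ignore"):
            return -np.log1p(-np.minimum(self.coords, 1.0))

    def forest_at(self, k: int) -> Forest:
        return self.template.with_lengths(self.lengths()[k])

    def samples(self) -> list[tuple[float, Forest]]:
        return [(float(t), self.forest_at(k))
                for k, t in enumerate(self.times)]

    @property
    def n_samples(self) -> int:
        return len(self.times)


def _metric_functions(model: str):
    if model == "two_state":
        return fisher_information_two_state, metric_and_derivative_two_state
    if model == "gaussian":
        return fisher_information_gaussian, metric_and_derivative_gaussian
    raise ValueError(f"unknown model {model!r}")


def _christoffel_in_coords(tree: Forest, x: np.ndarray, model: str,
                           parametrization: str) -> np.ndarray:
    """Gamma at coordinate vector x, in the requested parametrization.

    The weight-chart symbols are assembled from the weight-chart metric
    g'_ij = g_ij c_i c_j (with c_i = dl/dlam = 1/(1-lam_i)) and its exact
    lam-derivative rather than by transforming the length-chart symbols:
    near the boundary at infinity the length-chart metric degenerates
    numerically while the weight-chart one stays well conditioned.
    """
    _, mad = _metric_functions(model)
    if parametrization == "length":
        g, dg = mad(tree.with_lengths(x))
        return christoffel_from_metric(g, dg)
    lam = x
    l = -np.log1p(-lam)
    g, dg = mad(tree.with_lengths(l))
    c = 1.0 / (1.0 - lam)  # dl/dlam
    gw = g * c[:, None] * c[None, :]
    # d g'_ij / d lam_k = (d_k g_ij) c_k c_i c_j
    #                     + g_ij c_i c_j (delta_ik c_i + delta_jk c_j)
    dgw = dg * c[:, None, None] * c[None, :, None] * c[None, None, :]
    E = len(lam)
    idx = np.arange(E)
    extra = np.zeros((E, E, E))
    extra[idx, idx, :] += (gw * c[:, None])[idx, :]
    extra[idx, :, idx] += (gw * c[None, :])[:, idx].T
    dgw = dgw + extra
    return christoffel_from_metric(gw, dgw)


def _metric_in_coords(tree: Forest, x: np.ndarray, model: str,
                      parametrization: str) -> np.ndarray:
    metric, _ = _metric_functions(model)
    if parametrization == "length":
        return metric(tree.with_lengths(x))
    l = -np.log1p(-np.minimum(x, 1 - 1e-15))
    g = metric(tree.with_lengths(l))
    scale = 1.0 / (1.0 - x)
    return g * scale[:, None] * scale[None, :]


def shoot_geodesic(tree: Forest, v0: Sequence[float], t_max: float,
                   step: float = DEFAULT_STEP, model: str = "gaussian",
                   parametrization: str = "length",
                   unit_speed: bool = False) -> PiecewisePath:
    """Integrate the geodesic ODE from ``tree`` with initial velocity v0.

    ``v0`` is given in :meth:`Forest.edge_order` coordinates of the chosen
    parametrization.  Returns the sampled trajectory; ``status`` records
    whether integration completed, hit a BHV boundary (an internal
    coordinate reached 0) or the boundary at infinity (a weight reached 1).
    """
    if not tree.is_resolved():
        raise ValueError("geodesic shooting requires a fully resolved tree")
    if parametrization not in ("length", "weight"):
        raise ValueError(f"unknown parametrization {parametrization!r}")
    order = tree.edge_order()
    splits = [tree.split_of_edge(e) for e in order]
    pendant = np.array([s.is_pendant for s in splits])
    x = tree.length_vector().astype(float)
    if parametrization == "weight":
        x = -np.expm1(-x)
    v = np.asarray(v0, dtype=float).copy()
    if v.shape != x.shape:
        raise ValueError("v0 must have one entry per edge (2N-3)")
    if unit_speed and np.any(v):
        g = _metric_in_coords(tree, x, model, parametrization)
        v = v / math.sqrt(v @ g @ v)

    free = np.ones_like(x, dtype=bool)  # pendant clamp mask
    clamped: list[int] = []

    def accel(xx: np.ndarray, vv: np.ndarray) -> np.ndarray:
        # RK4 stages may poke just past a boundary; evaluate Gamma at the
        # nearest valid chart point (the step itself is event-checked)
        if parametrization == "weight":
            xx = np.clip(xx, 0.0, 1.0 - INF_TOL)
        else:
            xx = np.maximum(xx, 0.0)
        gamma = _christoffel_in_coords(tree, xx, model, parametrization)
        a = -np.einsum("kij,i,j->k", gamma, vv, vv)
        a[~free] = 0.0
        return a

    def rk4(xx, vv, h):
        k1x, k1v = vv, accel(xx, vv)
        k2x, k2v = vv + h / 2 * k1v, accel(xx + h / 2 * k1x, vv + h / 2 * k1v)
        k3x, k3v = vv + h / 2 * k2v, accel(xx + h / 2 * k2x, vv + h / 2 * k2v)
        k4x, k4v = vv + h * k3v, accel(xx + h * k3x, vv + h * k3v)
        nx = xx + h / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
        nv = vv + h / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
        nv[~free] = 0.0
        nx[~free] = 0.0
        return nx, nv

    def internal_exit(xx) -> bool:
        bad = (xx <= 0) & ~pendant
        if parametrization == "weight":
            bad |= xx >= 1.0 - INF_TOL
        return bool(np.any(bad))

    times = [0.0]
    xs = [x.copy()]
    vs = [v.copy()]
    status = "completed"
    t = 0.0
    n_steps = int(round(t_max / step))
    for _ in range(n_steps):
        h = min(step, t_max - t)
        if h <= 0:
            break
        nx, nv = rk4(x, v, h)
        if internal_exit(nx):
            # bisection refinement of the event time
            lo, hi = 0.0, h
            while hi - lo > BISECT_TOL:
                mid = (lo + hi) / 2
                mx, _ = rk4(x, v, mid)
                if internal_exit(mx):
                    hi = mid
                else:
                    lo = mid
            nx, nv = rk4(x, v, lo)
            t += lo
            np.clip(nx, 0.0, 1.0 if parametrization == "weight" else None,
                    out=nx)
            times.append(t)
            xs.append(nx)
            vs.append(nv)
            if parametrization == "weight" and np.any(nx >= 1.0 - 2 * INF_TOL):
                status = "boundary_at_infinity"
            else:
                status = "bhv_boundary"
            break
        # pendant clamping: zero coordinate and velocity, keep going
        neg_pendant = (nx < 0) & pendant
        if np.any(neg_pendant):
            for i in np.where(neg_pendant)[0]:
                clamped.append(int(i))
            nx[neg_pendant] = 0.0
            nv[neg_pendant] = 0.0
            free[neg_pendant] = False
        x, v = nx, nv
        t += h
        times.append(t)
        xs.append(x.copy())
        vs.append(v.copy())
    return PiecewisePath(
        template=tree, times=np.array(times), coords=np.array(xs),
        velocities=np.array(vs), model=model, parametrization=parametrization,
        status=status, clamped=sorted(set(clamped)))


def riemannian_path_length(path: PiecewisePath, model: str | None = None) -> float:
    """Riemann-sum length: sum of sqrt(dx' g(mid) dx) over segments."""
    model = model or path.model
    total = 0.0
    for k in range(path.n_samples - 1):
        a, b = path.coords[k], path.coords[k + 1]
        mid = (a + b) / 2
        if path.parametrization == "weight":
            mid = np.minimum(mid, 1 - 1e-12)
        g = _metric_in_coords(path.template, mid, model, path.parametrization)
        d = b - a
        q = float(d @ g @ d)
        total += math.sqrt(max(q, 0.0))
    return total


def distance_field(tree0: Forest, directions: Sequence[float] | int,
                   t_max: float, model: str = "gaussian",
                   step: float = DEFAULT_STEP,
                   parametrization: str = "length") -> pd.DataFrame:
    """Fan of unit-speed geodesics fired in the internal-edge plane.

    ``directions`` is a number of equally spaced angles or an explicit list
    of angles (radians) in the plane of the internal-edge coordinates; the
    initial pendant velocity is zero.  Returns a tidy table with one row
    per (direction, time) sample; time equals arc length by unit-speed
    normalization.
    """
    if isinstance(directions, int):
        directions = [2 * math.pi * k / directions for k in range(directions)]
    order = tree0.edge_order()
    internal = [k for k, e in enumerate(order)
                if not tree0.split_of_edge(e).is_pendant]
    if len(internal) != 2:
        raise ValueError("distance_field expects exactly 2 internal edges")
    rows = []
    for ang in directions:
        v0 = np.zeros(len(order))
        v0[internal[0]] = math.cos(ang)
        v0[internal[1]] = math.sin(ang)
        path = shoot_geodesic(tree0, v0, t_max, step=step, model=model,
                              parametrization=parametrization,
                              unit_speed=True)
        for k in range(path.n_samples):
            rec = {"direction": ang, "t": path.times[k],
                   "status": path.status}
            for idx, e in enumerate(order):
                rec[f"x{idx + 1}"] = path.coords[k][idx]
            rows.append(rec)
    return pd.DataFrame(rows)
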