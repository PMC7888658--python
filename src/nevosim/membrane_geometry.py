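"""Composite differentiable-manifold model of the basal membrane.

The membrane is a height field over a rectangular horizontal extent.  It is
assembled from three ingredients:

* a planar base part (altitude zero),
* dermal papillae: surfaces of revolution over pairwise disjoint base disks,
  each generated by a C3 shape curve ``theta -> (r(theta), h(theta))`` built
  from clamped quintic B-splines,
* a coarse vertical deformation ``chi`` given by a superposition of radially
  symmetric bumps that reuse the endpoint-flat vertical profile family.

Chart convention: every surface point maps to a 2D chart coordinate ``u``.
On the planar (possibly chi-deformed) part ``u`` is simply the horizontal
projection.  Inside the base disk of papilla *i* the chart coordinate is
``u = c_i + theta * e_alpha`` where ``theta`` is the *virtual* radius of the
shape curve, so the chart disk and the base disk share the radius ``R_i``.
The endpoint conditions of the shape curve (unit radial slope, vanishing
higher derivatives) make the induced metric continuously differentiable
across disk rims, so geodesics can be integrated in one global coordinate
frame without explicit chart handover.

Coordinates are right handed, z up, all lengths in micrometres; altitude
zero is the base plane of the rete ridges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.spatial import cKDTree

from .errors import (
    ConstructionError,
    ContractViolationError,
    DomainError,
    DomainExit,
    OffManifoldError,
    ParameterDomainError,
)

__all__ = [
    "ShapeCurve",
    "PapillaChart",
    "DeformationBump",
    "MembraneModel",
    "build_shape_curve",
    "surface_point",
    "chart_forward",
    "chart_inverse",
    "metric_tensor",
    "project_to_tangent",
    "pushforward",
    "geodesic_step",
    "P_ADMISSIBLE",
]

#: Admissible interval of the scalar shape parameter p.  p=0 yields the
#: conical/rounded profile (radial component is the identity), p=1 the most
#: shouldered, near-cylindrical profile.
P_ADMISSIBLE = (0.0, 1.0)

_DEGREE = 5
_BOUNDARY_TOL = 1e-6

# Fraction of the gap between the free interior control values and the base
# radius that p=1 closes; chosen so the p=1 profile stays a strict bijection
# while giving a pronounced shoulder (broadest admissible family found by a
# monotonicity sweep at build time).
_P_GAIN_4 = 0.55
_P_GAIN_5 = 0.45

# Interior control values of the vertical component, as fractions of H.
_H_C4 = 0.82
_H_C5 = 0.22


def _clamped_knots(span: float, degree: int, n_interior: int = 4) -> np.ndarray:
    interior = np.linspace(0.0, span, n_interior + 2)[1:-1]
    return np.concatenate(
        [np.zeros(degree + 1), interior, np.full(degree + 1, span)]
    )


def _endpoint_solve(knots, degree, left_values, right_values):
    """Solve for the 4 leading/trailing control points from endpoint data.

    ``left_values``/``right_values`` give (f, f', f'', f''') at 0 and at the
    right end of the knot span.  Derivatives of order <= 3 of a clamped
    quintic only involve the first/last four coefficients.
    """
    n = len(knots) - degree - 1
    span = knots[-1]
    rows_l = np.zeros((4, 4))
    rows_r = np.zeros((4, 4))
    for j in range(4):
        e = np.zeros(n)
        e[j] = 1.0
        b = BSpline(knots, e, degree)
        for m in range(4):
            rows_l[m, j] = b.derivative(m)(0.0) if m else b(0.0)
        e = np.zeros(n)
        e[n - 4 + j] = 1.0
        b = BSpline(knots, e, degree)
        for m in range(4):
            rows_r[m, j] = b.derivative(m)(span) if m else b(span)
    c_left = np.linalg.solve(rows_l, np.asarray(left_values, float))
    c_right = np.linalg.solve(rows_r, np.asarray(right_values, float))
    return c_left, c_right


def _greville(knots: np.ndarray, degree: int) -> np.ndarray:
    n = len(knots) - degree - 1
    return np.array([knots[j + 1 : j + 1 + degree].mean() for j in range(n)])


@dataclass
class ShapeCurve:
    """C3 generator curve of one papilla surface of revolution.

    ``r`` maps the virtual radius ``theta in [0, R]`` bijectively onto the
    physical radius, ``h`` gives the altitude profile from ``H`` at the apex
    down to zero at the rim.
    """

    R: float
    H: float
    p: float
    r_coeffs: np.ndarray
    h_coeffs: np.ndarray
    degree: int = _DEGREE
    _knots: np.ndarray = field(default=None, repr=False)
    _r: BSpline = field(default=None, repr=False)
    _h: BSpline = field(default=None, repr=False)

    def __post_init__(self):
        if self._knots is None:
            self._knots = _clamped_knots(self.R, self.degree)
        self._r = BSpline(self._knots, self.r_coeffs, self.degree)
        self._h = BSpline(self._knots, self.h_coeffs, self.degree)
        self._dr = self._r.derivative()
        self._dh = self._h.derivative()
        self._d2r = self._dr.derivative()
        self._d2h = self._dh.derivative()
        # dense monotone table for fast inversion of r
        grid = np.linspace(0.0, self.R, 512)
        self._inv_r_grid = np.asarray(self._r(grid))
        self._inv_theta_grid = grid

    # -- evaluation -------------------------------------------------------
    def r(self, theta):
        return self._r(np.clip(theta, 0.0, self.R))

    def h(self, theta):
        return self._h(np.clip(theta, 0.0, self.R))

    def dr(self, theta):
        return self._dr(np.clip(theta, 0.0, self.R))

    def dh(self, theta):
        return self._dh(np.clip(theta, 0.0, self.R))

    def r_inverse(self, radius, newton_iters: int = 3):
        """theta such that r(theta) = radius, vectorised (radius in [0, R])."""
        radius = np.clip(np.asarray(radius, float), 0.0, self.R)
        theta = np.interp(radius, self._inv_r_grid, self._inv_theta_grid)
        for _ in range(newton_iters):
            theta = theta - (self._r(theta) - radius) / self._dr(theta)
            theta = np.clip(theta, 0.0, self.R)
        return theta

    def height_to_theta(self, z, newton_iters: int = 40):
        """theta such that h(theta) = z for monotone profiles (bisection)."""
        z = float(z)
        lo, hi = 0.0, self.R
        for _ in range(newton_iters):
            mid = 0.5 * (lo + hi)
            if self._h(mid) > z:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


def build_shape_curve(R: float, H: float, p: float, degree: int = _DEGREE) -> ShapeCurve:
    """Construct the shape curve for base radius ``R``, height ``H``, shape ``p``.

    The radial and vertical components are clamped quintic B-splines whose
    four leading and trailing control points are pinned by the endpoint
    conditions (``r(0)=0, r(R)=R``, unit end slopes, vanishing second and
    third derivatives; ``h(0)=H, h(R)=0`` with flat ends).  The two free
    interior control vertices of the radial component are displaced towards
    the base radius by ``p``, which broadens the shoulder of the profile.
    """
    if R <= 0 or H <= 0:
        raise ParameterDomainError(f"R and H must be positive, got R={R}, H={H}")
    lo, hi = P_ADMISSIBLE
    if not (lo <= p <= hi):
        raise ParameterDomainError(f"shape parameter p={p} outside [{lo}, {hi}]")
    if degree < 3:
        raise ParameterDomainError("spline degree must be >= 3")
    if degree != _DEGREE:
        raise ParameterDomainError(
            "only the quintic construction is supported (degree 5)"
        )

    knots = _clamped_knots(R, degree)
    greville = _greville(knots, degree)

    # radial component: identity baseline, p raises the two free vertices
    cl, cr = _endpoint_solve(knots, degree, (0.0, 1.0, 0.0, 0.0), (R, 1.0, 0.0, 0.0))
    r_coeffs = greville.copy()
    r_coeffs[:4] = cl
    r_coeffs[-4:] = cr
    r_coeffs[4] = greville[4] + p * _P_GAIN_4 * (R - greville[4])
    r_coeffs[5] = greville[5] + p * _P_GAIN_5 * (R - greville[5])

    # vertical component: flat at both ends, fixed interior drop
    cl_h, cr_h = _endpoint_solve(knots, degree, (H, 0.0, 0.0, 0.0), (0.0, 0.0, 0.0, 0.0))
    h_coeffs = np.zeros_like(r_coeffs)
    h_coeffs[:4] = cl_h
    h_coeffs[-4:] = cr_h
    h_coeffs[4] = _H_C4 * H
    h_coeffs[5] = _H_C5 * H

    curve = ShapeCurve(R=R, H=H, p=p, r_coeffs=r_coeffs, h_coeffs=h_coeffs,
                       degree=degree, _knots=knots)
    _validate_curve(curve)
    return curve


def _validate_curve(curve: ShapeCurve) -> None:
    R, H = curve.R, curve.H
    checks = [
        (curve._r(0.0), 0.0), (curve._r(R), R),
        (curve._dr(0.0), 1.0), (curve._dr(R), 1.0),
        (curve._d2r(0.0), 0.0), (curve._d2r(R), 0.0),
        (curve._dr.derivative(2)(0.0), 0.0), (curve._dr.derivative(2)(R), 0.0),
        (curve._h(0.0), H), (curve._h(R), 0.0),
        (curve._dh(0.0), 0.0), (curve._dh(R), 0.0),
        (curve._d2h(0.0), 0.0), (curve._d2h(R), 0.0),
        (curve._dh.derivative(2)(0.0), 0.0), (curve._dh.derivative(2)(R), 0.0),
    ]
    scale = max(R, H)
    for got, want in checks:
        if abs(got - want) > _BOUNDARY_TOL * max(1.0, scale):
            raise ConstructionError(
                f"shape-curve boundary condition violated: got {got}, want {want}"
            )
    grid = np.linspace(0.0, R, 400)
    if np.min(curve._dr(grid)) <= 0.0:
        raise ConstructionError("radial component is not strictly increasing")
    hv = curve._h(grid)
    if hv.min() < -1e-9 * H or hv.max() > H * (1 + 1e-9):
        raise ConstructionError("vertical component leaves [0, H]")


# cached unit bump profile (H=1, R=1 vertical component) used for chi
_UNIT_BUMP: ShapeCurve | None = None


def unit_bump() -> ShapeCurve:
    global _UNIT_BUMP
    if _UNIT_BUMP is None:
        _UNIT_BUMP = build_shape_curve(1.0, 1.0, 0.0)
    return _UNIT_BUMP


@dataclass
class PapillaChart:
    """One papilla: base-disk center ``x_i`` and its shape curve."""

    center: np.ndarray
    shape: ShapeCurve

    def __post_init__(self):
        self.center = np.asarray(self.center, float)


@dataclass
class DeformationBump:
    """Radially symmetric vertical elevation (amplitude>0) or depression."""

    center: np.ndarray
    radius: float
    amplitude: float

    def __post_init__(self):
        self.center = np.asarray(self.center, float)


def surface_point(chart: PapillaChart, alpha: float, theta) -> np.ndarray:
    """Embed local polar coordinates of one papilla into 3-space."""
    theta = np.asarray(theta, float)
    if np.any(theta < 0) or np.any(theta > chart.shape.R + 1e-12):
        raise DomainError("theta outside [0, R]")
    r = chart.shape.r(theta)
    h = chart.shape.h(theta)
    return np.stack(
        [chart.center[0] + r * np.cos(alpha),
         chart.center[1] + r * np.sin(alpha),
         np.broadcast_to(h, np.shape(r)) if np.shape(r) else h],
        axis=-1,
    )


class MembraneModel:
    """The assembled membrane: extent, papillae and vertical deformation."""

    def __init__(self, extent, papillae=(), deformation=()):
        self.extent = (float(extent[0]), float(extent[1]))
        self.papillae = list(papillae)
        self.deformation = list(deformation)
        self._rebuild_index()
        self._validate()

    # -- bookkeeping ------------------------------------------------------
    def _rebuild_index(self):
        if self.papillae:
            self._centers = np.array([p.center for p in self.papillae])
            self._radii = np.array([p.shape.R for p in self.papillae])
            self._tree = cKDTree(self._centers)
            self._kmax = min(len(self.papillae), 8)
        else:
            self._centers = np.zeros((0, 2))
            self._radii = np.zeros(0)
            self._tree = None
            self._kmax = 0

    def _validate(self):
        lx, ly = self.extent
        for pap in self.papillae:
            c, R = pap.center, pap.shape.R
            if not (R <= c[0] <= lx - R and R <= c[1] <= ly - R):
                raise ConstructionError("papilla base disk leaves the extent")
        if len(self.papillae) > 1:
            d, idx = self._tree.query(self._centers, k=2)
            sums = self._radii + self._radii[idx[:, 1]]
            if np.any(d[:, 1] < sums - 1e-9):
                raise ConstructionError("papilla base disks overlap")

    # -- region lookup ----------------------------------------------------
    def locate(self, xi):
        """Index of the papilla disk containing each horizontal point (-1: planar)."""
        xi = np.atleast_2d(np.asarray(xi, float))
        out = np.full(len(xi), -1, dtype=int)
        if self._tree is None:
            return out
        d, idx = self._tree.query(xi, k=self._kmax)
        if self._kmax == 1:
            d, idx = d[:, None], idx[:, None]
        inside = d < self._radii[idx]
        has = inside.any(axis=1)
        first = inside.argmax(axis=1)
        out[has] = idx[has, first[has]]
        return out

    def in_domain(self, u):
        u = np.atleast_2d(np.asarray(u, float))
        lx, ly = self.extent
        return (
            (u[:, 0] >= 0) & (u[:, 0] <= lx) & (u[:, 1] >= 0) & (u[:, 1] <= ly)
        )

    # -- chi deformation --------------------------------------------------
    def chi(self, xi):
        """Coarse vertical deformation evaluated at horizontal points."""
        xi = np.atleast_2d(np.asarray(xi, float))
        z = np.zeros(len(xi))
        prof = unit_bump()
        for bump in self.deformation:
            d = np.linalg.norm(xi - bump.center, axis=1)
            t = np.clip(d / bump.radius, 0.0, 1.0)
            z += bump.amplitude * prof.h(t)
        return z

    def chi_grad(self, xi):
        xi = np.atleast_2d(np.asarray(xi, float))
        g = np.zeros_like(xi)
        prof = unit_bump()
        for bump in self.deformation:
            w = xi - bump.center
            d = np.linalg.norm(w, axis=1)
            mask = (d > 1e-12) & (d < bump.radius)
            t = d[mask] / bump.radius
            mag = bump.amplitude * prof.dh(t) / bump.radius
            g[mask] += (mag / d[mask])[:, None] * w[mask]
        return g

    # -- altitude field ---------------------------------------------------
    def altitude(self, xi, region=None):
        """Surface altitude over horizontal points (single valued)."""
        xi = np.atleast_2d(np.asarray(xi, float))
        z = self.chi(xi)
        region = self.locate(xi) if region is None else region
        for i in np.unique(region):
            if i < 0:
                continue
            pap = self.papillae[i]
            sel = region == i
            d = np.linalg.norm(xi[sel] - pap.center, axis=1)
            theta = pap.shape.r_inverse(d)
            z[sel] += pap.shape.h(theta)
        return z

    def altitude_grad(self, xi, region=None):
        """Horizontal gradient of the altitude field."""
        xi = np.atleast_2d(np.asarray(xi, float))
        g = self.chi_grad(xi)
        region = self.locate(xi) if region is None else region
        for i in np.unique(region):
            if i < 0:
                continue
            pap = self.papillae[i]
            sel = region == i
            w = xi[sel] - pap.center
            d = np.linalg.norm(w, axis=1)
            ok = d > 1e-12
            theta = pap.shape.r_inverse(d[ok])
            slope = pap.shape.dh(theta) / pap.shape.dr(theta)
            gi = np.zeros_like(w)
            gi[ok] = (slope / d[ok])[:, None] * w[ok]
            g[sel] += gi
        return g

    def surface_normal(self, xi, region=None):
        """Upward unit normal at horizontal points (vectorised)."""
        grad = self.altitude_grad(xi, region=region)
        n = np.concatenate([-grad, np.ones((len(grad), 1))], axis=1)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    # -- chart <-> horizontal ---------------------------------------------
    def horizontal_to_chart(self, xi):
        xi = np.atleast_2d(np.asarray(xi, float))
        u = xi.copy()
        region = self.locate(xi)
        for i in np.unique(region):
            if i < 0:
                continue
            pap = self.papillae[i]
            sel = region == i
            w = xi[sel] - pap.center
            d = np.linalg.norm(w, axis=1)
            theta = pap.shape.r_inverse(d)
            scale = np.where(d > 1e-12, theta / np.maximum(d, 1e-12), 1.0)
            u[sel] = pap.center + scale[:, None] * w
        return u

    def chart_to_horizontal(self, u):
        u = np.atleast_2d(np.asarray(u, float))
        xi = u.copy()
        region = self.locate(u)
        for i in np.unique(region):
            if i < 0:
                continue
            pap = self.papillae[i]
            sel = region == i
            w = u[sel] - pap.center
            theta = np.linalg.norm(w, axis=1)
            r = pap.shape.r(theta)
            scale = np.where(theta > 1e-12, r / np.maximum(theta, 1e-12), 1.0)
            xi[sel] = pap.center + scale[:, None] * w
        return xi

    # -- embedding & metric ----------------------------------------------
    def embed(self, u):
        """Chart coordinates -> 3D surface points."""
        u = np.atleast_2d(np.asarray(u, float))
        xi = self.chart_to_horizontal(u)
        z = self.altitude(xi)
        return np.concatenate([xi, z[:, None]], axis=1)

    def embedding_jacobian(self, u):
        """3x2 Jacobian of the embedding at one chart coordinate."""
        u = np.asarray(u, float).reshape(2)
        region = int(self.locate(u[None, :])[0])
        if region < 0:
            xi = u
            dxi = np.eye(2)
        else:
            pap = self.papillae[region]
            w = u - pap.center
            theta = float(np.linalg.norm(w))
            sh = pap.shape
            if theta < 1e-9:
                xi = pap.center.copy()
                dxi = np.eye(2)  # r'(0)=1, a'(0)=0
            else:
                r = float(sh.r(theta))
                drv = float(sh.dr(theta))
                a = r / theta
                da = (drv * theta - r) / theta**2
                xi = pap.center + a * w
                dxi = a * np.eye(2) + (da / theta) * np.outer(w, w)
        # vertical row: d z / d u = (dZ/dxi) . dxi/du   (+ papilla part in theta)
        gz = self.chi_grad(xi[None, :])[0] @ dxi
        if region >= 0:
            pap = self.papillae[region]
            w = u - pap.center
            theta = float(np.linalg.norm(w))
            if theta >= 1e-9:
                gz = gz + float(pap.shape.dh(theta)) * w / theta
        J = np.zeros((3, 2))
        J[:2, :] = dxi
        J[2, :] = gz
        return J

    def metric(self, u):
        J = self.embedding_jacobian(u)
        return J.T @ J

    def _christoffel(self, u, h=1e-4):
        """Christoffel symbols Gamma[k, i, j] from central differences of g."""
        u = np.asarray(u, float)
        g0 = self.metric(u)
        dg = np.zeros((2, 2, 2))
        for m in range(2):
            e = np.zeros(2)
            e[m] = h
            dg[m] = (self.metric(u + e) - self.metric(u - e)) / (2 * h)
        ginv = np.linalg.inv(g0)
        gamma = np.zeros((2, 2, 2))
        for k in range(2):
            for i in range(2):
                for j in range(2):
                    s = 0.0
                    for l in range(2):
                        s += ginv[k, l] * (dg[i][j, l] + dg[j][i, l] - dg[l][i, j])
                    gamma[k, i, j] = 0.5 * s
        return gamma


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers with contract checks)
# ---------------------------------------------------------------------------

def chart_forward(membrane: MembraneModel, x, atol: float = 1e-3) -> np.ndarray:
    """Map a 3D surface point to its 2D chart coordinates."""
    x = np.asarray(x, float).reshape(3)
    xi = x[:2]
    z = membrane.altitude(xi[None, :])[0]
    if abs(z - x[2]) > atol:
        raise OffManifoldError(
            f"point altitude {x[2]:.6f} differs from surface altitude {z:.6f}"
        )
    return membrane.horizontal_to_chart(xi[None, :])[0]


def chart_inverse(membrane: MembraneModel, u) -> np.ndarray:
    """Map 2D chart coordinates to the unique surface point above them."""
    u = np.asarray(u, float).reshape(2)
    if not membrane.in_domain(u[None, :])[0]:
        raise DomainError(f"chart coordinate {u} outside extent {membrane.extent}")
    return membrane.embed(u[None, :])[0]


def metric_tensor(membrane: MembraneModel, u) -> np.ndarray:
    u = np.asarray(u, float).reshape(2)
    if not membrane.in_domain(u[None, :])[0]:
        raise DomainError(f"chart coordinate {u} outside extent {membrane.extent}")
    return membrane.metric(u)


def project_to_tangent(membrane: MembraneModel, x, v, mode: str = "project") -> np.ndarray:
    """Project (default) or rotate a 3D vector into the tangent plane at x."""
    x = np.asarray(x, float).reshape(3)
    v = np.asarray(v, float).reshape(3)
    n = membrane.surface_normal(x[None, :2])[0]
    tangential = v - np.dot(v, n) * n
    if mode == "project":
        return tangential
    if mode == "rotate":
        norm_t = np.linalg.norm(tangential)
        norm_v = np.linalg.norm(v)
        if norm_t < 1e-15:
            return tangential
        return tangential * (norm_v / norm_t)
    raise ParameterDomainError(f"unknown tangent mode {mode!r}")


def pushforward(membrane: MembraneModel, x, v_tan, rtol: float = 1e-6) -> np.ndarray:
    """Identify a tangent 3-vector at x with its 2D chart representative."""
    x = np.asarray(x, float).reshape(3)
    v_tan = np.asarray(v_tan, float).reshape(3)
    u = chart_forward(membrane, x)
    J = membrane.embedding_jacobian(u)
    w, *_ = np.linalg.lstsq(J, v_tan, rcond=None)
    residual = np.linalg.norm(J @ w - v_tan)
    scale = max(np.linalg.norm(v_tan), 1e-12)
    if residual > max(rtol * scale, 1e-9):
        raise ContractViolationError(
            f"input vector is not tangent (residual {residual:.3e})"
        )
    return w


def geodesic_step(
    membrane: MembraneModel,
    u,
    v,
    dt: float,
    max_substep_um: float = 1.0,
    return_velocity: bool = False,
):
    """Integrate the geodesic ODE of the chart metric from (u, v) over dt.

    Classic RK4 on the first-order system with Christoffel symbols evaluated
    from the analytic metric by central differences.  Substeps are bounded so
    no single substep displaces the coordinate by more than ``max_substep_um``.
    Raises :class:`DomainExit` when the path leaves the extent.
    """
    if dt <= 0:
        raise ParameterDomainError("dt must be positive")
    u = np.asarray(u, float).reshape(2).copy()
    v = np.asarray(v, float).reshape(2).copy()
    if not np.all(np.isfinite(v)):
        raise ParameterDomainError("velocity must be finite")
    speed = float(np.linalg.norm(v))
    if speed == 0.0:
        return (u, v) if return_velocity else u
    nsub = max(1, int(np.ceil(speed * dt / max_substep_um)))
    h = dt / nsub

    def acc(uu, vv):
        gamma = membrane._christoffel(uu)
        return -np.einsum("kij,i,j->k", gamma, vv, vv)

    for _ in range(nsub):
        k1u, k1v = v, acc(u, v)
        k2u, k2v = v + 0.5 * h * k1v, acc(u + 0.5 * h * k1u, v + 0.5 * h * k1v)
        k3u, k3v = v + 0.5 * h * k2v, acc(u + 0.5 * h * k2u, v + 0.5 * h * k2v)
        k4u, k4v = v + h * k3v, acc(u + h * k3u, v + h * k3v)
        u = u + (h / 6.0) * (k1u + 2 * k2u + 2 * k3u + k4u)
        v = v + (h / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)
        if not membrane.in_domain(u[None, :])[0]:
            raise DomainExit(u)
    return (u, v) if return_velocity else u


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def membrane_to_dict(membrane: MembraneModel) -> dict:
    return {
        "extent": list(membrane.extent),
        "papillae": [
            {
                "center": list(map(float, p.center)),
                "R": p.shape.R,
                "H": p.shape.H,
                "p": p.shape.p,
                "degree": p.shape.degree,
                "r_coeffs": list(map(float, p.shape.r_coeffs)),
                "h_coeffs": list(map(float, p.shape.h_coeffs)),
            }
            for p in membrane.papillae
        ],
        "deformation": [
            {
                "center": list(map(float, b.center)),
                "radius": b.radius,
                "amplitude": b.amplitude,
            }
            for b in membrane.deformation
        ],
    }


def membrane_from_dict(doc: dict) -> MembraneModel:
    papillae = []
    for rec in doc["papillae"]:
        curve = ShapeCurve(
            R=rec["R"], H=rec["H"], p=rec["p"],
            r_coeffs=np.asarray(rec["r_coeffs"]),
            h_coeffs=np.asarray(rec["h_coeffs"]),
            degree=rec.get("degree", _DEGREE),
        )
        papillae.append(PapillaChart(center=np.asarray(rec["center"]), shape=curve))
    bumps = [
        DeformationBump(np.asarray(b["center"]), b["radius"], b["amplitude"])
        for b in doc.get("deformation", [])
    ]
    return MembraneModel(doc["extent"], papillae, bumps)


def save_membrane(membrane: MembraneModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(membrane_to_dict(membrane), fh, indent=1)


def load_membrane(path) -> MembraneModel:
    with open(path) as fh:
        return membrane_from_dict(json.load(fh))


def export_obj(membrane: MembraneModel, path, resolution: float = 20.0) -> None:
    """Write a triangulated height-field mesh as Wavefront OBJ."""
    lx, ly = membrane.extent
    nx = max(2, int(lx / resolution) + 1)
    ny = max(2, int(ly / resolution) + 1)
    xs = np.linspace(0, lx, nx)
    ys = np.linspace(0, ly, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    z = membrane.altitude(pts)
    with open(path, "w") as fh:
        for (x, y), zz in zip(pts, z):
            fh.write(f"v {x:.3f} {y:.3f} {zz:.3f}\n")
        for i in range(nx - 1):
            for j in range(ny - 1):
                a = i * ny + j + 1
                b = a + ny
                fh.write(f"f {a} {b} {a + 1}\n")
                fh.write(f"f {b} {b + 1} {a + 1}\n")
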