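"""Tensor-product B-spline surfaces in per-span matrix form.

Every nonempty knot span of a uniform B-spline surface evaluates as

    S(t, w) = T M_u V M_v^T W^T ,     T = [1, t, ..., t^k1], W = [1, w, ..., w^k2]

with (t, w) the local parameters of the span mapped to the unit square and
``V`` the (k1+1) x (k2+1) window of control points.  The product
``M_u V M_v^T`` is the span's monomial coefficient grid, so every span is an
explicit polynomial patch — which is what makes closed-form volume
integration possible downstream.

Conventions: control-net axis 0 is the ``u`` (circumferential) direction,
axis 1 the ``v`` (longitudinal) one.  Closure in ``u`` is a periodic wrap
stored as k1 duplicated trailing slices; apex/base closure ("pole caps")
repeats a single pole point in the first/last k2 v-slices.  With a uniform
degree-k basis the end-span boundary weight of the (k+1)-th local control
point is zero, so the boundary curve then degenerates exactly to the pole
and the surface is closed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .meshing import TriangleMesh, build_ring_mesh
from .shape_model import LandmarkShape

__all__ = [
    "BSplineSurface",
    "PolynomialPatch",
    "basis_matrix",
    "evaluate_surface",
    "evaluate_global",
    "to_polynomial_patches",
    "fit_surface_to_landmark_grid",
    "tessellate",
]

_SUPPORTED_ORDERS = (1, 2, 3)


@lru_cache(maxsize=None)
def _basis_matrix_cached(order: int) -> np.ndarray:
    if order == 1:
        M = np.array([[1.0, 0.0], [-1.0, 1.0]])
    elif order == 2:
        M = 0.5 * np.array([[1.0, 1.0, 0.0], [-2.0, 2.0, 0.0], [1.0, -2.0, 1.0]])
    elif order == 3:
        M = (1.0 / 6.0) * np.array(
            [
                [1.0, 4.0, 1.0, 0.0],
                [-3.0, 0.0, 3.0, 0.0],
                [3.0, -6.0, 3.0, 0.0],
                [-1.0, 3.0, -3.0, 1.0],
            ]
        )
    else:
        raise ValueError(
            f"unsupported B-spline order {order}; supported orders: {_SUPPORTED_ORDERS}"
        )
    M.setflags(write=False)
    return M


def basis_matrix(order: int) -> np.ndarray:
    """Uniform B-spline basis-conversion matrix of size (order+1, order+1).

    A span evaluates as ``[1, t, ..., t^k] @ M @ p_local`` with local
    parameter t in [0, 1].  Rows satisfy the partition of unity: a constant
    control polygon evaluates to the constant.
    """
    return _basis_matrix_cached(int(order))


@dataclass
class BSplineSurface:
    """Uniform tensor-product B-spline surface.

    ``control_net`` has shape (nu, nv, 3).  If `closed_u`, the trailing
    `order_u` u-slices must duplicate the leading ones (periodic wrap).  If
    `pole_caps`, the first and last `order_v` v-slices must each collapse to
    a single repeated pole point.
    """

    control_net: np.ndarray
    order_u: int = 3
    order_v: int = 3
    closed_u: bool = False
    closed_v: bool = False
    pole_caps: bool = False
    fit_rms: float | None = None

    def __post_init__(self):
        net = np.asarray(self.control_net, dtype=float)
        if net.ndim != 3 or net.shape[2] != 3:
            raise ValueError("control_net must be (nu, nv, 3)")
        basis_matrix(self.order_u), basis_matrix(self.order_v)
        if net.shape[0] < self.order_u + 1 or net.shape[1] < self.order_v + 1:
            raise ValueError("control net too small for requested orders")
        if self.closed_u:
            k1 = self.order_u
            if not np.allclose(net[-k1:], net[:k1], atol=1e-9):
                raise ValueError("closed_u requires trailing order_u slices to wrap")
        if self.pole_caps:
            k2 = self.order_v
            for sl in (net[:, :k2], net[:, -k2:]):
                if not np.allclose(sl, sl[0, 0], atol=1e-9):
                    raise ValueError("pole_caps requires collapsed first/last control rows")
        self.control_net = net

    @property
    def n_spans_u(self) -> int:
        return self.control_net.shape[0] - self.order_u

    @property
    def n_spans_v(self) -> int:
        return self.control_net.shape[1] - self.order_v

    @property
    def knots_u(self) -> np.ndarray:
        """Uniform knot sequence (unclamped) in the u direction."""
        return np.arange(self.control_net.shape[0] + self.order_u + 1, dtype=float)

    @property
    def knots_v(self) -> np.ndarray:
        return np.arange(self.control_net.shape[1] + self.order_v + 1, dtype=float)

    @property
    def is_closed(self) -> bool:
        """True if the surface encloses a volume (all boundaries degenerate)."""
        u_ok = self.closed_u
        v_ok = self.closed_v or self.pole_caps
        return u_ok and v_ok

    def local_net(self, span_u: int, span_v: int) -> np.ndarray:
        if not (0 <= span_u < self.n_spans_u and 0 <= span_v < self.n_spans_v):
            raise IndexError(
                f"span ({span_u}, {span_v}) out of range "
                f"({self.n_spans_u} x {self.n_spans_v} spans)"
            )
        k1, k2 = self.order_u, self.order_v
        return self.control_net[span_u : span_u + k1 + 1, span_v : span_v + k2 + 1]

    def transformed(self, matrix: np.ndarray, offset: np.ndarray) -> "BSplineSurface":
        """Apply the affine map ``p -> matrix @ p + offset`` to the control net."""
        net = self.control_net @ np.asarray(matrix, dtype=float).T + np.asarray(offset, float)
        return BSplineSurface(net, self.order_u, self.order_v,
                              self.closed_u, self.closed_v, self.pole_caps)


@dataclass
class PolynomialPatch:
    """Monomial expansion of one span: ``S_c(t, w) = sum B_c[r, l] t^r w^l``."""

    coeffs: np.ndarray  # (k1+1, k2+1, 3); [r, l, c]
    patch_index: tuple[int, int]

    @property
    def coeffs_x(self) -> np.ndarray:
        return self.coeffs[:, :, 0]

    @property
    def coeffs_y(self) -> np.ndarray:
        return self.coeffs[:, :, 1]

    @property
    def coeffs_z(self) -> np.ndarray:
        return self.coeffs[:, :, 2]

    def evaluate(self, t, w) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        w = np.asarray(w, dtype=float)
        k1, k2, _ = self.coeffs.shape
        T = np.stack([t ** r for r in range(k1)], axis=-1)
        W = np.stack([w ** l for l in range(k2)], axis=-1)
        return np.einsum("...r,rlc,...l->...c", T, self.coeffs, W)


def evaluate_surface(surface: BSplineSurface, t: float, w: float,
                     span: tuple[int, int]) -> np.ndarray:
    """Evaluate one span at local parameters (t, w) in the unit square."""
    k1, k2 = surface.order_u, surface.order_v
    M1, M2 = basis_matrix(k1), basis_matrix(k2)
    V = surface.local_net(*span)
    T = np.power(float(t), np.arange(k1 + 1))
    W = np.power(float(w), np.arange(k2 + 1))
    wu = T @ M1  # (k1+1,) weights over local u control points
    wv = W @ M2
    return np.einsum("i,ijc,j->c", wu, V, wv)


def _span_local(x: float, n_spans: int) -> tuple[int, float]:
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError("global parameter must lie in [0, 1]")
    s = min(int(x * n_spans), n_spans - 1)
    return s, x * n_spans - s


def evaluate_global(surface: BSplineSurface, u, v) -> np.ndarray:
    """Evaluate at global parameters (u, v) in [0, 1]^2, vectorized.

    The parameter domain maps each span to an equal sub-interval; for a
    closed ``u`` direction, u = 0 and u = 1 coincide.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    u, v = np.broadcast_arrays(u, v)
    out = np.empty(u.shape + (3,))
    k1, k2 = surface.order_u, surface.order_v
    M1, M2 = basis_matrix(k1), basis_matrix(k2)
    Su, Sv = surface.n_spans_u, surface.n_spans_v
    su = np.minimum((u * Su).astype(int), Su - 1)
    sv = np.minimum((v * Sv).astype(int), Sv - 1)
    t = u * Su - su
    w = v * Sv - sv
    T = np.stack([t ** r for r in range(k1 + 1)], axis=-1) @ M1
    W = np.stack([w ** l for l in range(k2 + 1)], axis=-1) @ M2
    net = surface.control_net
    for idx in np.ndindex(u.shape):
        V = net[su[idx] : su[idx] + k1 + 1, sv[idx] : sv[idx] + k2 + 1]
        out[idx] = np.einsum("i,ijc,j->c", T[idx], V, W[idx])
    return out


def to_polynomial_patches(surface: BSplineSurface) -> list[PolynomialPatch]:
    """Monomial coefficient grids ``M_u V M_v^T`` for every nonempty span."""
    M1 = basis_matrix(surface.order_u)
    M2 = basis_matrix(surface.order_v)
    patches = []
    for i in range(surface.n_spans_u):
        for j in range(surface.n_spans_v):
            V = surface.local_net(i, j)  # (k1+1, k2+1, 3)
            B = np.einsum("ri,ijc,lj->rlc", M1, V, M2)
            patches.append(PolynomialPatch(coeffs=B, patch_index=(i, j)))
    return patches


def _basis_weights(x: np.ndarray, order: int, n_spans: int) -> tuple[np.ndarray, np.ndarray]:
    """Span indices and local basis weights for global parameters in [0, 1]."""
    M = basis_matrix(order)
    s = np.minimum((x * n_spans).astype(int), n_spans - 1)
    t = x * n_spans - s
    T = np.stack([t ** r for r in range(order + 1)], axis=-1)
    return s, T @ M  # weights over control indices s .. s+order


def fit_surface_to_landmark_grid(
    grid: LandmarkShape,
    order_u: int = 3,
    order_v: int = 3,
    closed_u: bool = True,
    pole_caps: bool = True,
    n_ctrl_u: int | None = None,
    n_ctrl_v: int | None = None,
) -> BSplineSurface:
    """Least-squares control net fitting a landmark grid.

    Landmarks are assigned uniform parameters (columns -> u, rows -> v); the
    control net minimizing the summed squared distance between the surface at
    those parameters and the landmarks is solved coordinate-wise by linear
    least squares.  `n_ctrl_u` is the number of distinct circumferential
    control columns; `n_ctrl_v` the total number of longitudinal control
    slices (including the `order_v` repeated pole slices at each end when
    `pole_caps`).  The achieved RMS residual is stored as ``fit_rms``.
    """
    if grid.grid_dims is None:
        raise ValueError("landmark shape must carry grid_dims")
    rows, cols = grid.grid_dims
    pts = grid.points.reshape(rows, cols, 3)
    k1, k2 = order_u, order_v

    if n_ctrl_u is None:
        n_ctrl_u = cols
    if n_ctrl_v is None:
        n_ctrl_v = (rows - 2 + 2 * k2) if pole_caps else rows

    if closed_u:
        nu_unique = n_ctrl_u
        nu = nu_unique + k1
        u_params = np.arange(cols) / cols
    else:
        nu_unique = n_ctrl_u
        nu = n_ctrl_u
        u_params = np.arange(cols) / (cols - 1)
    nv = n_ctrl_v
    if pole_caps:
        if nv < 2 * k2 + 1:
            raise ValueError("pole_caps needs at least 2*order_v + 1 control slices")
        v_params = (np.arange(rows) + 1.0) / (rows + 1.0)
        interior = nv - 2 * k2
        n_unknown_v = interior + 2  # interior slices + apex + base points
    else:
        v_params = np.arange(rows) / (rows - 1)
        interior = nv
        n_unknown_v = nv

    n_spans_u = nu - k1
    n_spans_v = nv - k2
    if n_spans_u < 1 or n_spans_v < 1:
        raise ValueError("control net too small for requested orders")

    n_unknowns = nu_unique * (interior if pole_caps else nv)
    if pole_caps:
        n_unknowns += 2
    n_eq = rows * cols
    if n_eq < n_unknowns:
        raise ValueError(
            f"underdetermined fit: {n_eq} landmarks for {n_unknowns} control "
            "unknowns; use fewer control points"
        )

    def unknown_index(cu: int, cv: int) -> int:
        """Map stored-net control indices to unknown column (or pole ids)."""
        cu = cu % nu_unique if closed_u else cu
        if pole_caps:
            if cv < k2:
                return nu_unique * interior  # apex
            if cv >= nv - k2:
                return nu_unique * interior + 1  # base
            return cu * interior + (cv - k2)
        return cu * nv + cv

    su, wu = _basis_weights(u_params, k1, n_spans_u)
    sv, wv = _basis_weights(v_params, k2, n_spans_v)

    A = np.zeros((n_eq, n_unknowns))
    row = 0
    for jr in range(rows):
        for ic in range(cols):
            for a in range(k1 + 1):
                cu = su[ic] + a
                for bb in range(k2 + 1):
                    cv = sv[jr] + bb
                    A[row, unknown_index(cu, cv)] += wu[ic, a] * wv[jr, bb]
            row += 1

    rhs = pts.reshape(-1, 3)
    sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < n_unknowns:
        raise ValueError(
            "rank-deficient fit; use fewer control points or more landmarks"
        )
    rms = float(np.sqrt(((A @ sol - rhs) ** 2).sum(axis=1).mean()))

    net = np.empty((nu, nv, 3))
    for cu in range(nu):
        for cv in range(nv):
            net[cu, cv] = sol[unknown_index(cu, cv)]

    return BSplineSurface(
        net, order_u=k1, order_v=k2, closed_u=closed_u,
        pole_caps=pole_caps, fit_rms=rms,
    )


def tessellate(surface: BSplineSurface, res_u: int = 32, res_v: int = 32) -> TriangleMesh:
    """Regular parameter-grid triangulation of the surface.

    Sampling is span-aligned so knot lines (where low-order surfaces are only
    C0) are always hit exactly: the requested resolution is rounded up to a
    multiple of the span count.  The actual sample counts are
    ``nu = Su * ceil(res_u / Su)`` in a closed ``u`` direction (periodic, no
    duplicated seam), ``Su * ceil((res_u - 1) / Su) + 1`` in an open one, and
    analogously ``nv`` in v.  With pole caps the degenerate first/last sample
    rings collapse to single pole vertices (triangle fans), so the watertight
    sphere-topology mesh has ``nu * (nv - 2) + 2`` vertices.
    """
    if res_u < 2 or res_v < 2:
        raise ValueError("resolution must be >= 2 per direction")
    Su, Sv = surface.n_spans_u, surface.n_spans_v
    if surface.closed_u:
        n_u = Su * int(np.ceil(res_u / Su))
        us = np.arange(n_u) / n_u
    else:
        n_u = Su * int(np.ceil((res_u - 1) / Su)) + 1
        us = np.arange(n_u) / (n_u - 1)
    n_v = Sv * int(np.ceil((res_v - 1) / Sv)) + 1
    vs = np.arange(n_v) / (n_v - 1)
    res_v = n_v

    if surface.pole_caps:
        inner_vs = vs[1:-1] if res_v > 2 else vs
        rings = np.stack([evaluate_global(surface, us, np.full_like(us, v))
                          for v in inner_vs])
        apex = evaluate_global(surface, np.array([0.0]), np.array([0.0]))[0]
        base = evaluate_global(surface, np.array([0.0]), np.array([1.0]))[0]
        return build_ring_mesh(rings, closed_u=surface.closed_u,
                               apex_point=apex, base_point=base)
    rings = np.stack([evaluate_global(surface, us, np.full_like(us, v)) for v in vs])
    return build_ring_mesh(rings, closed_u=surface.closed_u)
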