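"""Forward transport problem: upwind-DG radiance solves and boundary readings.

The monochromatic radiance u(x, omega) obeys the stationary transport
(radiative transfer) equation

    omega . grad u + (mua + mus) u = mus * Integral k(omega . omega') u domega'

on the disk, with prescribed inflow on the boundary.  Space is discretized by
discontinuous Galerkin elements with a per-triangle linear basis and upwind
numerical fluxes; angle by the equispaced grid of :mod:`rtetomo.angular`.

The coupled system is solved by source iteration — exact per-direction upwind
sweeps with the scattering source lagged one iteration, i.e. a block
Gauss-Seidel in the direction blocks — optionally (and by default) wrapped in
LGMRES acceleration of the same fixed-point map, which matters in the
diffusive regime where the single-scattering albedo approaches one.

A detector reading is the edge-averaged outgoing flux density of the exitance
integrand (omega . nu) u over the detector's boundary edge; edge averaging
makes readings insensitive to the boundary-edge length and hence to mesh
resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._kernels import DEG_TOL, sweep_all
from .angular import AngularGrid
from .mesh import DetectorSpec, SourceSpec, TriMesh, upwind_order
from .phantom import OpticalCoefficients

logger = logging.getLogger(__name__)

__all__ = ["RadianceField", "MeasurementSet", "TransportSolver",
           "ConvergenceError", "incident_profile", "solve_rte",
           "boundary_exitance", "forward_map", "add_noise",
           "assemble_global_system"]


class ConvergenceError(RuntimeError):
    """Transport solve failed to reach the requested residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3e})")
        self.residual = residual


@dataclass
class RadianceField:
    """DG radiance: values[p, k, i] = nodal coefficient of direction p,
    element k, local node i.

    Values are finite and nonnegative up to the upwind-DG undershoot near
    collimated source peaks (a few percent of the peak value at practical
    resolutions).
    """

    values: np.ndarray  # (n_dir, n_elements, 3)
    mesh: TriMesh
    grid: AngularGrid


@dataclass
class MeasurementSet:
    """Detector x source matrix of boundary readings plus noise metadata."""

    M: np.ndarray  # (n_det, n_src)
    sources: list[SourceSpec]
    detectors: list[DetectorSpec]
    delta: float = 0.0
    seed: int | None = None


def _local_mass(areas: np.ndarray) -> np.ndarray:
    base = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    return areas[:, None, None] * base


class TransportSolver:
    """Reusable transport solve context for one (mesh, grid) pair.

    Precomputes direction-dependent geometry (edge fluxes, upwind element
    orders) once; :meth:`set_coefficients` re-assembles only the 3x3 local
    matrices, so the same solver serves every source, every adjoint solve, and
    every outer reconstruction iterate.
    """

    def __init__(self, mesh: TriMesh, grid: AngularGrid,
                 coeffs: OpticalCoefficients | None = None, tol: float = 1e-8,
                 max_iter: int = 2000, method: str = "gmres"):
        if grid.scatter_matrix is None:
            raise ValueError("angular grid has no scatter matrix; call "
                             "build_scatter_matrix first")
        if tol <= 0:
            raise ValueError("tol must be positive")
        if method not in ("gmres", "source"):
            raise ValueError(f"unknown method {method!r}")
        self.mesh = mesh
        self.grid = grid
        self.tol = tol
        self.max_iter = max_iter
        self.method = method
        T = mesh.n_elements
        self.an = np.einsum("pd,tld->ptl", grid.directions, mesh.normals)
        self.orders = np.empty((grid.n_dir, T), dtype=np.int64)
        for p in range(grid.n_dir):
            self.orders[p] = upwind_order(mesh, grid.directions[p])
        l_idx = np.arange(3)
        self.nb_a = np.where(mesh.neighbor >= 0, (mesh.neighbor_edge + 1) % 3, 0)
        self.nb_b = np.where(mesh.neighbor >= 0, mesh.neighbor_edge, 0)
        del l_idx
        self.mass = _local_mass(mesh.areas)
        self.n_bedges = len(mesh.boundary_edges)
        self.coeffs: OpticalCoefficients | None = None
        self._ainv = None
        if coeffs is not None:
            self.set_coefficients(coeffs)

    def set_coefficients(self, coeffs: OpticalCoefficients) -> None:
        """(Re)assemble the per-direction 3x3 element matrices for given
        optical coefficients."""
        if coeffs.mesh is not self.mesh:
            raise ValueError("coefficients were rasterized on a different mesh")
        mesh, grid = self.mesh, self.grid
        sigma_t = coeffs.mua + coeffs.mus
        # convection: row i constant, -(omega . grad phi_i) * area / 3
        wg = np.einsum("pd,tid->pti", grid.directions, mesh.grads)
        A = np.repeat((-wg * (mesh.areas[None, :, None] / 3.0))[..., None], 3,
                      axis=3)
        # outflow edge fluxes (own-element, symmetric edge mass)
        s_out = np.maximum(self.an, 0.0)
        for l in range(3):
            a, b = l, (l + 1) % 3
            c = s_out[:, :, l] * mesh.edge_len[None, :, l] / 6.0
            A[:, :, a, a] += 2.0 * c
            A[:, :, a, b] += c
            A[:, :, b, a] += c
            A[:, :, b, b] += 2.0 * c
        A += sigma_t[None, :, None, None] * self.mass[None]
        self._ainv = np.ascontiguousarray(np.linalg.inv(A))
        self.coeffs = coeffs

    # -- building blocks ---------------------------------------------------
    def zero_inflow(self) -> np.ndarray:
        return np.zeros((self.grid.n_dir, self.n_bedges, 2))

    def sweep(self, f: np.ndarray, bmom: np.ndarray) -> np.ndarray:
        """Exact per-direction transport solve with frozen source f and
        boundary inflow moments bmom."""
        if self._ainv is None:
            raise RuntimeError("call set_coefficients before solving")
        mesh = self.mesh
        return sweep_all(self.orders, self._ainv, self.an, mesh.edge_len,
                         mesh.neighbor, self.nb_a, self.nb_b, mesh.bedge_id,
                         bmom, f, mesh.areas)

    def scatter_source(self, u: np.ndarray) -> np.ndarray:
        """Nodal scattering source mus * (scatter_matrix applied over directions)."""
        f = np.einsum("pq,qti->pti", self.grid.scatter_matrix, u)
        f *= self.coeffs.mus[None, :, None]
        return f

    # -- solves ------------------------------------------------------------
    def solve(self, bmom: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
        shape = (self.grid.n_dir, self.mesh.n_elements, 3)
        b = self.sweep(np.zeros(shape), bmom)
        if not np.any(b):
            return np.zeros(shape)
        if self.method == "source":
            return self._solve_source_iteration(b, bmom)
        return self._solve_gmres(b, x0)

    def _solve_source_iteration(self, b, bmom):
        u = b.copy()
        f_old = self.scatter_source(u)
        res = np.inf
        for it in range(self.max_iter):
            u = self.sweep(f_old, bmom)
            f_new = self.scatter_source(u)
            scale = np.abs(f_new).max()
            res = np.abs(f_new - f_old).max() / scale if scale > 0 else 0.0
            f_old = f_new
            if res <= self.tol:
                logger.debug("source iteration converged in %d iterations", it + 1)
                return u
        raise ConvergenceError(
            f"source iteration did not converge in {self.max_iter} iterations", res)

    def _solve_gmres(self, b, x0):
        shape = b.shape
        n = b.size
        zero_b = np.zeros((self.grid.n_dir, self.n_bedges, 2))

        def matvec(x):
            u = x.reshape(shape)
            ku = self.sweep(self.scatter_source(u), zero_b)
            return (u - ku).ravel()

        A = spla.LinearOperator((n, n), matvec=matvec)
        x0v = None if x0 is None else x0.ravel()
        x, info = spla.lgmres(A, b.ravel(), x0=x0v, rtol=self.tol, atol=0.0,
                              maxiter=self.max_iter, inner_m=30)
        if info != 0:
            res = np.linalg.norm(matvec(x) - b.ravel()) / np.linalg.norm(b)
            raise ConvergenceError("Krylov-accelerated source iteration did "
                                   f"not converge (info={info})", res)
        return x.reshape(shape)


def _hat_edge_moments(mesh: TriMesh, edges):
    """Moments m_i = integral_e (hat) phi_i ds of a boundary hat profile,
    per edge of a boundary unit: (edge_id, m_start, m_end) records."""
    out = []
    for eid, t, l, h_s, h_e in edges:
        le = mesh.edge_len[t, l]
        out.append((eid, le / 6.0 * (2.0 * h_s + h_e), le / 6.0 * (h_s + 2.0 * h_e)))
    return out


def incident_profile(src: SourceSpec, mesh: TriMesh, grid: AngularGrid) -> np.ndarray:
    """Boundary inflow moments for a collimated hat source.

    The incident impulse is the piecewise-linear hat peaked at the source's
    boundary node (amplitude ``src.amplitude``: 2/support for unit injected
    power, 1 for unit peak), vanishing at the neighboring boundary nodes, and
    collimated in the one grid direction nearest to the inward radial
    direction.  Returned as moments m_i = integral_e g(x) phi_i(x) ds per
    boundary edge, the form consumed by the DG boundary flux term.
    """
    if src.direction_index is None:
        raise ValueError("source has no incident direction; place boundary "
                         "units with an angular grid")
    bmom = np.zeros((grid.n_dir, len(mesh.boundary_edges), 2))
    di = src.direction_index
    w = grid.directions[di]
    for eid, m_s, m_e in _hat_edge_moments(mesh, src.edges):
        t, l = map(int, mesh.boundary_edges[eid])
        if w @ mesh.normals[t, l] >= -DEG_TOL:
            raise ValueError(f"source {src.index}: incident direction is not "
                             "inflow on its boundary edge")
        bmom[di, eid, 0] = src.amplitude * m_s
        bmom[di, eid, 1] = src.amplitude * m_e
    return bmom


def solve_rte(mesh: TriMesh, grid: AngularGrid, coeffs: OpticalCoefficients,
              inflow: np.ndarray, tol: float = 1e-8, max_iter: int = 2000,
              method: str = "gmres") -> RadianceField:
    """One-shot transport solve; see :class:`TransportSolver` for reuse."""
    solver = TransportSolver(mesh, grid, coeffs, tol=tol, max_iter=max_iter,
                             method=method)
    return RadianceField(solver.solve(inflow), mesh, grid)


def boundary_exitance(field: RadianceField, det: DetectorSpec,
                      grid: AngularGrid) -> float:
    """Hat-weighted outgoing flux density around the detector node:

        (1/W) * integral_supp hat(x) sum_{omega . nu > 0} (omega . nu)
                u(x, omega) w_omega ds,    W = integral hat = support / 2.

    The hat weighting centers the reading exactly at the detector's boundary
    node and makes it insensitive to the local boundary-edge length, so
    readings are comparable across meshes of different resolution.
    """
    mesh = field.mesh
    total = 0.0
    for eid, t, l, h_s, h_e in det.edges:
        if mesh.neighbor[t, l] >= 0:
            raise ValueError("detector edge is not on the boundary")
        a, b = l, (l + 1) % 3
        an = grid.directions @ mesh.normals[t, l]
        out = an > 0
        le = mesh.edge_len[t, l]
        m_a = le / 6.0 * (2.0 * h_s + h_e)
        m_b = le / 6.0 * (h_s + 2.0 * h_e)
        total += float(np.sum(grid.weights[out] * an[out] *
                              (m_a * field.values[out, t, a]
                               + m_b * field.values[out, t, b])))
    return total / (det.support / 2.0)


def forward_map(coeffs: OpticalCoefficients, sources: list[SourceSpec],
                detectors: list[DetectorSpec], mesh: TriMesh, grid: AngularGrid,
                tol: float = 1e-8, max_iter: int = 2000, method: str = "gmres",
                solver: TransportSolver | None = None,
                warm_start: list[np.ndarray] | None = None,
                return_fields: bool = False):
    """Measurements for all source-detector pairs: column i of M holds the
    readings at every detector for source i (one transport solve per source)."""
    if solver is None:
        solver = TransportSolver(mesh, grid, coeffs, tol=tol, max_iter=max_iter,
                                 method=method)
    elif solver.coeffs is not coeffs:
        solver.set_coefficients(coeffs)
    M = np.empty((len(detectors), len(sources)))
    fields = []
    for i, src in enumerate(sources):
        x0 = warm_start[i] if warm_start is not None else None
        u = solver.solve(incident_profile(src, mesh, grid), x0=x0)
        fld = RadianceField(u, mesh, grid)
        for j, det in enumerate(detectors):
            M[j, i] = boundary_exitance(fld, det, grid)
        if return_fields or warm_start is not None:
            fields.append(u)
    if warm_start is not None:
        warm_start[:] = fields
    ms = MeasurementSet(M, sources, detectors)
    return (ms, fields) if return_fields else ms


def add_noise(ms: MeasurementSet, delta: float, seed: int) -> MeasurementSet:
    """Multiplicative Gaussian noise M -> M * (1 + delta * z), z ~ N(0, 1) iid."""
    if delta < 0:
        raise ValueError("noise level delta must be >= 0")
    rng = np.random.default_rng(seed)
    noisy = ms.M * (1.0 + delta * rng.standard_normal(ms.M.shape))
    return MeasurementSet(noisy, ms.sources, ms.detectors, delta=delta, seed=seed)


def assemble_global_system(solver: TransportSolver, bmom: np.ndarray):
    """Directly assemble the full coupled sparse system (all directions,
    elements and nodes, scattering included) and its right-hand side.

    Independent oracle for the iterative path; intended for small problems
    (the matrix is (n_dir * n_elements * 3) square).  Unknown ordering matches
    the field layout: index = (p * T + k) * 3 + i.
    """
    mesh, grid = solver.mesh, solver.grid
    coeffs = solver.coeffs
    T, P = mesh.n_elements, grid.n_dir
    n = P * T * 3
    mass = solver.mass
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)

    def ix(p, k, i):
        return (p * T + k) * 3 + i

    sigma_t = coeffs.mua + coeffs.mus
    for p in range(P):
        w = grid.directions[p]
        for k in range(T):
            wg = mesh.grads[k] @ w
            for i in range(3):
                for j in range(3):
                    rows.append(ix(p, k, i))
                    cols.append(ix(p, k, j))
                    vals.append(-wg[i] * mesh.areas[k] / 3.0
                                + sigma_t[k] * mass[k, i, j])
            for l in range(3):
                s = solver.an[p, k, l]
                a, b = l, (l + 1) % 3
                le = mesh.edge_len[k, l]
                if s > 0:
                    for (r, c, m) in ((a, a, 2), (a, b, 1), (b, a, 1), (b, b, 2)):
                        rows.append(ix(p, k, r))
                        cols.append(ix(p, k, c))
                        vals.append(s * le / 6.0 * m)
                elif s < -DEG_TOL:
                    t2 = mesh.neighbor[k, l]
                    if t2 >= 0:
                        na, nb_ = solver.nb_a[k, l], solver.nb_b[k, l]
                        for (r, c, m) in ((a, na, 2), (a, nb_, 1),
                                          (b, na, 1), (b, nb_, 2)):
                            rows.append(ix(p, k, r))
                            cols.append(ix(p, t2, c))
                            vals.append(s * le / 6.0 * m)
                    else:
                        be = mesh.bedge_id[k, l]
                        rhs[ix(p, k, a)] -= s * bmom[p, be, 0]
                        rhs[ix(p, k, b)] -= s * bmom[p, be, 1]
            # scattering coupling within the element, across directions
            for q in range(P):
                c_s = coeffs.mus[k] * grid.scatter_matrix[p, q]
                if c_s == 0.0:
                    continue
                for i in range(3):
                    for j in range(3):
                        rows.append(ix(p, k, i))
                        cols.append(ix(q, k, j))
                        vals.append(-c_s * mass[k, i, j])
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return A, rhs


def solve_direct(solver: TransportSolver, bmom: np.ndarray) -> np.ndarray:
    """Solve the fully assembled coupled system with a sparse direct solver."""
    A, rhs = assemble_global_system(solver, bmom)
    u = spla.spsolve(A.tocsc(), rhs)
    return u.reshape(solver.grid.n_dir, solver.mesh.n_elements, 3)
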