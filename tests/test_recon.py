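"""Reconstruction primitives: TV forms, shrinkage, LM step, Bregman updates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtetomo.angular import build_angular_grid
from rtetomo.forward import forward_map
from rtetomo.mesh import mesh_disk, place_boundary_units
from rtetomo.phantom import Inclusion, Phantom, rasterize
from rtetomo.recon import (JacobianBlock, RegParams, ReconState, error_metrics,
                           lm_step, reconstruct, shrink, tv_operator,
                           tv_smoothed)
from tests.conftest import two_triangle_mesh


# ---------------------------------------------------------------- shrinkage
def test_shrink_branch_table():
    assert shrink(0.5, 0.2) == pytest.approx(0.3)
    assert shrink(0.1, 0.2) == 0.0
    assert shrink(-0.5, 0.2) == pytest.approx(-0.3)
    assert shrink(0.2, 0.2) == 0.0
    with pytest.raises(ValueError):
        shrink(1.0, -0.1)


@settings(deadline=None, max_examples=200)
@given(st.floats(-100, 100), st.floats(0, 50))
def test_shrink_properties(x, t):
    y = shrink(x, t)
    assert abs(y) <= abs(x) + 1e-12
    assert shrink(-x, t) == pytest.approx(-y, abs=1e-12)  # odd in x
    assert shrink(y, 0.0) == y  # idempotent at zero threshold


# ---------------------------------------------------------------- TV forms
def test_tv_smoothed_constant_field():
    m = mesh_disk(10.0, 300, seed=1)
    total_len = float(m.edge_len[m.interior_edges[:, 0],
                                 m.interior_edges[:, 1]].sum())
    eps = 1e-3
    assert tv_smoothed(np.full(m.n_elements, 0.7), m, eps) == \
        pytest.approx(eps * total_len, rel=1e-12)


def test_tv_smoothed_single_jump():
    m = two_triangle_mesh(shared_len=1.0)
    vals = np.array([0.0, 1.0])
    assert tv_smoothed(vals, m, 1e-12) == pytest.approx(1.0, abs=1e-6)
    # eps bound: difference from the sharp value is at most eps * total length
    eps = 1e-6
    assert abs(tv_smoothed(vals, m, eps) - 1.0) <= eps * 1.0 + 1e-12


def test_tv_operator_structure():
    m = mesh_disk(10.0, 300, seed=2)
    mu = np.random.default_rng(0).uniform(0.01, 0.02, m.n_elements)
    op = tv_operator(mu, m, 1e-6)
    L = op.L.toarray()
    assert np.allclose(L, L.T)
    assert np.allclose(L @ np.ones(m.n_elements), 0.0, atol=1e-9)
    w = np.linalg.eigvalsh(L)
    assert w.min() > -1e-8 * w.max()  # positive semidefinite
    # constant state: L = (1/eps) x edge-length weighted Laplacian
    eps = 1e-3
    Lc = tv_operator(np.full(m.n_elements, 0.5), m, eps).L.toarray()
    t1, _, t2, _ = m.interior_edges[0]
    le = m.edge_len[m.interior_edges[0, 0], m.interior_edges[0, 1]]
    assert Lc[t1, t2] == pytest.approx(-le / eps, rel=1e-12)


def test_tv_operator_is_gradient_of_smoothed_tv():
    m = mesh_disk(10.0, 60, seed=3)
    rng = np.random.default_rng(1)
    mu = rng.uniform(0.0, 1.0, m.n_elements)
    v = rng.normal(size=m.n_elements)
    eps = 1e-2
    L = tv_operator(mu, m, eps).L
    analytic = float((L @ mu) @ v)
    h = 1e-7
    fd = (tv_smoothed(mu + h * v, m, eps) - tv_smoothed(mu - h * v, m, eps)) / (2 * h)
    assert analytic == pytest.approx(fd, rel=1e-6)


# ---------------------------------------------------------------- LM step
def _toy_state(n, mua=None):
    mua = np.full(n, 0.01) if mua is None else mua
    return ReconState(mua=mua.copy(), D=mua.copy(), b=np.zeros(n))


def test_lm_step_stationary_at_zero_residual():
    m = two_triangle_mesh()
    state = _toy_state(2)
    jac = [JacobianBlock(J=np.array([[1.0, 0.2], [0.1, 0.9]]), source_index=0)]
    res = [np.zeros(2)]
    params = RegParams(alpha=0.0, beta=0.0, eta=1e-3)
    tvop = tv_operator(state.mua, m, params.eps)
    out = lm_step(state, jac, res, tvop, params)
    assert np.allclose(out, state.mua, atol=1e-14)


def test_lm_step_exact_newton_on_identity_jacobian():
    m = two_triangle_mesh()
    target = np.array([0.3, 0.7])
    state = _toy_state(2, mua=np.array([0.5, 0.5]))
    jac = [JacobianBlock(J=np.eye(2), source_index=0)]
    res = [state.mua - target]
    params = RegParams(alpha=0.0, beta=0.0, eta=0.0)
    tvop = tv_operator(state.mua, m, params.eps)
    out = lm_step(state, jac, res, tvop, params)
    assert np.allclose(out, target, atol=1e-12)


def test_lm_step_matches_quadratic_oracle():
    """The step must minimize the Step-1* quadratic model; oracle: solve the
    model assembled independently by finite differences of the objective."""
    rng = np.random.default_rng(7)
    m = mesh_disk(10.0, 30, seed=4)
    n = m.n_elements
    state = ReconState(mua=rng.uniform(0.005, 0.02, n),
                       D=rng.uniform(0.0, 0.02, n), b=rng.normal(0, 0.01, n))
    jac = [JacobianBlock(J=rng.normal(size=(4, n)), source_index=i)
           for i in range(2)]
    res = [rng.normal(size=4) for _ in range(2)]
    params = RegParams(alpha=3e-3, beta=1e-3, eta=0.5)
    tvop = tv_operator(state.mua, m, params.eps)

    def objective(mu):
        val = 0.0
        for blk, r in zip(jac, res):
            q = blk.J @ (mu - state.mua) + r
            val += 0.5 * q @ q
        val += 0.5 * params.alpha * mu @ (tvop.L @ mu)
        val += 0.5 * params.eta * np.sum((state.D - mu - state.b) ** 2)
        return val

    h = 1e-2  # the objective is exactly quadratic: no truncation error
    grad = np.empty(n)
    hess = np.empty((n, n))
    e = np.eye(n)
    for i in range(n):
        grad[i] = (objective(state.mua + h * e[i])
                   - objective(state.mua - h * e[i])) / (2 * h)
    for i in range(n):
        for j in range(i, n):
            hess[i, j] = hess[j, i] = (
                objective(state.mua + h * (e[i] + e[j]))
                - objective(state.mua + h * (e[i] - e[j]))
                - objective(state.mua + h * (e[j] - e[i]))
                + objective(state.mua - h * (e[i] + e[j]))) / (4 * h * h)
    oracle = state.mua + np.linalg.solve(hess, -grad)
    out = lm_step(state, jac, res, tvop, params)
    assert np.abs(out - oracle).max() < 1e-6 * np.abs(oracle).max()


def test_lm_step_requires_some_regularization():
    m = two_triangle_mesh()
    state = _toy_state(2)
    jac = [JacobianBlock(J=np.array([[1.0, 1.0]]), source_index=0)]  # rank 1
    res = [np.array([0.5])]
    params = RegParams(alpha=0.0, beta=0.0, eta=0.0)
    tvop = tv_operator(state.mua, m, params.eps)
    with pytest.raises(np.linalg.LinAlgError):
        lm_step(state, jac, res, tvop, params)


# ---------------------------------------------------------------- metrics
def test_error_metrics_identities():
    truth = np.array([1.0, 2.0, 3.0])
    f_true = np.array([0.5, 0.25])
    assert error_metrics(truth, truth, f_true, f_true) == (0.0, 0.0)
    _, e = error_metrics(1.1 * truth, truth, f_true, f_true)
    assert e == pytest.approx(0.1, rel=1e-12)
    rng = np.random.default_rng(2)
    a, b = rng.normal(size=5), rng.normal(size=5)
    fa, fb = rng.normal(size=4), rng.normal(size=4)
    e_r, e_m = error_metrics(a, b, fa, fb)
    assert e_r == pytest.approx(np.sqrt(((fa - fb) ** 2).sum())
                                / np.sqrt((fb ** 2).sum()))
    assert e_m == pytest.approx(np.sqrt(((a - b) ** 2).sum())
                                / np.sqrt((b ** 2).sum()))
    with pytest.raises(ValueError):
        error_metrics(a, np.zeros(5), fa, fb)


def test_bregman_variable_update_arithmetic():
    # b^{n+1} = b^n + mua^{n+1} - D^{n+1}
    assert 0.1 + 0.5 - 0.3 == pytest.approx(0.3)
    # shrinkage step consistency: D = shrink(mua + b, beta/eta)
    assert shrink(0.5 + 0.1, 0.2) == pytest.approx(0.4)


# ------------------------------------------------------- small end-to-end
def test_zero_contrast_reconstruction_stays_at_background():
    """Data synthesized from the background itself: the background start is
    already the optimum, so the iteration stops immediately and returns it."""
    m = mesh_disk(10.0, 150, seed=2, boundary_multiple=8)
    g = build_angular_grid(8, 0.9)
    co = rasterize(Phantom(0.01, 5.0), m)
    src, det = place_boundary_units(m, 4, 4, g)
    data = forward_map(co, src, det, m, g, tol=1e-10)
    params = RegParams(alpha=1e-4, beta=1e-3, eta=1e-5, max_outer=10,
                       stop_tol=1e-4)
    mua, state = reconstruct(data, m, g, co.mus, co.mua.copy(), params,
                             truth_mua=co.mua, tol=1e-10)
    assert state.iter <= 2
    assert np.abs(mua - 0.01).max() < 1e-3 * 0.01


def test_recovery_error_decreases_on_selfconsistent_toy():
    """Same-mesh, noise-free single-inclusion problem: the solution error
    must decrease over the first iterations."""
    m = mesh_disk(10.0, 300, seed=2, boundary_multiple=8)
    g = build_angular_grid(16, 0.9)
    ph = Phantom(0.01, 2.0, [Inclusion((5.0, 0.0), 2.0, 0.02, 2.0)])
    co = rasterize(ph, m)
    src, det = place_boundary_units(m, 4, 4, g)
    data = forward_map(co, src, det, m, g, tol=1e-8)
    params = RegParams(alpha=1e-6, beta=1e-5, eta=1e-6, max_outer=5,
                       stop_tol=1e-6)
    init = np.full(m.n_elements, 0.01)
    mua, state = reconstruct(data, m, g, co.mus, init, params,
                             truth_mua=co.mua, tol=1e-8)
    E = [h["E_mua"] for h in state.history]
    E.append(float(np.linalg.norm(mua - co.mua) / np.linalg.norm(co.mua)))
    assert E[-1] < E[0]
    assert E[1] <= E[0] + 1e-12
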