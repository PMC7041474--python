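"""Independent oracles for the test suite.

Everything here is deliberately implemented on a different code path from the
package: dense matrices assembled with Kronecker products, ADMM (not
primal-dual) for the nonsmooth convex programs, explicit finite-difference
time stepping for the wave equation, and direct summation for metrics.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

SQRT2 = np.sqrt(2.0)


# -- dense difference operators (Kronecker assembly) ------------------------

def _d1(n: int) -> np.ndarray:
    """Forward difference with zero last row, as a dense n x n matrix."""
    m = np.zeros((n, n))
    for i in range(n - 1):
        m[i, i] = -1.0
        m[i, i + 1] = 1.0
    return m


def dense_diff_matrices(shape):
    """(Dx, Dy, Dz) acting on flattened (C-order) volumes of ``shape``."""
    nx, ny, nz = shape
    ix, iy, iz = np.eye(nx), np.eye(ny), np.eye(nz)
    dx = np.kron(np.kron(_d1(nx), iy), iz)
    dy = np.kron(np.kron(ix, _d1(ny)), iz)
    dz = np.kron(np.kron(ix, iy), _d1(nz))
    return dx, dy, dz


def dense_grad(shape) -> np.ndarray:
    """(3n, n) gradient: rows grouped per component (x, y, z)."""
    return np.vstack(dense_diff_matrices(shape))


def dense_symgrad(shape) -> np.ndarray:
    """(6n, 3n) symmetrized derivative in the sqrt(2)-scaled off-diagonal
    basis, so that plain Euclidean row-group norms equal Frobenius norms.

    Input ordering: stacked components (qx, qy, qz); output row groups
    (xx, yy, zz, sqrt2*xy, sqrt2*xz, sqrt2*yz).
    """
    dx, dy, dz = dense_diff_matrices(shape)
    n = dx.shape[0]
    zero = np.zeros((n, n))
    r = 1.0 / SQRT2  # sqrt(2) * (1/2) = 1/sqrt(2)
    rows = [
        [dx, zero, zero],
        [zero, dy, zero],
        [zero, zero, dz],
        [r * dy, r * dx, zero],
        [r * dz, zero, r * dx],
        [zero, r * dz, r * dy],
    ]
    return np.block(rows)


def dense_radon(radon) -> np.ndarray:
    """Dense matrix of a single-slice projector by probing with unit volumes."""
    geo = radon.geo
    assert geo.nz == 1
    n = geo.nx * geo.nx
    cols = []
    for j in range(n):
        p = np.zeros(n)
        p[j] = 1.0
        cols.append(radon.apply(p.reshape(geo.nx, geo.nx, 1)).ravel())
    return np.array(cols).T


# -- group shrinkage --------------------------------------------------------

def _group_shrink(y: np.ndarray, n_groups: int, thresh: float) -> np.ndarray:
    """Block soft-thresholding; ``y`` is stacked per component, groups are
    formed across components (component-major layout of dense_grad)."""
    comp = y.reshape(-1, n_groups)  # rows: components, cols: voxels
    mag = np.linalg.norm(comp, axis=0)
    factor = np.maximum(0.0, 1.0 - thresh / np.maximum(mag, 1e-300))
    return (comp * factor).ravel()


def _group_norm_sum(y: np.ndarray, n_groups: int) -> float:
    return float(np.sum(np.linalg.norm(y.reshape(-1, n_groups), axis=0)))


# -- ADMM solvers -----------------------------------------------------------

def _admm(a_blocks, proxes, n: int, n_iter: int, rho: float = 1.0):
    """Generic ADMM for  min sum_i g_i(A_i u)  via splitting z_i = A_i u.

    ``a_blocks``: list of dense matrices; ``proxes``: list of callables
    ``prox_i(y, rho)`` evaluating ``argmin g_i(z) + rho/2 ||z - y||^2``.
    Returns the primal iterate u.
    """
    a_mat = np.vstack(a_blocks)
    gram = a_mat.T @ a_mat + 1e-10 * np.eye(n)
    cho = scipy.linalg.cho_factor(gram)
    sizes = [blk.shape[0] for blk in a_blocks]
    splits = np.cumsum(sizes)[:-1]
    z = np.zeros(a_mat.shape[0])
    lam = np.zeros_like(z)
    u = np.zeros(n)
    for _ in range(n_iter):
        u = scipy.linalg.cho_solve(cho, a_mat.T @ (z - lam))
        au = a_mat @ u
        y = au + lam
        z = np.concatenate(
            [prox(part, rho) for prox, part in zip(proxes, np.split(y, splits))]
        )
        lam = lam + au - z
    return u


def tgv_reconstruct_oracle(radon, f: np.ndarray, mu: float, alpha0: float,
                           alpha1: float, n_iter: int = 20000, rho: float = 1.0):
    """Solve  min_{p,q} mu/2 ||Rp - f||^2 + a1 ||grad p - q||_1 + a0 ||Eq||_1
    on a single-slice grid by dense ADMM.  Returns (p, q, objective)."""
    geo = radon.geo
    shape = geo.volume_shape
    n = int(np.prod(shape))
    r_mat = dense_radon(radon)
    g_mat = dense_grad(shape)
    e_mat = dense_symgrad(shape)
    f_vec = f.ravel()

    a1_blk = r_mat @ np.hstack([np.eye(n), np.zeros((n, 3 * n))])
    a2_blk = np.hstack([g_mat, -np.eye(3 * n)])
    a3_blk = np.hstack([np.zeros((6 * n, n)), e_mat])
    proxes = [
        lambda y, r: (mu * f_vec + r * y) / (mu + r),
        lambda y, r: _group_shrink(y, n, alpha1 / r),
        lambda y, r: _group_shrink(y, n, alpha0 / r),
    ]
    u = _admm([a1_blk, a2_blk, a3_blk], proxes, 4 * n, n_iter, rho)
    p, q = u[:n], u[n:]
    obj = (0.5 * mu * np.sum((r_mat @ p - f_vec) ** 2)
           + alpha1 * _group_norm_sum(g_mat @ p - q, n)
           + alpha0 * _group_norm_sum(e_mat @ q, n))
    return p.reshape(shape), q, float(obj)


def tv_reconstruct_oracle(radon, f: np.ndarray, mu: float, alpha1: float,
                          n_iter: int = 20000, rho: float = 1.0):
    """Solve  min_p mu/2 ||Rp - f||^2 + a1 ||grad p||_1  by dense ADMM."""
    geo = radon.geo
    shape = geo.volume_shape
    n = int(np.prod(shape))
    r_mat = dense_radon(radon)
    g_mat = dense_grad(shape)
    f_vec = f.ravel()
    proxes = [
        lambda y, r: (mu * f_vec + r * y) / (mu + r),
        lambda y, r: _group_shrink(y, n, alpha1 / r),
    ]
    p = _admm([r_mat, g_mat], proxes, n, n_iter, rho)
    obj = (0.5 * mu * np.sum((r_mat @ p - f_vec) ** 2)
           + alpha1 * _group_norm_sum(g_mat @ p, n))
    return p.reshape(shape), float(obj)


def tgv_value_oracle(p: np.ndarray, alpha0: float, alpha1: float,
                     n_iter: int = 20000, rho: float = 1.0) -> float:
    """min_q a1 ||grad p - q||_1 + a0 ||Eq||_1 by dense ADMM over q."""
    shape = p.shape
    n = int(np.prod(shape))
    g_mat = dense_grad(shape)
    e_mat = dense_symgrad(shape)
    gp = g_mat @ p.ravel()

    def prox_shifted(y, r):
        # argmin a1 ||gp - z||_groups + r/2 ||z - y||^2
        return gp - _group_shrink(gp - y, n, alpha1 / r)

    proxes = [prox_shifted, lambda y, r: _group_shrink(y, n, alpha0 / r)]
    q = _admm([np.eye(3 * n), e_mat], proxes, 3 * n, n_iter, rho)
    return float(alpha1 * _group_norm_sum(gp - q, n)
                 + alpha0 * _group_norm_sum(e_mat @ q, n))


# -- finite-difference wave oracle ------------------------------------------

def fdtd_propagate(field0: np.ndarray, cs: float, t_end: float, d_s: float,
                   d_z: float, n_steps: int) -> np.ndarray:
    """Leapfrog solution of the 2D wave equation with periodic boundaries,
    zero initial velocity, fourth-order spatial Laplacian."""
    dt = t_end / n_steps

    def lap(u):
        out = np.zeros_like(u)
        for axis, d in ((0, d_s), (1, d_z)):
            up1, um1 = np.roll(u, -1, axis), np.roll(u, 1, axis)
            up2, um2 = np.roll(u, -2, axis), np.roll(u, 2, axis)
            out += (-up2 + 16 * up1 - 30 * u + 16 * um1 - um2) / (12 * d * d)
        return out

    u_prev = field0.copy()
    # first step from zero velocity (Taylor): u1 = u0 + dt^2/2 c^2 lap(u0)
    u = u_prev + 0.5 * (cs * dt) ** 2 * lap(u_prev)
    for _ in range(n_steps - 1):
        u, u_prev = 2 * u - u_prev + (cs * dt) ** 2 * lap(u), u
    return u


# -- direct metric oracles --------------------------------------------------

def ssim_window_oracle(x: np.ndarray, ref: np.ndarray, data_range: float,
                       win: int = 7) -> float:
    """SSIM by explicit sliding uniform windows (standard constants),
    averaged over all fully interior windows."""
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    h, w = x.shape
    vals = []
    for i in range(h - win + 1):
        for j in range(w - win + 1):
            a = x[i:i + win, j:j + win].ravel()
            b = ref[i:i + win, j:j + win].ravel()
            ma, mb = a.mean(), b.mean()
            # unbiased (N-1) moments, matching the standard formulation
            va = a.var(ddof=1)
            vb = b.var(ddof=1)
            cov = np.cov(a, b, ddof=1)[0, 1]
            vals.append(((2 * ma * mb + c1) * (2 * cov + c2))
                        / ((ma ** 2 + mb ** 2 + c1) * (va + vb + c2)))
    return float(np.mean(vals))
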