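"""Primal-dual (Chambolle-Pock) TGV- and TV-regularized Radon inversion.

Solves, over pressure volumes p (and auxiliary vector fields q for TGV),

    min_p  mu/2 ||R p - f||^2 + TGV_a(p),
    TGV_a(p) = min_q  alpha1 ||grad p - q||_l1 + alpha0 ||E q||_l1,

or the TV analogue ``min_p mu/2 ||R p - f||^2 + alpha1 ||grad p||_l1``,
by the saddle-point iteration with combined operator

    A(p, q) = (R p, grad p - q, E q),     A*(g, v, w) = (R* g - div v, -div w - v),

dual proximal maps ``g -> mu/(mu+sigma) (g - sigma f)`` for the discrepancy
and pointwise Euclidean/Frobenius-ball projections for the l1 conjugates, and
an extragradient step.  The projector is rescaled to unit norm beforehand, so
the step-size rule ``sigma * tau < 1/12`` (TGV; 1/13 for TV) guarantees
convergence.  Iterates are all zero-initialized; the stopping rule is the
fixed iteration count (an optional relative-change early stop is off by
default).  Solutions may take negative values.
"""

from __future__ import annotations

import numpy as np

from . import diffops
from .geometry import GeometryConfig, SolverParams, check_sinogram, check_volume
from .radon import RadonTransform, estimate_operator_norm, normalize_problem


# -- combined operator ------------------------------------------------------

class TgvOperator:
    """Linear map A(p, q) = (R p, grad p - q, E q) with its exact adjoint.

    Domain elements are tuples ``(p, q)``; range elements ``(g, v, w)``.
    Inner products are Euclidean except on W, where off-diagonal tensor slots
    are counted twice (Frobenius pairing).
    """

    def __init__(self, radon: RadonTransform):
        self.radon = radon

    def apply(self, pq):
        p, q = pq
        return (self.radon.apply(p), diffops.grad(p) - q, diffops.symgrad(q))

    def adjoint(self, gvw):
        g, v, w = gvw
        return (self.radon.adjoint(g) - diffops.div_vector(v),
                -diffops.div_tensor(w) - v)


def apply_A(p, q, geo: GeometryConfig, radon: RadonTransform | None = None):
    """A(p, q) = (R p, grad p - q, E q)."""
    if radon is None:
        radon = RadonTransform(geo)
    q = np.asarray(q, dtype=float)
    if q.shape != geo.volume_shape + (3,):
        raise ValueError(f"q shape {q.shape} inconsistent with geometry")
    return TgvOperator(radon).apply((check_volume(p, geo), q))


def apply_A_adjoint(g, v, w, geo: GeometryConfig, radon: RadonTransform | None = None):
    """A*(g, v, w) = (R* g - div v, -div w - v)."""
    if radon is None:
        radon = RadonTransform(geo)
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != geo.volume_shape + (3,) or w.shape != geo.volume_shape + (6,):
        raise ValueError("v/w shapes inconsistent with geometry")
    return TgvOperator(radon).adjoint((check_sinogram(g, geo), v, w))


def estimate_combined_norm(radon: RadonTransform, n_iter: int = 500,
                           seed: int = 0) -> float:
    """Power-iteration estimate of ``||A||`` for the combined TGV operator.

    Runs the power iteration on A*A over the product space P x V with the
    W-weighted range pairing built into the adjoint; with the projector scaled
    to unit norm the squared estimate stays below 12.
    """
    op = TgvOperator(radon)
    geo = radon.geo
    rng = np.random.default_rng(seed)
    p = rng.standard_normal(geo.volume_shape)
    q = rng.standard_normal(geo.volume_shape + (3,))
    dot = lambda x, y: diffops.dot_p(x[0], y[0]) + diffops.dot_v(x[1], y[1])
    nrm = np.sqrt(dot((p, q), (p, q)))
    x = (p / nrm, q / nrm)
    lam = 0.0
    for _ in range(n_iter):
        y = op.adjoint(op.apply(x))
        lam = dot(x, y)
        nrm = np.sqrt(dot(y, y))
        if nrm == 0:
            return 0.0
        x = (y[0] / nrm, y[1] / nrm)
    return float(np.sqrt(max(lam, 0.0)))


# -- proximal maps ----------------------------------------------------------

def prox_discrepancy(g: np.ndarray, f: np.ndarray, sigma: float,
                     mu: float) -> np.ndarray:
    """Resolvent of the conjugate discrepancy: ``mu/(mu+sigma) * (g - sigma f)``."""
    if sigma <= 0 or mu <= 0:
        raise ValueError("sigma and mu must be positive")
    return (mu / (mu + sigma)) * (g - sigma * f)


def project_linf_vector(v: np.ndarray, alpha1: float) -> np.ndarray:
    """Pointwise projection onto the Euclidean ball of radius ``alpha1``."""
    if alpha1 <= 0:
        raise ValueError("alpha1 must be positive")
    mag = diffops.vector_magnitude(v)
    factor = alpha1 / np.maximum(mag, alpha1)
    return v * factor[..., None]


def project_linf_tensor(w: np.ndarray, alpha0: float) -> np.ndarray:
    """Pointwise projection onto the Frobenius ball of radius ``alpha0``."""
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    mag = diffops.tensor_magnitude(w)
    factor = alpha0 / np.maximum(mag, alpha0)
    return w * factor[..., None]


# -- regularizer values -----------------------------------------------------

def tv_value(p: np.ndarray) -> float:
    """Discrete total variation: l1 norm of pointwise gradient magnitudes."""
    return float(np.sum(diffops.vector_magnitude(diffops.grad(np.asarray(p, float)))))


def tgv_value(p: np.ndarray, alpha0: float = 2.5, alpha1: float = 1.0,
              inner_iters: int = 2000) -> float:
    """Second-order TGV of ``p``: inner minimization over q by primal-dual.

    Solves ``min_q alpha1 ||grad p - q||_l1 + alpha0 ||E q||_l1`` with the same
    machinery as the reconstruction (operator ``q -> (q, E q)``); returns the
    smaller of the values at the last and at the ergodic-average iterate (both
    feasible, so the result is always an upper bound on the true minimum).
    """
    if inner_iters < 1:
        raise ValueError("inner_iters must be >= 1")
    p = np.asarray(p, dtype=float)
    gp = diffops.grad(p)

    def value(q):
        return float(
            alpha1 * np.sum(diffops.vector_magnitude(gp - q))
            + alpha0 * np.sum(diffops.tensor_magnitude(diffops.symgrad(q)))
        )

    # ||q -> (q, E q)||^2 <= 1 + 8; symmetric steps just below 1/3
    step = 1.0 / 3.0 - 1e-9
    sigma = tau = step
    q = np.zeros(p.shape + (3,))
    qb = q.copy()
    q_sum = np.zeros_like(q)
    v = np.zeros_like(q)
    w = np.zeros(p.shape + (6,))
    for _ in range(inner_iters):
        v = project_linf_vector(v + sigma * (qb - gp), alpha1)
        w = project_linf_tensor(w + sigma * diffops.symgrad(qb), alpha0)
        q_new = q - tau * (v - diffops.div_tensor(w))
        qb = 2.0 * q_new - q
        q = q_new
        q_sum += q
    return min(value(q), value(q_sum / inner_iters))


# -- reconstruction ---------------------------------------------------------

def _primal_objective(p, f_scaled, radon_scaled, params: SolverParams,
                      tgv_budget: int = 200) -> float:
    resid = radon_scaled.apply(p) - f_scaled
    data = 0.5 * params.mu * float(np.sum(resid * resid))
    if params.regularizer == "tv":
        return data + params.alpha1 * tv_value(p)
    return data + tgv_value(p, params.alpha0, params.alpha1, inner_iters=tgv_budget)


def reconstruct(f: np.ndarray, geo: GeometryConfig, params: SolverParams,
                radon: RadonTransform | None = None):
    """TGV-regularized inversion of the slice-wise Radon transform.

    The projector and datum are first rescaled to unit operator norm; ``mu``
    applies to the rescaled problem (as in the measurement model, where the
    calibration constant is likewise absorbed into ``mu``).  Runs exactly
    ``params.n_iter`` iterations (dual, primal, extragradient) from zero
    initialization and returns ``(p, diagnostics)``.
    """
    if params.regularizer == "tv":
        return reconstruct_tv(f, geo, params, radon=radon)
    f = check_sinogram(f, geo)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite sinogram")
    radon_s, f_s, scale = normalize_problem(geo, f, radon=radon)
    mu, a1, a0 = params.mu, params.alpha1, params.alpha0
    sigma, tau = params.sigma, params.tau

    p = np.zeros(geo.volume_shape)
    q = np.zeros(geo.volume_shape + (3,))
    pb, qb = p.copy(), q.copy()
    g = np.zeros(geo.sinogram_shape)
    v = np.zeros_like(q)
    w = np.zeros(geo.volume_shape + (6,))

    diag = {"scale": scale, "iterations": params.n_iter, "objective": [],
            "residual": []}
    log_every = params.log_every or 0
    for n in range(params.n_iter):
        g = (mu / (mu + sigma)) * (g + sigma * (radon_s.apply(pb) - f_s))
        v = project_linf_vector(v + sigma * (diffops.grad(pb) - qb), a1)
        w = project_linf_tensor(w + sigma * diffops.symgrad(qb), a0)
        p_new = p - tau * (radon_s.adjoint(g) - diffops.div_vector(v))
        q_new = q + tau * (v + diffops.div_tensor(w))
        pb = 2.0 * p_new - p
        qb = 2.0 * q_new - q
        if params.stop_tol is not None and (n + 1) % 50 == 0:
            denom = np.linalg.norm(p_new)
            if denom > 0 and np.linalg.norm(p_new - p) / denom < params.stop_tol:
                p, q = p_new, q_new
                diag["iterations"] = n + 1
                break
        p, q = p_new, q_new
        if log_every and (n + 1) % log_every == 0:
            resid = radon_s.apply(p) - f_s
            diag["residual"].append(float(np.linalg.norm(resid)))
            if params.record_objective:
                diag["objective"].append(
                    _primal_objective(p, f_s, radon_s, params)
                )
    resid = radon_s.apply(p) - f_s
    diag["final_residual"] = float(np.linalg.norm(resid))
    if params.record_objective:
        diag["final_objective"] = _primal_objective(p, f_s, radon_s, params,
                                                    tgv_budget=1000)
    return p, diag


def reconstruct_tv(f: np.ndarray, geo: GeometryConfig, params: SolverParams,
                   radon: RadonTransform | None = None):
    """TV-regularized inversion: the same scheme with q and w removed.

    ``params.alpha1`` plays the role of the TV weight.
    """
    f = check_sinogram(f, geo)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite sinogram")
    if params.sigma * params.tau * 13.0 >= 1.0:
        raise ValueError("TV variant needs sigma*tau < 1/13")
    radon_s, f_s, scale = normalize_problem(geo, f, radon=radon)
    mu, a1 = params.mu, params.alpha1
    sigma, tau = params.sigma, params.tau

    p = np.zeros(geo.volume_shape)
    pb = p.copy()
    g = np.zeros(geo.sinogram_shape)
    v = np.zeros(geo.volume_shape + (3,))

    diag = {"scale": scale, "iterations": params.n_iter, "objective": [],
            "residual": []}
    log_every = params.log_every or 0
    for n in range(params.n_iter):
        g = (mu / (mu + sigma)) * (g + sigma * (radon_s.apply(pb) - f_s))
        v = project_linf_vector(v + sigma * diffops.grad(pb), a1)
        p_new = p - tau * (radon_s.adjoint(g) - diffops.div_vector(v))
        pb = 2.0 * p_new - p
        if params.stop_tol is not None and (n + 1) % 50 == 0:
            denom = np.linalg.norm(p_new)
            if denom > 0 and np.linalg.norm(p_new - p) / denom < params.stop_tol:
                p = p_new
                diag["iterations"] = n + 1
                break
        p = p_new
        if log_every and (n + 1) % log_every == 0:
            resid = radon_s.apply(p) - f_s
            diag["residual"].append(float(np.linalg.norm(resid)))
            if params.record_objective:
                diag["objective"].append(
                    0.5 * mu * float(np.sum(resid * resid)) + a1 * tv_value(p)
                )
    resid = radon_s.apply(p) - f_s
    diag["final_residual"] = float(np.linalg.norm(resid))
    if params.record_objective:
        diag["final_objective"] = (
            0.5 * mu * float(np.sum(resid * resid)) + a1 * tv_value(p)
        )
    return p, diag
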