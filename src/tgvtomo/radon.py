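"""Slice-wise discrete 2D Radon transform, adjoint, and normalization.

The projector uses an exact pixel-footprint (strip) discretization: for every
angle, each square pixel deposits its projection profile — the trapezoid
obtained by projecting the square onto the offset axis, carrying total mass
equal to the pixel area — onto the s-bins, with each bin receiving the bin
average of the profile.  Forward and adjoint share one sparse matrix per
geometry, so the pair ``(R, R*)`` is adjoint to machine precision, which the
convergence theory of the primal-dual solver requires.

The same weights are applied independently to every z-slice.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .geometry import GeometryConfig, check_sinogram, check_volume


def _trapezoid_cdf(t: np.ndarray, a: float, b: float) -> np.ndarray:
    """CDF at ``t`` of the unit-mass trapezoid ``box_a/a * box_b/b``.

    ``a, b`` are the widths of the two boxes (the pixel extents projected on
    the two lattice directions); degenerate ``b -> 0`` reduces to a box.
    """
    big, small = max(a, b), min(a, b)
    small = max(small, 1e-12 * big)
    c1 = 0.5 * (big + small)
    c2 = 0.5 * (big - small)
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    lo = t <= -c1
    hi = t >= c1
    rise = (~lo) & (t < -c2)
    fall = (~hi) & (t > c2)
    mid = ~(lo | hi | rise | fall)
    out[lo] = 0.0
    out[hi] = 1.0
    out[rise] = (t[rise] + c1) ** 2 / (2.0 * big * small)
    out[fall] = 1.0 - (c1 - t[fall]) ** 2 / (2.0 * big * small)
    out[mid] = 0.5 * small / big + (t[mid] + c2) / big
    return out


def _build_matrix(geo: GeometryConfig) -> sp.csr_matrix:
    """Stacked sparse projection matrix of shape (n_angles * ns, nx * nx)."""
    nx, ns = geo.nx, geo.ns
    d, ds = geo.dx, geo.ds
    centers = geo.pixel_centers
    xc, yc = np.meshgrid(centers, centers, indexing="ij")
    xc = xc.ravel()
    yc = yc.ravel()
    pix_area = d * d
    rows, cols, vals = [], [], []
    cols_base = np.arange(nx * nx)
    for ai, phi in enumerate(geo.angles):
        c, s = np.cos(phi), np.sin(phi)
        sc = xc * c + yc * s
        a = d * abs(c)
        b = d * abs(s)
        half = 0.5 * (a + max(b, 1e-12 * max(a, b, d)))
        span = int(np.ceil(2 * half / ds)) + 2
        k_lo = np.floor((sc - half + 1.0) / ds).astype(np.int64)
        offs = np.arange(span)
        kk = k_lo[:, None] + offs[None, :]          # (npix, span)
        left = -1.0 + kk * ds - sc[:, None]
        right = left + ds
        w = _trapezoid_cdf(right, a, b) - _trapezoid_cdf(left, a, b)
        w *= pix_area / ds                           # bin-averaged line integral
        keep = (kk >= 0) & (kk < ns) & (w > 0)
        rows.append((ai * ns + kk[keep]).ravel())
        cols.append(np.broadcast_to(cols_base[:, None], kk.shape)[keep].ravel())
        vals.append(w[keep].ravel())
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geo.n_angles * ns, nx * nx),
    )
    return mat.tocsr()


class RadonTransform:
    """Matrix-free linear-map contract (``apply`` / ``adjoint``) for R: P -> S."""

    def __init__(self, geo: GeometryConfig, scale: float = 1.0):
        self.geo = geo
        self.scale = float(scale)
        self._mat = _build_matrix(geo)
        self._mat_t = self._mat.T.tocsr()

    def apply(self, p: np.ndarray) -> np.ndarray:
        p = check_volume(p, self.geo)
        geo = self.geo
        flat = p.reshape(geo.nx * geo.nx, geo.nz)
        out = self._mat @ flat                        # (n_angles*ns, nz)
        out = out.reshape(geo.n_angles, geo.ns, geo.nz).transpose(1, 0, 2)
        return np.ascontiguousarray(out) * self.scale

    def adjoint(self, g: np.ndarray) -> np.ndarray:
        g = check_sinogram(g, self.geo)
        geo = self.geo
        flat = np.ascontiguousarray(g.transpose(1, 0, 2)).reshape(
            geo.n_angles * geo.ns, geo.nz
        )
        out = self._mat_t @ flat
        return out.reshape(geo.nx, geo.nx, geo.nz) * self.scale

    def rescaled(self, factor: float) -> "RadonTransform":
        """Cheap copy with the scale multiplied by ``factor`` (shares weights)."""
        other = object.__new__(RadonTransform)
        other.geo = self.geo
        other.scale = self.scale * factor
        other._mat = self._mat
        other._mat_t = self._mat_t
        return other


def radon_forward(p: np.ndarray, geo: GeometryConfig) -> np.ndarray:
    """Slice-wise Radon transform of a pressure volume."""
    return RadonTransform(geo).apply(p)


def radon_adjoint(g: np.ndarray, geo: GeometryConfig) -> np.ndarray:
    """Exact adjoint of :func:`radon_forward`."""
    return RadonTransform(geo).adjoint(g)


def estimate_operator_norm(op, template: np.ndarray, n_iter: int = 100,
                           seed: int = 0, dot=None) -> float:
    """Power-iteration estimate of ``||op||`` from a seeded random start.

    Iterates ``x <- op*(op x) / ||.||`` on the domain described by the array
    ``template`` (only its shape is used); returns the square root of the
    largest-eigenvalue estimate of ``op* op``.  ``dot`` optionally overrides
    the domain inner product (defaults to the Euclidean one).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if dot is None:
        dot = lambda a, b: float(np.vdot(a, b).real)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(np.shape(template))
    nrm = np.sqrt(dot(x, x))
    if nrm == 0:
        return 0.0
    x = x / nrm
    lam = 0.0
    for _ in range(n_iter):
        y = op.adjoint(op.apply(x))
        lam = dot(x, y)
        nrm = np.sqrt(dot(y, y))
        if nrm == 0:
            return 0.0
        x = y / nrm
    return float(np.sqrt(max(lam, 0.0)))


def normalize_problem(geo: GeometryConfig, f: np.ndarray,
                      radon: RadonTransform | None = None,
                      n_iter: int = 100, seed: int = 0):
    """Scale the projector pair and the datum to unit operator norm.

    Estimates ``||R||`` by power iteration; if it exceeds 1, returns
    ``(R/c, f/c, c)`` with ``c = ||R||`` so the scaled projector has unit norm
    (the primal-dual step-size rule assumes ``||R|| <= 1``), else returns the
    inputs unchanged with ``c = 1``.
    """
    f = check_sinogram(f, geo)
    if radon is None:
        radon = RadonTransform(geo)
    c = estimate_operator_norm(
        radon, np.empty(geo.volume_shape), n_iter=n_iter, seed=seed
    )
    if c <= 1.0:
        return radon, f, 1.0
    return radon.rescaled(1.0 / c), f / c, c
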