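"""Discrete differential operators for TGV on the voxel grid.

Forward differences with a zero difference at the trailing boundary define the
gradient on scalar volumes and the symmetrized derivative on vector fields;
the divergences are their exact negative adjoints (backward differences with
the matching boundary closure), so that

    <grad p, v>_V = -<p, div_vector v>_P,
    <symgrad v, w>_W = -<v, div_tensor w>_V,

hold to floating-point roundoff.  All difference quotients use unit (voxel)
spacing; physical spacing is absorbed into the regularization weights.

Symmetric tensors are stored with 6 components (xx, yy, zz, xy, xz, yz); the
W inner product counts the off-diagonal slots twice so the pointwise magnitude
is the Frobenius norm of the symmetric 3x3 matrix.
"""

from __future__ import annotations

import numpy as np

#: multiplicities of the 6 stored tensor slots in the Frobenius inner product
W_WEIGHTS = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


def _fwd_diff(a: np.ndarray, axis: int) -> np.ndarray:
    """Forward difference, zero at the last index along ``axis``."""
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    src[axis] = slice(1, None)
    dst[axis] = slice(None, -1)
    out[tuple(dst)] = a[tuple(src)] - a[tuple(dst)]
    return out


def _bwd_div(a: np.ndarray, axis: int) -> np.ndarray:
    """Negative adjoint of :func:`_fwd_diff` along ``axis``.

    Interior: ``a[i] - a[i-1]``; first index: ``a[0]``; last index: ``-a[n-2]``.
    """
    out = np.empty_like(a)
    n = a.shape[axis]
    idx = lambda s: tuple(s if ax == axis else slice(None) for ax in range(a.ndim))
    if n == 1:
        out[...] = 0.0
        return out
    out[idx(slice(1, -1))] = a[idx(slice(1, -1))] - a[idx(slice(0, -2))]
    out[idx(0)] = a[idx(0)]
    out[idx(n - 1)] = -a[idx(n - 2)]
    return out


def grad(p: np.ndarray) -> np.ndarray:
    """Discrete gradient P -> V (forward differences)."""
    p = np.asarray(p, dtype=float)
    return np.stack([_fwd_diff(p, ax) for ax in range(3)], axis=-1)


def div_vector(v: np.ndarray) -> np.ndarray:
    """Discrete divergence V -> P; exact negative adjoint of :func:`grad`."""
    v = np.asarray(v, dtype=float)
    return sum(_bwd_div(v[..., ax], ax) for ax in range(3))


# index pairs of the stored tensor slots
_SLOTS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def symgrad(v: np.ndarray) -> np.ndarray:
    """Symmetrized derivative V -> W, ``E(v)_ij = (d_i v_j + d_j v_i) / 2``."""
    v = np.asarray(v, dtype=float)
    out = np.empty(v.shape[:-1] + (6,))
    for slot, (i, j) in enumerate(_SLOTS):
        if i == j:
            out[..., slot] = _fwd_diff(v[..., i], i)
        else:
            out[..., slot] = 0.5 * (_fwd_diff(v[..., j], i) + _fwd_diff(v[..., i], j))
    return out


def div_tensor(w: np.ndarray) -> np.ndarray:
    """Divergence W -> V; exact negative adjoint of :func:`symgrad`.

    ``(div w)_i = sum_j d_j w_ij`` with backward differences; by the symmetry
    of ``w`` the off-diagonal double-count of the W inner product cancels the
    1/2 of the symmetrization, making the adjoint identity exact.
    """
    w = np.asarray(w, dtype=float)
    slot_of = {frozenset(pair): slot for slot, pair in enumerate(_SLOTS)}
    out = np.empty(w.shape[:-1] + (3,))
    for i in range(3):
        out[..., i] = sum(
            _bwd_div(w[..., slot_of[frozenset((i, j))]], j) for j in range(3)
        )
    return out


# -- inner products and pointwise norms ------------------------------------

def dot_p(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.vdot(a, b).real)


def dot_v(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.vdot(a, b).real)


def dot_w(a: np.ndarray, b: np.ndarray) -> float:
    """W inner product with doubled off-diagonal slots (Frobenius pairing)."""
    return float(np.sum(a * b * W_WEIGHTS))


def vector_magnitude(v: np.ndarray) -> np.ndarray:
    """Pointwise Euclidean magnitude of a vector field."""
    return np.sqrt(np.sum(v * v, axis=-1))


def tensor_magnitude(w: np.ndarray) -> np.ndarray:
    """Pointwise Frobenius magnitude of a symmetric tensor field."""
    return np.sqrt(np.sum(w * w * W_WEIGHTS, axis=-1))
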