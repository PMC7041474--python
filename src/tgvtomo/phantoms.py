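"""Synthetic initial-pressure phantoms.

The default phantom mirrors the structure of typical photoacoustic targets:
a thin, bright vascular skeleton (value exactly 1) laid over sub-unit smooth
background structures — two ellipsoids of variable pressure (tumor-like) and
a linearly increasing ramp (tissue background) — composed additively, then
embedded centered in a larger zero reconstruction domain.  The vessel
skeleton is generated procedurally as random smooth cubic-spline curves
rasterized to one-voxel width, preserving the statistical character (thin
bright curvilinear structures) of skeletonized vascular data.

A second phantom family emulates hair-loop/microsphere samples: thin closed
loops of random orientation plus small filled spheres, all of value 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import CubicSpline


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Recipe for the composed default phantom.

    ``ellipsoids`` entries are ``(center, semiaxes, value)`` in voxel units;
    ``ramp`` is ``(box, axis, vmin, vmax)`` with ``box`` a voxel box
    ``((x0, x1), (y0, y1), (z0, z1))`` of half-open index ranges.
    """

    inner_shape: tuple[int, int, int] = (128, 128, 40)
    outer_shape: tuple[int, int, int] = (281, 281, 40)
    n_curves: int = 8
    ellipsoids: tuple = (
        ((40, 44, 20), (22, 16, 12), 0.3),
        ((88, 84, 18), (18, 24, 14), 0.6),
    )
    ramp: tuple = (((16, 112), (70, 122), (4, 36)), "y", 0.0, 0.8)
    seed: int = 0

    def __post_init__(self):
        if any(i > o for i, o in zip(self.inner_shape, self.outer_shape)):
            raise ValueError("inner shape must fit inside the outer shape")


def _check_shape(shape) -> tuple[int, int, int]:
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or any(n < 1 for n in shape):
        raise ValueError(f"invalid volume shape {shape}")
    return shape


def make_vessel_skeleton(shape, n_curves: int, seed: int = 0) -> np.ndarray:
    """Binary volume of ``n_curves`` random smooth one-voxel-wide curves.

    Each curve is a cubic spline through uniformly sampled control points,
    sampled densely enough that consecutive rasterized voxels differ by at
    most one index per axis (26-connectivity).  Curve voxels have value 1.
    """
    shape = _check_shape(shape)
    if n_curves < 0:
        raise ValueError("n_curves must be >= 0")
    rng = np.random.default_rng(seed)
    vol = np.zeros(shape)
    extent = np.array(shape, dtype=float)
    for _ in range(n_curves):
        n_ctrl = int(rng.integers(4, 7))
        ctrl = rng.uniform(0.05, 0.95, size=(n_ctrl, 3)) * extent
        t = np.linspace(0.0, 1.0, n_ctrl)
        spline = CubicSpline(t, ctrl, axis=0)
        # arc length bound -> sampling step < half a voxel
        n_samp = max(64, int(8 * np.sum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1))))
        pts = spline(np.linspace(0.0, 1.0, n_samp))
        idx = np.rint(pts - 0.5).astype(int)
        keep = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        idx = idx[keep]
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0
    return vol


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semiaxes
    if min(ax, ay, az) <= 0:
        raise ValueError("semiaxes must be positive")
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    r2 = (((x + 0.5) - cx) / ax) ** 2 + (((y + 0.5) - cy) / ay) ** 2 \
        + (((z + 0.5) - cz) / az) ** 2
    return r2 <= 1.0


def add_ellipsoid(vol: np.ndarray, center, semiaxes, value: float) -> np.ndarray:
    """Add ``value`` on an ellipsoidal region (additive composition).

    Supports centered anywhere; parts of the ellipsoid outside the volume are
    clipped.  Returns a new volume.
    """
    if not np.isfinite(value):
        raise ValueError("ellipsoid value must be finite")
    vol = np.asarray(vol, dtype=float)
    out = vol.copy()
    out[_ellipsoid_mask(vol.shape, center, semiaxes)] += value
    return out


def add_ramp(vol: np.ndarray, region, axis: str, vmin: float, vmax: float) -> np.ndarray:
    """Add a value varying affinely from ``vmin`` to ``vmax`` along ``axis``
    inside a voxel box; a single-slice region receives ``vmin``."""
    axes = {"x": 0, "y": 1, "z": 2}
    if axis not in axes:
        raise ValueError(f"axis must be one of {sorted(axes)}")
    if vmin > vmax:
        raise ValueError("need vmin <= vmax")
    vol = np.asarray(vol, dtype=float)
    sl = []
    for dim, (lo, hi) in enumerate(region):
        if not (0 <= lo <= hi <= vol.shape[dim]):
            raise ValueError(f"region {region} exceeds volume shape {vol.shape}")
        sl.append(slice(lo, hi))
    out = vol.copy()
    ax = axes[axis]
    n = sl[ax].stop - sl[ax].start
    if n == 0:
        import warnings

        warnings.warn("empty ramp region; no-op", stacklevel=2)
        return out
    profile = np.full(n, vmin) if n == 1 else np.linspace(vmin, vmax, n)
    shape = [1, 1, 1]
    shape[ax] = n
    out[tuple(sl)] += profile.reshape(shape)
    return out


def compose_default_phantom(spec: PhantomSpec = PhantomSpec()) -> np.ndarray:
    """Skeleton + ellipsoids + ramp on the inner grid, embedded centered
    (x, y, and z) in the zero-padded outer grid.  Deterministic in the seed."""
    inner = make_vessel_skeleton(spec.inner_shape, spec.n_curves, spec.seed)
    for center, semiaxes, value in spec.ellipsoids:
        inner = add_ellipsoid(inner, center, semiaxes, value)
    region, axis, vmin, vmax = spec.ramp
    inner = add_ramp(inner, region, axis, vmin, vmax)
    outer = np.zeros(spec.outer_shape)
    off = [(o - i) // 2 for o, i in zip(spec.outer_shape, spec.inner_shape)]
    outer[off[0]: off[0] + spec.inner_shape[0],
          off[1]: off[1] + spec.inner_shape[1],
          off[2]: off[2] + spec.inner_shape[2]] = inner
    return outer


def inner_region_slices(spec: PhantomSpec) -> tuple[slice, slice, slice]:
    """Slices of the embedded inner phantom inside the outer volume."""
    off = [(o - i) // 2 for o, i in zip(spec.outer_shape, spec.inner_shape)]
    return tuple(slice(off[d], off[d] + spec.inner_shape[d]) for d in range(3))


def make_hairloop_phantom(shape, n_loops: int = 3, n_spheres: int = 5,
                          seed: int = 0) -> np.ndarray:
    """Thin closed loops of random orientation plus small filled spheres,
    all of value 1 on a zero background."""
    shape = _check_shape(shape)
    if n_loops < 0 or n_spheres < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    vol = np.zeros(shape)
    extent = np.array(shape, dtype=float)
    for _ in range(n_loops):
        center = rng.uniform(0.3, 0.7, size=3) * extent
        radius = rng.uniform(0.15, 0.3) * float(min(shape[:2]))
        # random orthonormal in-plane frame
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(3)
        v -= u * (u @ v)
        v /= np.linalg.norm(v)
        theta = np.linspace(0.0, 2 * np.pi, int(16 * radius), endpoint=False)
        pts = center + radius * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v))
        idx = np.rint(pts - 0.5).astype(int)
        keep = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        idx = idx[keep]
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0
    for _ in range(n_spheres):
        center = rng.uniform(0.2, 0.8, size=3) * extent
        radius = rng.uniform(1.5, 3.0)
        mask = _ellipsoid_mask(shape, center, (radius, radius, radius))
        vol[mask] = 1.0
    return vol
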