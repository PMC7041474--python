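"""Grids, physical conventions and solver parameter containers.

The reconstruction domain is the box ``[-sqrt(2)/2, sqrt(2)/2]^2 x [0, h]``
subdivided into ``nx * nx * nz`` cubic cells; the half integration length of
the projection lines is normalized to ``L = 1`` so projection offsets live in
``[-1, 1]``.  Projection angles are uniform on ``[0, pi)``.

Array conventions used throughout the package:

* pressure volumes ("space P"): ``float`` arrays of shape ``(nx, nx, nz)``,
  axis order (x, y, z);
* vector fields ("space V"): shape ``(nx, nx, nz, 3)``, components (x, y, z);
* symmetric tensor fields ("space W"): shape ``(nx, nx, nz, 6)``, components
  ordered (xx, yy, zz, xy, xz, yz) with the pointwise magnitude taken as the
  Frobenius norm of the symmetric 3x3 matrix (off-diagonals counted twice);
* sinograms / snapshot stacks ("space S"): shape ``(ns, n_angles, nz)``,
  axis order (offset s, angle phi, height z); s-bin centers are
  ``-1 + (k + 1/2) * 2/ns``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

SQRT2 = math.sqrt(2.0)


@dataclasses.dataclass(frozen=True)
class GeometryConfig:
    """Discretization and acquisition geometry.

    Parameters
    ----------
    nx : lateral grid size (the volume is ``nx * nx * nz``).
    nz : number of z-slices.
    n_angles : number of uniformly spaced projection angles on ``[0, pi)``.
    ns : number of projection-offset bins on ``[-1, 1]``; defaults to ``2 * nx``
        which oversamples the diagonal of the lateral domain.
    h : physical height of the volume; defaults to cubic voxels
        (``sqrt(2) * nz / nx``).
    cs : speed of sound (length / time, in the normalized length units).
    T : snapshot time of the phase-contrast measurement.
    """

    nx: int
    nz: int
    n_angles: int
    ns: int | None = None
    h: float | None = None
    cs: float = 1.0
    T: float = 0.25

    def __post_init__(self):
        if self.nx < 1 or self.nz < 1 or self.n_angles < 1:
            raise ValueError("grid sizes and angle count must be positive")
        if self.ns is None:
            object.__setattr__(self, "ns", 2 * self.nx)
        if self.ns < 1:
            raise ValueError("ns must be positive")
        if self.h is None:
            object.__setattr__(self, "h", SQRT2 * self.nz / self.nx)
        if self.h <= 0 or self.cs <= 0:
            raise ValueError("h and cs must be positive")

    # -- derived grid quantities -------------------------------------------
    @property
    def dx(self) -> float:
        """Lateral voxel size."""
        return SQRT2 / self.nx

    @property
    def ds(self) -> float:
        """Projection-offset bin width."""
        return 2.0 / self.ns

    @property
    def dz(self) -> float:
        return self.h / self.nz

    @property
    def angles(self) -> np.ndarray:
        """Uniform angles ``phi_k = k * pi / n_angles`` on ``[0, pi)``."""
        return np.arange(self.n_angles) * (np.pi / self.n_angles)

    @property
    def s_centers(self) -> np.ndarray:
        return -1.0 + (np.arange(self.ns) + 0.5) * self.ds

    @property
    def pixel_centers(self) -> np.ndarray:
        """Lateral cell-center coordinates on ``[-sqrt(2)/2, sqrt(2)/2]``."""
        return -SQRT2 / 2 + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return (self.nx, self.nx, self.nz)

    @property
    def sinogram_shape(self) -> tuple[int, int, int]:
        return (self.ns, self.n_angles, self.nz)

    def subsample_angles(self, factor: int) -> "GeometryConfig":
        """Geometry with every ``factor``-th angle kept (factor must divide)."""
        if self.n_angles % factor != 0:
            raise ValueError(
                f"angle subsampling factor {factor} does not divide {self.n_angles}"
            )
        return dataclasses.replace(self, n_angles=self.n_angles // factor)


@dataclasses.dataclass
class SolverParams:
    """Parameters of the primal-dual reconstruction (Chambolle-Pock).

    ``mu`` weights the data-discrepancy term ``mu/2 ||Rp - f||^2``; ``alpha1``
    and ``alpha0`` weight the first- and second-order TGV terms.  The step
    sizes must satisfy ``sigma * tau * ||A||^2 < 1``; the combined TGV operator
    with a unit-norm projector satisfies ``||A||^2 < 12``, hence the default
    symmetric choice ``sigma = tau = 1/sqrt(12) - 1e-6``.  The TV operator
    only admits the cruder bound ``||A||^2 <= 13``, so the TV default is
    ``1/sqrt(13) - 1e-6``.
    """

    mu: float
    n_iter: int
    alpha1: float = 1.0
    alpha0: float = 2.5
    sigma: float | None = None
    tau: float | None = None
    regularizer: str = "tgv"
    record_objective: bool = False
    log_every: int = 0
    #: optional relative-change early stop (checked every 50 iterations);
    #: None keeps the fixed iteration count as the only stopping rule
    stop_tol: float | None = None

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.alpha0 <= 0 or self.alpha1 <= 0:
            raise ValueError("alpha0, alpha1 must be positive")
        if self.regularizer not in ("tgv", "tv"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")
        bound = 12.0 if self.regularizer == "tgv" else 13.0
        if self.sigma is None and self.tau is None:
            step = 1.0 / math.sqrt(bound) - 1e-6
            self.sigma = step
            self.tau = step
        elif self.sigma is None or self.tau is None:
            raise ValueError("set both sigma and tau or neither")
        if self.sigma <= 0 or self.tau <= 0 or self.sigma * self.tau * bound >= 1.0:
            raise ValueError(
                f"need sigma, tau > 0 with sigma*tau < 1/{bound:g} for the "
                f"{self.regularizer} operator"
            )


def check_volume(p: np.ndarray, geo: GeometryConfig | None = None) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 3:
        raise ValueError(f"pressure volume must be 3D, got shape {p.shape}")
    if geo is not None and p.shape != geo.volume_shape:
        raise ValueError(f"volume shape {p.shape} != geometry {geo.volume_shape}")
    return p


def check_sinogram(f: np.ndarray, geo: GeometryConfig | None = None) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ValueError(f"sinogram must be 3D (s, angle, z), got shape {f.shape}")
    if geo is not None and f.shape != geo.sinogram_shape:
        raise ValueError(f"sinogram shape {f.shape} != geometry {geo.sinogram_shape}")
    return f
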