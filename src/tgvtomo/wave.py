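"""Acoustic propagation and back propagation in the sinogram domain.

The projection data of a pressure field obeying the free-space wave equation
with zero initial velocity itself satisfies, per angle, the 2D wave equation
in (s, z).  Its solution at time ``T`` is the inverse Fourier transform of the
initial spectrum multiplied by ``cos(cs |k| T)``; back propagation applies the
same multiplier to twice the measured time-``T`` sinogram, recovering the
initial sinogram plus an outgoing echo at time ``2T`` which has left the
region of interest whenever ``2 cs T`` exceeds the support-plus-ROI radius.

All spectral computations run on a zero-padded grid (default pad factor 2 per
axis, settable per axis for strongly anisotropic grids, data centered) to emulate free-space propagation and suppress periodic
wrap-around; snapshot stacks may be kept on the padded "camera" grid so the
full wave pattern is retained for back propagation.
"""

from __future__ import annotations

import numpy as np
import scipy.fft

from .geometry import GeometryConfig
from .radon import radon_forward


def _pad_factors(pad_factor) -> tuple[int, int]:
    """Per-axis (s, z) padding factors from an int or a pair."""
    if np.isscalar(pad_factor):
        pf = (int(pad_factor), int(pad_factor))
    else:
        pf = (int(pad_factor[0]), int(pad_factor[1]))
    if min(pf) < 1:
        raise ValueError("pad factors must be >= 1")
    return pf


def _padded_sizes(n_s: int, n_z: int, pad_factor) -> tuple[int, int]:
    pf_s, pf_z = _pad_factors(pad_factor)
    return pf_s * n_s, pf_z * n_z


def _propagator(ps: int, pz: int, geo: GeometryConfig, time: float) -> np.ndarray:
    ks = 2 * np.pi * scipy.fft.fftfreq(ps, d=geo.ds)
    kz = 2 * np.pi * scipy.fft.fftfreq(pz, d=geo.dz)
    kmag = np.sqrt(ks[:, None] ** 2 + kz[None, :] ** 2)
    return np.cos(geo.cs * kmag * time)


def _apply_multiplier(stack: np.ndarray, geo: GeometryConfig, time: float,
                      pad_factor: int, crop_to: tuple[int, int] | None) -> np.ndarray:
    """Multiply each (s, z) angle-plane spectrum by ``cos(cs |k| time)``.

    ``stack`` has shape (n_s, n_angles, n_z); the plane is embedded centered
    into the padded grid.  If ``crop_to`` is given the central block of that
    shape is returned, otherwise the full padded field.
    """
    stack = np.asarray(stack, dtype=float)
    if not np.all(np.isfinite(stack)):
        raise ValueError("non-finite values in snapshot/sinogram stack")
    n_s, n_ang, n_z = stack.shape
    ps, pz = _padded_sizes(n_s, n_z, pad_factor)
    off_s, off_z = (ps - n_s) // 2, (pz - n_z) // 2
    field = np.zeros((n_ang, ps, pz))
    field[:, off_s:off_s + n_s, off_z:off_z + n_z] = stack.transpose(1, 0, 2)
    spec = scipy.fft.fft2(field, axes=(-2, -1))
    spec *= _propagator(ps, pz, geo, time)[None, :, :]
    field = scipy.fft.ifft2(spec, axes=(-2, -1)).real
    if crop_to is None:
        return np.ascontiguousarray(field.transpose(1, 0, 2))
    cs_, cz_ = crop_to
    os_, oz_ = (ps - cs_) // 2, (pz - cz_) // 2
    out = field[:, os_:os_ + cs_, oz_:oz_ + cz_]
    return np.ascontiguousarray(out.transpose(1, 0, 2))


def forward_propagate(sino0: np.ndarray, geo: GeometryConfig,
                      pad_factor=2, crop: bool = True) -> np.ndarray:
    """Evolve the initial sinogram to time ``geo.T`` under the 2D wave equation.

    With ``crop=False`` the full padded field (the "camera sees the whole
    wave pattern" setting) is returned; its grid is ``pad_factor`` times the
    sinogram grid per axis, data centered.
    """
    n_s, _, n_z = np.asarray(sino0).shape
    crop_to = (n_s, n_z) if crop else None
    return _apply_multiplier(sino0, geo, geo.T, pad_factor, crop_to)


def to_phase_contrast(sino_t: np.ndarray, k_pc: float = 1.0) -> np.ndarray:
    """Phase-contrast snapshot stack: pointwise scaling by the calibration
    constant ``k_pc = 2*pi/lambda_PB * dn/dp`` (radians per pressure-length)."""
    if not np.isfinite(k_pc):
        raise ValueError("k_pc must be finite")
    return np.asarray(sino_t, dtype=float) * k_pc


def back_propagate(snap: np.ndarray, geo: GeometryConfig, k_pc: float = 1.0,
                   pad_factor=2) -> np.ndarray:
    """Frequency-domain back propagation of a snapshot stack.

    Recovers (approximately, inside the region of interest) the initial
    sinogram as ``F^-1[ F[2 R[p_T]] cos(cs |k| T) ]`` where
    ``R[p_T] = snap / k_pc``.  Snapshot stacks larger than the nominal
    sinogram grid are treated as centered padded camera fields and the
    result is cropped back to ``geo.sinogram_shape``.
    """
    if k_pc == 0:
        raise ValueError("k_pc must be nonzero")
    snap = np.asarray(snap, dtype=float)
    n_s, n_ang, n_z = snap.shape
    if n_ang != geo.n_angles:
        raise ValueError(f"snapshot stack has {n_ang} angles, geometry {geo.n_angles}")
    pf = pad_factor if (n_s == geo.ns and n_z == geo.nz) else (1, 1)
    return _apply_multiplier(2.0 * snap / k_pc, geo, geo.T, pf,
                             crop_to=(geo.ns, geo.nz))


def simulate_measurement(p0: np.ndarray, geo: GeometryConfig, k_pc: float = 1.0,
                         noise_sd: float = 0.0, seed: int = 0,
                         pad_factor=2, crop: bool = False) -> np.ndarray:
    """Full measurement model: project, propagate to time ``T``, convert to
    phase contrast, add white Gaussian camera noise.

    By default the snapshots are returned on the padded camera grid
    (``crop=False``) so that back propagation sees the entire wave pattern.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    sino0 = radon_forward(p0, geo)
    snap = to_phase_contrast(
        forward_propagate(sino0, geo, pad_factor=pad_factor, crop=crop), k_pc
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        snap = snap + rng.normal(0.0, noise_sd, size=snap.shape)
    return snap
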