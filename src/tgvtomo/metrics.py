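"""Evaluation quantities: PSNR, SSIM, maximum amplitude projections,
volume statistics, and the angular-sampling resolution relation."""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

_AXES = {"x": 0, "y": 1, "z": 2}


def psnr(x: np.ndarray, ref: np.ndarray, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB: ``10 log10(peak^2 / MSE)``.

    ``peak`` defaults to the maximum of the reference (ground-truth) volume.
    Identical inputs yield ``inf``.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {ref.shape}")
    if peak is None:
        peak = float(np.max(ref))
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak * peak / mse))


def ssim(x: np.ndarray, ref: np.ndarray, win_size: int = 7,
         volumetric: bool = False) -> float:
    """Mean structural similarity with the standard constants.

    By default computed slice-wise over z with a ``win_size x win_size``
    window and averaged; ``volumetric=True`` uses a 3D window instead.  The
    data range is taken from the reference volume.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {ref.shape}")
    data_range = float(np.ptp(ref))
    if data_range == 0:
        raise ValueError("reference volume is constant; SSIM undefined")
    if volumetric:
        return float(structural_similarity(ref, x, win_size=win_size,
                                           data_range=data_range))
    vals = [
        structural_similarity(ref[:, :, z], x[:, :, z], win_size=win_size,
                              data_range=data_range)
        for z in range(x.shape[2])
    ]
    return float(np.mean(vals))


def map_projection(p: np.ndarray, axis: str = "z") -> np.ndarray:
    """Maximum amplitude projection: pointwise maximum along one axis."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    return np.max(np.asarray(p, dtype=float), axis=_AXES[axis])


def volume_stats(p: np.ndarray, n_bins: int = 100):
    """Population mean, standard deviation, and histogram over all voxels.

    Returns ``(mean, std, (counts, bin_edges))`` with ``n_bins`` equal bins
    spanning ``[min, max]``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    p = np.asarray(p, dtype=float)
    counts, edges = np.histogram(p, bins=n_bins)
    return float(np.mean(p)), float(np.std(p)), (counts, edges)


def resolution_limit(delta_phi_deg: float, side_length: float) -> float:
    """Smallest resolvable feature for a given angular step.

    Inverts the Nyquist/Fourier-slice sampling relation
    ``delta_phi_max = 90 deg * Lambda_min / SL``:  a cube of side ``SL``
    sampled with angular step ``delta_phi`` resolves structures down to
    ``Lambda_min = delta_phi * SL / 90``.  Units follow ``side_length``.
    """
    if delta_phi_deg <= 0 or side_length <= 0:
        raise ValueError("delta_phi and side length must be positive")
    return delta_phi_deg * side_length / 90.0
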