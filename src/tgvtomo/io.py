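"""HDF5 / TIFF round-tripping of volumes, sinograms, and snapshot stacks.

HDF5 is the canonical interchange format: volumes are stored under the
dataset ``pressure``, sinograms under ``sinogram``, snapshot stacks under
``snapshots``, each with grid/acquisition attributes.  Multi-page TIFF export
is provided for visualization (volumes: z-pages; sinograms: angle-pages of
s x z images).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import GeometryConfig


def _write_attrs(dset, attrs: dict):
    for key, val in attrs.items():
        dset.attrs[key] = val


def save_volume(path, p: np.ndarray, geo: GeometryConfig | None = None,
                extra_attrs: dict | None = None):
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset("pressure", data=np.asarray(p, dtype=float))
        attrs = {"nx": p.shape[0], "nz": p.shape[2]}
        if geo is not None:
            attrs.update({"h": geo.h, "L": 1.0})
        _write_attrs(dset, {**attrs, **(extra_attrs or {})})


def load_volume(path) -> np.ndarray:
    with h5py.File(path, "r") as fh:
        return fh["pressure"][()]


def save_sinogram(path, f: np.ndarray, geo: GeometryConfig,
                  dataset: str = "sinogram", extra_attrs: dict | None = None):
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset(dataset, data=np.asarray(f, dtype=float))
        _write_attrs(dset, {
            "ns": f.shape[0], "n_angles": f.shape[1], "nz": f.shape[2],
            "angles": geo.angles, **(extra_attrs or {}),
        })


def load_sinogram(path, dataset: str = "sinogram") -> np.ndarray:
    with h5py.File(path, "r") as fh:
        return fh[dataset][()]


def save_snapshots(path, snap: np.ndarray, geo: GeometryConfig, k_pc: float,
                   extra_attrs: dict | None = None):
    save_sinogram(path, snap, geo, dataset="snapshots",
                  extra_attrs={"cs": geo.cs, "T": geo.T, "k_pc": k_pc,
                               **(extra_attrs or {})})


def load_snapshots(path) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as fh:
        dset = fh["snapshots"]
        return dset[()], float(dset.attrs.get("k_pc", 1.0))


def volume_to_tiff(path, p: np.ndarray):
    """z-pages of x-y images."""
    tifffile.imwrite(path, np.moveaxis(np.asarray(p, np.float32), 2, 0),
                     photometric="minisblack")


def volume_from_tiff(path) -> np.ndarray:
    return np.moveaxis(tifffile.imread(path).astype(float), 0, 2)


def sinogram_to_tiff(path, f: np.ndarray):
    """angle-pages of s-z images."""
    tifffile.imwrite(path, np.moveaxis(np.asarray(f, np.float32), 1, 0),
                     photometric="minisblack")


def sinogram_from_tiff(path) -> np.ndarray:
    return np.moveaxis(tifffile.imread(path).astype(float), 0, 1)


def resolve(path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    return path
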