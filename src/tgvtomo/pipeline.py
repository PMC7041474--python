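"""End-to-end orchestration: simulate -> back-propagate -> reconstruct ->
evaluate, driven by a structured (YAML/dict) configuration.

Stages are pure file-to-file maps; every artifact carries provenance
attributes (config hash, seed, package version).  A single experiment seed
fans out to per-stage seeds derived by hashing the stage name, so stages are
individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import io
from .fbp import fbp_reconstruct
from .geometry import GeometryConfig, SolverParams
from .metrics import psnr, ssim, volume_stats
from .phantoms import PhantomSpec, compose_default_phantom, make_hairloop_phantom
from .solver import reconstruct
from .wave import back_propagate, simulate_measurement

__version__ = "0.1.0"


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def subsample_angles(data: np.ndarray, factor: int) -> np.ndarray:
    """Keep every ``factor``-th angle (starting at index 0) of a sinogram or
    snapshot stack; the remaining angles stay uniform on [0, pi)."""
    data = np.asarray(data)
    n_ang = data.shape[1]
    if factor < 1 or n_ang % factor != 0:
        raise ValueError(f"factor {factor} does not divide {n_ang} angles")
    return data[:, ::factor, :]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _validate(config: dict):
    errors = []
    if "geometry" not in config:
        errors.append("geometry: missing section")
    else:
        for key in ("nx", "nz", "n_angles"):
            if key not in config["geometry"]:
                errors.append(f"geometry.{key}: required")
    for entry in config.get("reconstruct", []):
        method = entry.get("method")
        if method not in ("tgv", "tv", "fbp"):
            errors.append(f"reconstruct[].method: unknown method {method!r}")
        if method in ("tgv", "tv") and "mu" not in entry:
            errors.append(f"reconstruct[].mu: required for {method}")
    if errors:
        raise ValueError("invalid experiment config:\n  " + "\n  ".join(errors))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_experiment(config: dict, out_dir) -> dict:
    """Run the configured pipeline; returns the manifest (also written to
    ``out_dir/manifest.json``)."""
    _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    chash = _config_hash(config)
    prov = {"config_hash": chash, "seed": seed, "version": __version__}
    manifest = {"config": config, **prov, "artifacts": {}, "metrics": {}}

    geo = GeometryConfig(**config["geometry"])

    # phantom ------------------------------------------------------------
    ph_cfg = dict(config.get("phantom", {}))
    kind = ph_cfg.pop("kind", "default")
    ph_seed = stage_seed(seed, "phantom")
    if kind == "default":
        spec = PhantomSpec(**{"seed": ph_seed, **ph_cfg})
        truth = compose_default_phantom(spec)
    elif kind == "hairloop":
        truth = make_hairloop_phantom(ph_cfg.pop("shape", geo.volume_shape),
                                      seed=ph_seed, **ph_cfg)
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    if truth.shape != geo.volume_shape:
        raise ValueError(
            f"phantom shape {truth.shape} != geometry {geo.volume_shape}"
        )
    io.save_volume(out / "phantom.h5", truth, geo, extra_attrs=prov)
    manifest["artifacts"]["phantom"] = "phantom.h5"

    # simulate + back-propagate -----------------------------------------
    sim = dict(config.get("simulate", {}))
    k_pc = float(sim.get("k_pc", 1.0))
    snap = simulate_measurement(
        truth, geo, k_pc=k_pc, noise_sd=float(sim.get("noise_sd", 0.0)),
        seed=stage_seed(seed, "simulate"),
        pad_factor=sim.get("pad_factor", 2),
    )
    io.save_snapshots(out / "snapshots.h5", snap, geo, k_pc, extra_attrs=prov)
    manifest["artifacts"]["snapshots"] = "snapshots.h5"

    factor = int(config.get("subsample", {}).get("factor", 1))
    snap_used = subsample_angles(snap, factor)
    geo_used = geo.subsample_angles(factor)
    sino = back_propagate(snap_used, geo_used, k_pc=k_pc)
    io.save_sinogram(out / "sinogram.h5", sino, geo_used, extra_attrs=prov)
    manifest["artifacts"]["sinogram"] = "sinogram.h5"
    manifest["n_angles_used"] = geo_used.n_angles

    # reconstructions ----------------------------------------------------
    wanted = set(config.get("metrics", []))
    for entry in config.get("reconstruct", []):
        method = entry["method"]
        name = entry.get("name", method)
        if method == "fbp":
            recon = fbp_reconstruct(sino, geo_used,
                                    filter=entry.get("filter", "ram-lak"),
                                    interp=entry.get("interp", "linear"))
        else:
            params = SolverParams(
                mu=float(entry["mu"]), n_iter=int(entry.get("n_iter", 1000)),
                alpha0=float(entry.get("alpha0", 2.5)),
                alpha1=float(entry.get("alpha1", 1.0)), regularizer=method,
            )
            recon, _ = reconstruct(sino, geo_used, params)
        fname = f"recon_{name}.h5"
        io.save_volume(out / fname, recon, geo, extra_attrs=prov)
        manifest["artifacts"][f"recon_{name}"] = fname
        report = {}
        if "psnr" in wanted:
            report["psnr"] = psnr(recon, truth)
        if "ssim" in wanted:
            report["ssim"] = ssim(recon, truth)
        if "stats" in wanted:
            mean, std, _ = volume_stats(recon)
            report.update(mean=mean, std=std)
        manifest["metrics"][name] = report

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
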