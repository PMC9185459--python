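"""Serialization: dielectric maps, scattering datasets, reconstruction
results and configuration files.

Arrays travel in npz containers with a JSON metadata string embedded, so
a write-then-read round trip is lossless at full floating precision.
Every grid quantity can also be exported as CSV (row-major, with the
domain extent and pixel count in a header comment).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .forward import AntennaArray, ScatteringDataset
from .grids import ImagingGrid, build_grid
from .inverse import ReconstructionResult
from .medium import BackgroundMedium
from .phantoms import PhantomMap

__all__ = [
    "save_phantom", "load_phantom",
    "save_dataset", "load_dataset", "dataset_to_csv",
    "save_result", "load_result",
    "grid_to_csv", "load_config", "save_config", "config_hash",
]

PathLike = Union[str, Path]


def _meta(obj: dict) -> str:
    return json.dumps(obj, sort_keys=True)


def save_phantom(phantom: PhantomMap, path: PathLike) -> None:
    meta = dict(phantom.meta)
    meta.update({"extent": phantom.grid.extent, "pixels": phantom.grid.pixels})
    np.savez(
        path,
        eps_r=phantom.eps_r,
        sigma=phantom.sigma,
        labels=phantom.labels if phantom.labels is not None else np.array([]),
        __meta__=_meta(meta),
    )


def load_phantom(path: PathLike) -> PhantomMap:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        grid = build_grid(meta.pop("extent"), meta.pop("pixels"))
        labels = data["labels"] if data["labels"].size else None
        return PhantomMap(grid, data["eps_r"], data["sigma"], labels, meta=meta)


def save_dataset(dataset: ScatteringDataset, path: PathLike) -> None:
    meta = {
        "n_sources": dataset.array.n_sources,
        "n_receivers": dataset.array.n_receivers,
        "radius": dataset.array.radius,
        "receiver_angle_offset": dataset.array.receiver_angle_offset,
        "eps_rb": dataset.medium.eps_rb,
        "sigma_b": dataset.medium.sigma_b,
        "noise": dataset.noise,
    }
    np.savez(
        path,
        re=dataset.data.real,
        im=dataset.data.imag,
        frequencies=dataset.medium.frequencies,
        __meta__=_meta(meta),
    )


def load_dataset(path: PathLike) -> ScatteringDataset:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        array = AntennaArray(
            meta["n_sources"], meta["n_receivers"], meta["radius"],
            meta.get("receiver_angle_offset", 0.0),
        )
        medium = BackgroundMedium(meta["eps_rb"], meta["sigma_b"],
                                  data["frequencies"])
        return ScatteringDataset(
            data["re"] + 1j * data["im"], array, medium,
            noise=meta.get("noise", {}),
        )


def dataset_to_csv(dataset: ScatteringDataset, path: PathLike) -> None:
    """Flat export: freq_hz, source_idx, receiver_idx, re, im."""
    f, l, q = np.meshgrid(
        dataset.medium.frequencies,
        np.arange(dataset.n_sources),
        np.arange(dataset.n_receivers),
        indexing="ij",
    )
    flat = np.column_stack([
        f.ravel(), l.ravel(), q.ravel(),
        dataset.data.real.ravel(), dataset.data.imag.ravel(),
    ])
    np.savetxt(
        path, flat, delimiter=",",
        header="freq_hz,source_idx,receiver_idx,re,im", comments="",
        fmt=["%.10g", "%d", "%d", "%.17g", "%.17g"],
    )


def grid_to_csv(grid: ImagingGrid, values: np.ndarray, path: PathLike) -> None:
    np.savetxt(
        path, grid.reshape(values), delimiter=",",
        header=f"extent={grid.extent} pixels={grid.pixels} row-major, "
               "row 0 = bottom",
        fmt="%.17g",
    )


def save_result(result: ReconstructionResult, path: PathLike) -> None:
    meta = {
        "extent": result.grid.extent,
        "pixels": result.grid.pixels,
        "residuals": result.residuals,
        "initial_residual": result.initial_residual,
        "config": result.config,
    }
    chis = np.stack(result.chi_per_iteration)
    np.savez(
        path,
        chi_re=chis.real, chi_im=chis.imag,
        eps_r=result.eps_r, sigma=result.sigma,
        __meta__=_meta(meta),
    )


def load_result(path: PathLike) -> ReconstructionResult:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        grid = build_grid(meta["extent"], meta["pixels"])
        chis = data["chi_re"] + 1j * data["chi_im"]
        return ReconstructionResult(
            grid=grid,
            chi_per_iteration=[c for c in chis],
            residuals=meta["residuals"],
            initial_residual=meta["initial_residual"],
            eps_r=data["eps_r"],
            sigma=data["sigma"],
            config=meta["config"],
        )


def load_config(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
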