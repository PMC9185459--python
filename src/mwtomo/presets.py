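"""Canonical experiment configurations.

``circular_validation_config`` and ``breast_sweep_config`` carry the
published measurement setup: an 18 x 18 cm domain in an eps_rb = 10
background, 18 line sources on a 10 cm circle, scattered fields sampled
at 15 equispaced frequencies from 600 kHz to 600 MHz, data simulated on
a 150 x 150 grid and inverted on a 64 x 64 grid (10 BIM iterations for
the circular model, 5 for the breast sweep).  The circular model samples
30 receiver positions; the breast sweep uses the 18-receiver ring.

The ``reduced_*`` variants are desk-scale protocols for quick end-to-end
runs on one CPU: smaller inversion grids and, for the sweep, a thinner
source/frequency stack and a 64 x 64 simulation grid.  They change
problem sizes only, never the physics or the phantom definitions.
"""

from __future__ import annotations

import copy

from .medium import SWEEP_F_MAX_HZ, SWEEP_F_MIN_HZ
from .phantoms import TUMOR_DIAMETERS_M, TUMOR_POSITIONS_M

__all__ = [
    "circular_validation_config",
    "reduced_circular_config",
    "breast_sweep_config",
    "reduced_sweep_config",
    "sweep_phantom_specs",
]


def circular_validation_config() -> dict:
    """Concentric-circle model at the published settings."""
    return {
        "seed": 0,
        "grid": {"extent": 0.18, "fine_pixels": 150, "inversion_pixels": 64},
        "array": {"n_sources": 18, "n_receivers": 30, "radius": 0.10},
        "medium": {"eps_rb": 10.0, "sigma_b": 0.0},
        "frequencies": {
            "f_min": SWEEP_F_MIN_HZ, "f_max": SWEEP_F_MAX_HZ, "count": 15,
        },
        "phantom": {"kind": "circular", "tumor_center": [0.0, 0.015]},
        "solver": {
            "iterations": 10,
            "lambda": None,
            "init": "multi_freq_source",
            "eps_range": [2.5, 67.0],
            "sigma_max": 4.0,
        },
        "noise": {"snr_db": None},
        "refiner": {"checkpoint": None},
    }


def reduced_circular_config() -> dict:
    """Circular model with the inversion grid reduced to 32 x 32."""
    cfg = circular_validation_config()
    cfg["grid"]["inversion_pixels"] = 32
    return cfg


def breast_sweep_config() -> dict:
    """Breast-class sweep protocol at the published settings."""
    cfg = circular_validation_config()
    cfg["array"]["n_receivers"] = 18
    cfg["solver"]["iterations"] = 5
    cfg["solver"]["init"] = "constant_min"
    cfg["phantom"] = {
        "kind": "breast", "class_id": 1, "seed": 0,
        "tumor_diameter": 0.005, "tumor_center": [0.0, 0.0],
    }
    return cfg


def reduced_sweep_config() -> dict:
    """Desk-scale breast sweep: 64 x 64 simulation grid, 24 x 24
    inversion grid, 8 sources, 5 frequencies."""
    cfg = breast_sweep_config()
    cfg["grid"]["fine_pixels"] = 64
    cfg["grid"]["inversion_pixels"] = 24
    cfg["array"]["n_sources"] = 8
    cfg["frequencies"]["count"] = 5
    cfg["refiner"] = {
        "checkpoint": None,
        "depth": 3,
        "base_channels": 16,
        "epochs": 150,
        "learning_rate": 1e-3,
        "batch_size": 16,
        "split_fraction": 0.9,
    }
    return cfg


def sweep_phantom_specs(seed: int = 0) -> list[dict]:
    """The deterministic 108-phantom sweep: 4 classes x 3 tumor
    diameters x 9 tumor positions, in fixed nested order."""
    specs = []
    for class_id in (1, 2, 3, 4):
        for diameter in TUMOR_DIAMETERS_M:
            for center in TUMOR_POSITIONS_M:
                specs.append({
                    "class_id": class_id,
                    "tumor_diameter": diameter,
                    "tumor_center": list(center),
                    "seed": int(seed),
                })
    return specs


def apply_phantom_spec(config: dict, spec: dict) -> dict:
    """A copy of ``config`` with its phantom section set from a sweep spec."""
    cfg = copy.deepcopy(config)
    cfg["phantom"] = {"kind": "breast", **spec}
    return cfg
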