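"""Quantitative evaluation of reconstructions.

The headline figure of merit is the Frobenius-norm relative error

    Re = (1/Nt) * sum_j ||eps_true_j - eps_est_j||_F / ||eps_true_j||_F

averaged over Nt test images, with accuracy reported as 100*(1 - Re) %.
A linear tissue model sigma(eps_r) = 0.019 eps_r - 0.047 recovers the
conductivity map from a retrieved permittivity map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ErrorReport",
    "ConductivityModel",
    "relative_error",
    "conductivity_from_permittivity",
]


@dataclass(frozen=True)
class ErrorReport:
    """Relative-error summary over a batch of test images."""

    per_test: np.ndarray

    def __post_init__(self) -> None:
        pt = np.atleast_1d(np.asarray(self.per_test, dtype=float))
        if pt.size == 0:
            raise ValueError("at least one test is required")
        pt.setflags(write=False)
        object.__setattr__(self, "per_test", pt)

    @property
    def n_tests(self) -> int:
        return self.per_test.size

    @property
    def relative_error(self) -> float:
        """Mean Frobenius relative error over the batch (dimensionless)."""
        return float(np.mean(self.per_test))

    @property
    def accuracy_percent(self) -> float:
        """100 * (1 - Re); pairs with the relative error by construction."""
        return 100.0 * (1.0 - self.relative_error)

    def as_dict(self) -> dict:
        return {
            "relative_error": self.relative_error,
            "accuracy_percent": self.accuracy_percent,
            "n_tests": self.n_tests,
            "per_test": self.per_test.tolist(),
        }


def relative_error(
    truth_maps: Sequence[np.ndarray],
    estimate_maps: Sequence[np.ndarray],
) -> ErrorReport:
    """Frobenius relative error averaged over paired truth/estimate maps.

    Raises
    ------
    ValueError
        On length/shape mismatch or an all-zero truth map (undefined ratio).
    """
    truth_maps = [np.asarray(t, dtype=float) for t in truth_maps]
    estimate_maps = [np.asarray(e, dtype=float) for e in estimate_maps]
    if len(truth_maps) != len(estimate_maps):
        raise ValueError("truth and estimate lists must have equal length")
    errs = []
    for t, e in zip(truth_maps, estimate_maps):
        if t.shape != e.shape:
            raise ValueError(f"shape mismatch: {t.shape} vs {e.shape}")
        denom = np.linalg.norm(t)
        if denom == 0:
            raise ValueError("all-zero truth map: relative error undefined")
        errs.append(np.linalg.norm(t - e) / denom)
    return ErrorReport(np.asarray(errs))


@dataclass(frozen=True)
class ConductivityModel:
    """Linear permittivity-to-conductivity tissue model (S/m)."""

    slope: float = 0.019
    intercept: float = -0.047

    def __call__(self, eps_r: np.ndarray) -> np.ndarray:
        sigma = self.slope * np.asarray(eps_r, dtype=float) + self.intercept
        return np.maximum(sigma, 0.0)


def conductivity_from_permittivity(eps_r: np.ndarray) -> np.ndarray:
    """sigma = 0.019 * eps_r - 0.047 (S/m), floored at 0.

    The floor only engages below eps_r ~ 2.47, just under the assumed
    tissue range, so it is almost never active.
    """
    return ConductivityModel()(eps_r)
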