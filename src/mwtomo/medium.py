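"""Homogeneous background medium and the frequency sweep.

The background is a lossless or lossy non-magnetic dielectric with relative
permittivity ``eps_rb`` and conductivity ``sigma_b``.  Per-frequency angular
frequencies and background wavenumbers k_b = omega * sqrt(eps_b * mu0) are
precomputed for the whole sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.constants import epsilon_0, mu_0, speed_of_light

__all__ = ["BackgroundMedium", "default_frequency_sweep"]

# Printed measurement band: 15 equispaced frequencies, 600 kHz to 600 MHz.
SWEEP_F_MIN_HZ = 600e3
SWEEP_F_MAX_HZ = 600e6
SWEEP_N_FREQ = 15


def default_frequency_sweep(n_freq: int = SWEEP_N_FREQ) -> np.ndarray:
    """Equispaced frequency list over the default measurement band (Hz)."""
    return np.linspace(SWEEP_F_MIN_HZ, SWEEP_F_MAX_HZ, n_freq)


@dataclass(frozen=True)
class BackgroundMedium:
    """Homogeneous background with an attached frequency list.

    Attributes
    ----------
    eps_rb : float
        Background relative permittivity (dimensionless).
    sigma_b : float
        Background conductivity (S/m); 0 for a lossless background.
    frequencies : ndarray
        Frequencies of the measurement sweep (Hz), positive and distinct.
    """

    eps_rb: float
    sigma_b: float = 0.0
    frequencies: np.ndarray = field(default_factory=default_frequency_sweep)

    def __post_init__(self) -> None:
        freqs = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        if freqs.size < 1:
            raise ValueError("at least one frequency is required")
        if np.any(freqs <= 0):
            raise ValueError("all frequencies must be positive")
        if np.unique(freqs).size != freqs.size:
            raise ValueError("frequencies must be distinct")
        freqs.setflags(write=False)
        object.__setattr__(self, "frequencies", freqs)
        if self.eps_rb < 1:
            raise ValueError("background relative permittivity must be >= 1")

    @property
    def n_freq(self) -> int:
        return self.frequencies.size

    @property
    def eps_b(self) -> float:
        """Absolute background permittivity (F/m)."""
        return self.eps_rb * epsilon_0

    @property
    def mu0(self) -> float:
        return mu_0

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies (rad/s)."""
        return 2.0 * np.pi * self.frequencies

    @property
    def k_b(self) -> np.ndarray:
        """Background wavenumbers k_b = omega*sqrt(eps_b*mu0) (1/m)."""
        return self.omega * np.sqrt(self.eps_b * mu_0)

    def wavelength(self, frequency_index: int = -1) -> float:
        """Background wavelength at one frequency of the sweep (m)."""
        f = self.frequencies[frequency_index]
        return speed_of_light / (f * np.sqrt(self.eps_rb))

    def replace_frequencies(self, frequencies: Sequence[float]) -> "BackgroundMedium":
        return BackgroundMedium(self.eps_rb, self.sigma_b, np.asarray(frequencies, float))
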