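"""Simulate multi-source, multi-frequency scattering from the
concentric-circle phantom.

Builds the validation phantom (8 cm disc of eps_r 40 holding a 6 cm disc
of eps_r 4.5 and a 1 cm tumor of eps_r 57, immersed in an eps_r 10
background), illuminates it with line sources on a 10 cm ring, and
samples the scattered field at ring receivers over the measurement band.
"""

import numpy as np

from mwtomo import (
    AntennaArray,
    BackgroundMedium,
    build_grid,
    circular_phantom,
    simulate_dataset,
)

grid = build_grid(0.18, 64)            # 18 cm domain, 64 x 64 simulation cells
phantom = circular_phantom(grid)
medium = BackgroundMedium(10.0, frequencies=np.linspace(600e3, 600e6, 15))
array = AntennaArray(n_sources=18, n_receivers=30, radius=0.10)

dataset = simulate_dataset(phantom, array, medium)

print(f"dataset shape (F, L, Nr): {dataset.data.shape}")
mags = np.abs(dataset.data)
for f in (0, 7, 14):
    print(f"  f = {medium.frequencies[f]/1e6:7.1f} MHz   "
          f"mean |Es| = {mags[f].mean():.3e}")
print(
    "Scattering grows with frequency: at 600 kHz the domain is a tiny\n"
    "fraction of a wavelength and the phantom is nearly invisible, while\n"
    "at 600 MHz the 18 cm domain spans about one background wavelength."
)
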