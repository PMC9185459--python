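"""Reconstruct the concentric-circle phantom with the quadratic-programming
Born iterative method.

Data are simulated on a finer grid than the inversion grid (avoiding the
inverse crime) and inverted by alternating total-field solves with
Tikhonov-regularized QP contrast updates.  Prints the per-iteration data
residual and the final Frobenius relative error against the true map.
This desk-scale setup (64 x 64 simulation, 24 x 24 inversion, 8 sources)
runs in about a minute; the published protocol uses 150 x 150 / 64 x 64
grids with 18 sources and 10 iterations.
"""

import numpy as np

from mwtomo import (
    AntennaArray,
    BackgroundMedium,
    BIMConfig,
    bim_reconstruct,
    build_grid,
    circular_phantom,
    relative_error,
    simulate_dataset,
)

medium = BackgroundMedium(10.0, frequencies=np.linspace(600e3, 600e6, 8))
array = AntennaArray(n_sources=8, n_receivers=30, radius=0.10)
fine = build_grid(0.18, 64)
dataset = simulate_dataset(circular_phantom(fine), array, medium,
                           inversion_pixels=24)

inv_grid = build_grid(0.18, 24)
result = bim_reconstruct(dataset, inv_grid,
                         BIMConfig(iterations=6, init_mode="multi_freq_source"))

print("data residual per iteration:")
for k, r in enumerate(result.residuals, 1):
    print(f"  iteration {k}: {r:.3f}")

truth = circular_phantom(inv_grid)
report = relative_error([truth.eps_image()], [result.eps_image()])
print(f"\nFrobenius relative error: {report.relative_error:.3f} "
      f"({100 * report.relative_error:.1f}%)")
print(
    "The residual falls as the linearisation is re-centred each iteration;\n"
    "the remaining error reflects the strong (chi = 3) outer disc, which a\n"
    "Born-type linearisation can only partially resolve."
)
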