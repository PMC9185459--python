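"""Train the encoder-decoder refiner on a miniature phantom sweep.

BIM reconstructions of strong scatterers are blurry and biased; the
U-Net learns the mapping from reconstructed to true permittivity maps.
This miniature demonstration uses a 12-phantom sweep at small problem
sizes and a short training run; the full protocol reconstructs all 108
sweep phantoms and trains longer.
"""

import warnings

import numpy as np

from mwtomo import RefinerConfig, build_refiner, refine, relative_error, train
from mwtomo.pipeline import reconstruct_sweep_pair
from mwtomo.presets import reduced_sweep_config
from mwtomo.refine import TrainingPair, split_pairs

warnings.filterwarnings("ignore")

config = reduced_sweep_config()
config["grid"]["fine_pixels"] = 48
config["grid"]["inversion_pixels"] = 16
config["frequencies"]["count"] = 4

specs = [
    {"class_id": c, "tumor_diameter": d, "tumor_center": [0.0, 0.0], "seed": 0}
    for c in (1, 2, 3, 4) for d in (0.003, 0.005, 0.008)
]
print(f"reconstructing {len(specs)} phantoms ...")
pairs = [TrainingPair(*reconstruct_sweep_pair(s, config), provenance=s)
         for s in specs]

rcfg = RefinerConfig(input_size=16, depth=3, base_channels=8, epochs=150,
                     seed=0, batch_size=4, split_fraction=0.75,
                     learning_rate=3e-3)
model = build_refiner(rcfg)
history = train(model, pairs, rcfg)
print(f"train loss: {history['train_loss'][0]:.4f} -> "
      f"{history['train_loss'][-1]:.4f}")

_, val = split_pairs(pairs, rcfg.split_fraction, rcfg.seed)
raw = relative_error([p.target for p in val], [p.input for p in val])
ref = relative_error([p.target for p in val],
                     [refine(model, p.input) for p in val])
print(f"held-out BIM-only error:  {raw.relative_error:.3f} "
      f"(accuracy {raw.accuracy_percent:.1f}%)")
print(f"held-out refined error:   {ref.relative_error:.3f} "
      f"(accuracy {ref.accuracy_percent:.1f}%)")
print(
    "The network recovers the sharp skin/fat/gland structure that the\n"
    "linearised inversion blurs, cutting the Frobenius error of held-out\n"
    "reconstructions."
)
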