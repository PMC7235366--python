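"""Generate the reference synthetic image set and inspect its structure.

Builds 10 balanced classes of 16x16 RGB images from seeded low-frequency
templates plus jitter and pixel noise, then shows the class balance, the
pixel range, and how separable the classes are for a nearest-template
classifier at increasing noise.
"""

import numpy as np

from repnonuniq import SyntheticImageConfig, generate_train_test
from repnonuniq.synthdata import class_templates, generate_dataset

cfg = SyntheticImageConfig(seed=1)
train, test = generate_train_test(cfg)
print(f"train: {train.images.shape}, test: {test.images.shape}")
print(f"labels per class (train): {np.bincount(train.labels)}")
print(f"pixel range: [{train.images.min():.3f}, {train.images.max():.3f}]")

print("\nnearest-template accuracy vs generation noise:")
for sd in (0.05, 0.3, 0.8):
    noisy_cfg = SyntheticImageConfig(seed=1, pixel_noise_sd=sd, jitter_pixels=0)
    data = generate_dataset(noisy_cfg, "test")
    T = class_templates(noisy_cfg).reshape(noisy_cfg.num_classes, -1)
    X = data.images.reshape(len(data), -1)
    acc = np.mean(((X[:, None] - T[None]) ** 2).sum(-1).argmin(1) == data.labels)
    print(f"  sd={sd:.2f}: {acc:.3f}")
# High accuracy at low noise confirms the class structure is strong
# enough for a small CNN to reach ceiling within a few epochs.
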