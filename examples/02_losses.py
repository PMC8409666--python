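"""The three training losses on a toy prediction.

Bootstrapped cross-entropy averages only the K hardest voxels (largest
per-voxel losses), so it sits above the plain mean cross-entropy and
decreases as K grows.
"""

import numpy as np

from gadseg import bootstrapped_ce, cross_entropy_loss, dice_loss

rng = np.random.default_rng(0)
target = (rng.random(1000) < 0.05).astype(float)      # sparse lesion voxels
pred = np.clip(target * 0.7 + rng.uniform(0.01, 0.25, 1000), 0.01, 0.99)

print(f"Dice loss:          {dice_loss(target, pred):.4f}")
print(f"cross-entropy:      {cross_entropy_loss(target, pred):.4f}")
for k in (10, 100, 1000):
    print(f"bootstrapped CE K={k:<5d} {bootstrapped_ce(target, pred, k):.4f}")
print("-> smaller K focuses on the hardest voxels and gives a larger loss")
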