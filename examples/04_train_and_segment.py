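"""Train a tiny network on a small phantom cohort and segment a held-out scan.

Desk-scale counterpart of the clinical training run: tiny widths, Dice
loss, a few epochs on CPU.  Takes roughly half a minute.
"""

import warnings

warnings.filterwarnings("ignore", message="volume shape")

from gadseg import TrainConfig, dice_3d, train
from gadseg.pipeline import default_desk_spec, simulate_cohort

phantoms = simulate_cohort(8, default_desk_spec(0), seed=0)
cfg = TrainConfig.desk_scale(seed=0)
result = train([p.stack for p in phantoms[:6]],
               [p.stack for p in phantoms[6:7]], cfg)
print(result.log.to_string(index=False))

held = phantoms[7]
pred = result.segment(held.stack)
print(f"\nheld-out scan 3D Dice: {dice_3d(pred, held.mask):.3f}")
print("-> the probability map, binarized at 0.5, against the ground truth mask")
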