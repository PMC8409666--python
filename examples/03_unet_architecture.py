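"""Architecture accounting for the slice-wise segmentation network.

The default network takes a 10-channel 256x256 slice through five encoder
depths (32..512 filters), a parameter-free upsampling decoder with skip
concatenation, and a 1x1 sigmoid head.
"""

import numpy as np

from gadseg import UNetSpec, build_unet, count_parameters

spec = UNetSpec()  # 10 input channels
print(f"closed-form parameter count: {count_parameters(spec):,}")
net = build_unet(spec)
print(f"built-model parameter count: {net.n_parameters():,}")
print(f"≈ {net.n_parameters() / 1e6:.1f} million trainable parameters")

tiny = UNetSpec.tiny()
x = np.random.default_rng(0).normal(size=(1, 10, 64, 64)).astype(np.float32)
p = build_unet(tiny).forward(x)
print(f"\ntiny desk-scale variant: {count_parameters(tiny):,} parameters; "
      f"64x64 slice -> probability map {p.shape}, range "
      f"({p.min():.3f}, {p.max():.3f})")
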