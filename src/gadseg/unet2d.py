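"""2D encoder-decoder segmentation network (U-Net) specification and builder.

The default architecture takes a 10-channel 2D slice and produces a
voxelwise lesion-probability map of the same spatial size:

* encoder: five depths with 32, 64, 128, 256, 512 filters; each depth is
  two 3x3 convolutions, each followed by batch normalization and ReLU;
  2x2 max pooling between depths (the 512 stage is the bottleneck);
* decoder: four stages of non-learned 2x2 upsampling, concatenation with
  the matching encoder skip, then two 3x3 conv+BN+ReLU blocks at the
  skip's filter width (256, 128, 64, 32);
* head: 1x1 convolution to one channel plus sigmoid.

With 10 input channels this totals 7,854,561 trainable parameters
(~7.8-7.9 million).  The decoder's nominal filter list (512, 256, 128,
64, 32) reads the 512 entry as the bottleneck output entering the decoder
path; a learned (transposed-convolution) upsampling would not reproduce
that parameter total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from ._nn import Adam, BatchNorm2d, Conv2d, Layer, MaxPool2, Param, ReLU, Upsample2, sigmoid


@dataclass(frozen=True)
class UNetSpec:
    """Declarative architecture: everything needed to build and count."""

    in_channels: int = 10
    encoder_filters: tuple[int, ...] = (32, 64, 128, 256, 512)
    convs_per_depth: int = 2
    kernel: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if len(self.encoder_filters) < 2:
            raise ValueError("need at least two depths")

    @property
    def depths(self) -> int:
        return len(self.encoder_filters)

    @property
    def decoder_filters(self) -> tuple[int, ...]:
        """Bottleneck width followed by the per-stage decoder conv widths."""
        return tuple(reversed(self.encoder_filters))

    @property
    def pool_factor(self) -> int:
        return 2 ** (self.depths - 1)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "UNetSpec":
        d = yaml.safe_load(text)
        d["encoder_filters"] = tuple(d["encoder_filters"])
        return cls(**d)

    @classmethod
    def tiny(cls, in_channels: int = 10, seed: int = 0) -> "UNetSpec":
        """Desk-scale width for CPU training on small phantoms."""
        return cls(in_channels=in_channels, encoder_filters=(8, 16, 32, 64, 128),
                   seed=seed)


def count_parameters(spec: UNetSpec) -> int:
    """Closed-form trainable-parameter count for a spec.

    Convolutions contribute k*k*c_in*c_out weights + c_out biases; each is
    followed by a batch norm contributing 2*c_out (scale and shift; running
    statistics are not trainable).  The 1x1 head contributes c*1 + 1.
    """
    k2 = spec.kernel * spec.kernel
    total = 0

    def block(c_in: int, c_out: int) -> int:
        per = 0
        c = c_in
        for _ in range(spec.convs_per_depth):
            per += k2 * c * c_out + c_out + 2 * c_out
            c = c_out
        return per

    c_prev = spec.in_channels
    for f in spec.encoder_filters:
        total += block(c_prev, f)
        c_prev = f
    enc = spec.encoder_filters
    c_prev = enc[-1]
    for f in reversed(enc[:-1]):
        total += block(c_prev + f, f)  # upsampled path concat skip
        c_prev = f
    total += enc[0] * 1 + 1  # 1x1 sigmoid head
    return total


class _ConvBlock:
    """convs_per_depth x (conv 3x3 -> BN -> ReLU)."""

    def __init__(self, c_in: int, c_out: int, spec: UNetSpec, rng: np.random.Generator):
        self.layers: list[Layer] = []
        c = c_in
        for _ in range(spec.convs_per_depth):
            self.layers += [Conv2d(c, c_out, spec.kernel, rng), BatchNorm2d(c_out), ReLU()]
            c = c_out

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def params(self):
        return [p for l in self.layers for p in l.params()]


class UNet2D:
    """Trainable image-to-probability-map function (NCHW in, N1HW out)."""

    def __init__(self, spec: UNetSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        enc = spec.encoder_filters
        self.enc_blocks = []
        c = spec.in_channels
        for f in enc:
            self.enc_blocks.append(_ConvBlock(c, f, spec, rng))
            c = f
        self.pools = [MaxPool2() for _ in enc[:-1]]
        self.ups = [Upsample2() for _ in enc[:-1]]
        self.dec_blocks = []
        c = enc[-1]
        for f in reversed(enc[:-1]):
            self.dec_blocks.append(_ConvBlock(c + f, f, spec, rng))
            c = f
        self.head = Conv2d(enc[0], 1, 1, rng)
        self._skip_widths = tuple(reversed(enc[:-1]))

    # -- parameter access ---------------------------------------------------
    def params(self) -> list[Param]:
        ps = []
        for b in self.enc_blocks:
            ps += b.params()
        for b in self.dec_blocks:
            ps += b.params()
        ps += self.head.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.val.size for p in self.params()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.val for i, p in enumerate(self.params())}
        bns = [l for b in self.enc_blocks + self.dec_blocks for l in b.layers
               if isinstance(l, BatchNorm2d)]
        for i, bn in enumerate(bns):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.val[...] = state[f"param_{i}"]
        bns = [l for b in self.enc_blocks + self.dec_blocks for l in b.layers
               if isinstance(l, BatchNorm2d)]
        for i, bn in enumerate(bns):
            bn.running_mean = np.array(state[f"bn_{i}_mean"], dtype=np.float32)
            bn.running_var = np.array(state[f"bn_{i}_var"], dtype=np.float32)

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected (N,{self.spec.in_channels},H,W), got {x.shape}")
        f = self.spec.pool_factor
        if x.shape[2] % f or x.shape[3] % f:
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by {f}")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (N, C, H, W) to voxelwise probabilities (N, 1, H, W)."""
        x = np.asarray(x, dtype=np.float32)
        self._check_input(x)
        skips = []
        for i, block in enumerate(self.enc_blocks[:-1]):
            x = block.forward(x, train)
            skips.append(x)
            x = self.pools[i].forward(x, train)
        x = self.enc_blocks[-1].forward(x, train)
        self._skip_channels = []
        for i, block in enumerate(self.dec_blocks):
            x = self.ups[i].forward(x, train)
            skip = skips[-(i + 1)]
            self._skip_channels.append((x.shape[1], skip.shape[1]))
            x = np.concatenate([x, skip], axis=1)
            x = block.forward(x, train)
        z = self.head.forward(x, train)
        # strict (0,1): float32 sigmoid can otherwise round to exactly 0 or 1
        p = np.clip(sigmoid(z), 1e-7, 1.0 - 1e-7)
        if train:
            self._p = p
        return p

    def backward(self, dloss_dp: np.ndarray) -> None:
        """Accumulate parameter gradients given d(loss)/d(probability)."""
        dz = (dloss_dp * self._p * (1.0 - self._p)).astype(np.float32)
        dy = self.head.backward(dz)
        dskips = []
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            dy = self.dec_blocks[i].backward(dy)
            c_up, _ = self._skip_channels[i]
            dy, dskip = dy[:, :c_up], dy[:, c_up:]
            dskips.append(dskip)
            dy = self.ups[i].backward(dy)
        dy = self.enc_blocks[-1].backward(dy)
        dskips = dskips[::-1]  # dskips[i] pairs with enc block i (from deepest-1 up)
        for i in range(len(self.enc_blocks) - 2, -1, -1):
            dy = self.pools[i].backward(dy)
            dy = dy + dskips[len(self.dec_blocks) - 1 - i]
            dy = self.enc_blocks[i].backward(dy)

    def make_optimizer(self, lr: float = 1e-4, beta1: float = 0.5) -> Adam:
        return Adam(self.params(), lr=lr, beta1=beta1)


def build_unet(spec: UNetSpec) -> UNet2D:
    """Instantiate the network; deterministic given ``spec.seed``."""
    return UNet2D(spec)


def save_checkpoint(path, net: UNet2D) -> None:
    """Persist architecture spec + weights as an .npz checkpoint."""
    state = net.state_dict()
    state["__spec__"] = np.frombuffer(net.spec.to_yaml().encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> UNet2D:
    with np.load(path) as data:
        spec = UNetSpec.from_yaml(bytes(data["__spec__"]).decode())
        net = UNet2D(spec)
        net.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
    return net
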