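"""Training loop for the slice-wise segmentation network.

Batches are consecutive, non-overlapping runs of 2D slices within one scan
(never spanning scans).  Because enhancing lesions are spatially sparse,
batch sampling is lesion-balanced: every batch containing at least one
mask-positive voxel is used every epoch, while an all-empty batch is kept
independently with probability ``keep_empty_prob``.  Validation is the
mean 3D Dice over the validation scans (per-image Dice of restacked
slice predictions against the mask), and the checkpoint maximizing it is
returned.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .imgio import ContrastConfig, VolumeStack
from .losses import get_loss
from .metrics import dice_3d
from .unet2d import UNet2D, UNetSpec, build_unet


@dataclass
class TrainConfig:
    """Optimization settings.

    Clinical-scale defaults: batch size 16, Adam with momentum term 0.5 and
    learning rate 1e-4.  Desk-scale runs on small phantoms typically use
    :meth:`desk_scale` (tiny widths, a larger learning rate).
    """

    batch_size: int = 16
    lr: float = 1e-4
    beta1: float = 0.5
    loss: str = "bootstrap_ce"
    loss_params: dict = dc_field(default_factory=lambda: {"k": 3072})
    keep_empty_prob: float = 0.1
    epochs: int = 10
    seed: int = 0
    contrast_config: ContrastConfig = dc_field(default_factory=ContrastConfig.full)
    encoder_filters: tuple[int, ...] = (32, 64, 128, 256, 512)
    threshold: float = 0.5  # binarization of the sigmoid output downstream

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 <= self.keep_empty_prob <= 1.0):
            raise ValueError("keep_empty_prob must be in [0, 1]")

    def unet_spec(self) -> UNetSpec:
        return UNetSpec(in_channels=self.contrast_config.n_channels,
                        encoder_filters=self.encoder_filters, seed=self.seed)

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """Tiny-width configuration for CPU training on small phantoms."""
        kw = dict(loss="dice", loss_params={}, lr=3e-3, batch_size=4,
                  encoder_filters=(8, 16, 32, 64, 128), epochs=10)
        kw.update(overrides)
        return cls(**kw)


def _stack_input(stack: VolumeStack, channels: tuple[str, ...]) -> np.ndarray:
    """Reorder/select stack channels into model input order (C, S, H, W)."""
    idx = []
    for ch in channels:
        if ch not in stack.channels:
            raise ValueError(f"stack {stack.scan_id!r} lacks channel {ch!r}")
        idx.append(stack.channels.index(ch))
    return stack.data[idx]


def batch_stream(scans: list[VolumeStack], cfg: TrainConfig,
                 rng: np.random.Generator):
    """Yield one epoch of lesion-balanced training batches (x, y).

    x is (B, C, H, W), y is (B, 1, H, W).  Slice windows partition each
    scan (a trailing remainder shorter than the batch size is dropped);
    the emitted order is shuffled by ``rng``.
    """
    if not scans:
        raise ValueError("no training scans")
    windows = []
    for si, scan in enumerate(scans):
        if scan.mask is None:
            raise ValueError(f"scan {scan.scan_id!r} has no mask")
        if cfg.batch_size > scan.n_slices:
            raise ValueError(
                f"batch_size {cfg.batch_size} exceeds slice count {scan.n_slices}")
        for start in range(0, scan.n_slices - cfg.batch_size + 1, cfg.batch_size):
            has_lesion = bool(scan.mask[start:start + cfg.batch_size].any())
            windows.append((si, start, has_lesion))
    emitted = [w for w in windows
               if w[2] or rng.random() < cfg.keep_empty_prob]
    rng.shuffle(emitted)
    for si, start, _ in emitted:
        scan = scans[si]
        sl = slice(start, start + cfg.batch_size)
        x = np.moveaxis(_stack_input(scan, cfg.contrast_config.channels)[:, sl], 0, 1)
        y = scan.mask[sl][:, None].astype(np.float32)
        yield np.ascontiguousarray(x), y


@dataclass
class TrainResult:
    """Best-validation checkpoint, its config, and the per-epoch log."""

    net: UNet2D
    config: TrainConfig
    log: pd.DataFrame  # epoch, train_loss, val_dice
    best_val_dice: float

    def predict(self, stack: VolumeStack) -> np.ndarray:
        return predict_volume(self, stack)

    def segment(self, stack: VolumeStack) -> np.ndarray:
        """Binarized prediction at the configured threshold."""
        return (self.predict(stack) >= self.config.threshold).astype(np.uint8)


def predict_volume(result: TrainResult, stack: VolumeStack,
                   chunk: int = 16) -> np.ndarray:
    """Slice-wise inference restacked into a 3D probability map in (0, 1)."""
    x = _stack_input(stack, result.config.contrast_config.channels)
    net = result.net
    if x.shape[0] != net.spec.in_channels:
        raise ValueError("channel count does not match the trained model")
    n_slices = x.shape[1]
    out = np.empty(stack.spatial_shape, dtype=np.float32)
    for start in range(0, n_slices, chunk):
        batch = np.ascontiguousarray(np.moveaxis(x[:, start:start + chunk], 0, 1))
        out[start:start + chunk] = net.forward(batch, train=False)[:, 0]
    return out


def _validation_dice(net: UNet2D, cfg: TrainConfig,
                     val_scans: list[VolumeStack]) -> float:
    """Mean of per-image 3D Dice on binarized predictions."""
    dummy = TrainResult(net=net, config=cfg, log=pd.DataFrame(), best_val_dice=np.nan)
    vals = []
    for scan in val_scans:
        pred = (predict_volume(dummy, scan) >= cfg.threshold).astype(np.uint8)
        d = dice_3d(pred, scan.mask)
        if not np.isnan(d):
            vals.append(d)
    return float(np.mean(vals)) if vals else 0.0


def train(train_scans: list[VolumeStack], val_scans: list[VolumeStack],
          cfg: TrainConfig) -> TrainResult:
    """Train the network; deterministic given cfg.seed and thread count.

    Raises on an empty validation set and aborts with a diagnostic if the
    loss becomes non-finite.
    """
    if not val_scans:
        raise ValueError("validation set is empty")
    loss_fn, grad_fn = get_loss(cfg.loss, **cfg.loss_params)
    net = build_unet(cfg.unet_spec())
    opt = net.make_optimizer(lr=cfg.lr, beta1=cfg.beta1)
    rng = np.random.default_rng(cfg.seed)

    best_state, best_dice = None, -np.inf
    log_rows = []
    for epoch in range(1, cfg.epochs + 1):
        losses = []
        for x, y in batch_stream(train_scans, cfg, rng):
            p = net.forward(x, train=True)
            loss = loss_fn(y, p)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss {loss!r} at epoch {epoch}, "
                    f"step {len(losses) + 1}; lower the learning rate")
            opt.zero_grad()
            net.backward(grad_fn(y, p))
            opt.step()
            losses.append(loss)
        val_dice = _validation_dice(net, cfg, val_scans)
        log_rows.append({"epoch": epoch,
                         "train_loss": float(np.mean(losses)) if losses else np.nan,
                         "val_dice": val_dice})
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = copy.deepcopy(net.state_dict())
    if best_state is not None:
        net.load_state_dict(best_state)
    log = pd.DataFrame(log_rows, columns=["epoch", "train_loss", "val_dice"])
    return TrainResult(net=net, config=cfg, log=log, best_val_dice=float(best_dice))
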