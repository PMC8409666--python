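"""Volume I/O and multi-contrast channel stacking.

Volumes live on a fixed grid convention: array axis order is
``(channel, slice, row, column)`` with the slice axis being the thick
(nominally 3 mm) acquisition axis.  Voxel indices are 0-based and bounding
boxes are half-open ``[start, stop)``.  No resampling or registration is
performed here; inputs are assumed co-registered already.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import nibabel as nib
import numpy as np

#: The ten recognized channel identifiers: five MRI contrasts followed by
#: five tissue-probability maps (gray matter, white matter, CSF, lateral
#: ventricles, lesion prior).
MRI_CHANNELS = ("t1_post", "t1_pre", "flair", "t2", "pd")
PROBABILITY_CHANNELS = ("p_gm", "p_wm", "p_csf", "p_vent", "p_lesion")
ALL_CHANNELS = MRI_CHANNELS + PROBABILITY_CHANNELS

#: Nominal template-space grid: 64 slices of 256x256 at 1x1x3 mm.
NOMINAL_SHAPE = (64, 256, 256)
DEFAULT_SPACING = (3.0, 1.0, 1.0)  # slice, row, column (mm)


class ChannelMismatchError(ValueError):
    """A requested channel is missing or shaped inconsistently."""


@dataclass(frozen=True)
class ContrastConfig:
    """An ordered input-channel combination for the segmentation model.

    The five probability maps are normally appended to whatever subset of
    MRI contrasts an experiment uses, giving the 10/9/8/7/6/5-channel
    combinations explored in the input-ablation experiments.
    """

    name: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [c for c in self.channels if c not in ALL_CHANNELS]
        if unknown:
            raise ValueError(f"unknown channel(s): {unknown}")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channels in config")
        if not self.channels:
            raise ValueError("empty channel list")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @classmethod
    def full(cls) -> "ContrastConfig":
        """All five contrasts plus all five probability maps (10 channels)."""
        return cls("full_10ch", ALL_CHANNELS)

    @classmethod
    def from_contrasts(cls, contrasts: Sequence[str], name: str | None = None,
                       probability_maps: bool = True) -> "ContrastConfig":
        chans = tuple(contrasts) + (PROBABILITY_CHANNELS if probability_maps else ())
        return cls(name or "+".join(contrasts), chans)


@dataclass
class VolumeStack:
    """An ordered multi-channel 3D volume with optional lesion mask.

    ``data`` is (channel, slice, row, column); all channels share one grid.
    Probability-map channels are clipped to [0, 1] on construction.
    """

    channels: tuple[str, ...]
    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    mask: np.ndarray | None = None
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (C,S,R,Col), got {self.data.ndim}D")
        if self.data.shape[0] != len(self.channels):
            raise ChannelMismatchError(
                f"{len(self.channels)} channels declared, data has {self.data.shape[0]}")
        for i, ch in enumerate(self.channels):
            if ch in PROBABILITY_CHANNELS:
                np.clip(self.data[i], 0.0, 1.0, out=self.data[i])
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.spatial_shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != volume shape {self.spatial_shape}")
            self.mask = (self.mask > 0).astype(np.uint8)
        if self.spatial_shape != NOMINAL_SHAPE:
            warnings.warn(
                f"volume shape {self.spatial_shape} differs from nominal "
                f"{NOMINAL_SHAPE}; the model is fully convolutional so this "
                "is allowed but worth checking", stacklevel=2)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise ChannelMismatchError(f"channel {name!r} not in stack") from None


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3D NIfTI volume, returning the grid and the voxel spacing.

    The on-disk (x, y, z) axes are transposed to the package's
    (slice, row, column) order, taking the last header axis as the slice
    axis; the affine orientation is preserved in the header on write.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    # disk (x, y, z) -> (slice=z, row=y, col=x)
    grid = np.ascontiguousarray(np.transpose(data, (2, 1, 0)).astype(np.float32))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return grid, spacing


def write_volume(path: str | Path, grid: np.ndarray,
                 spacing: tuple[float, float, float] = DEFAULT_SPACING) -> None:
    """Write a (slice, row, column) grid as NIfTI with the given spacing."""
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError("grid must be 3D")
    disk = np.transpose(grid, (2, 1, 0))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(disk), affine)
    img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
    nib.save(img, str(path))


def write_mask(path: str | Path, mask: np.ndarray,
               spacing: tuple[float, float, float] = DEFAULT_SPACING) -> None:
    """Write a binary mask as a 0/1 integer NIfTI volume."""
    write_volume(path, (np.asarray(mask) > 0).astype(np.uint8), spacing)


def stack_channels(volumes: Mapping[str, np.ndarray], config: ContrastConfig,
                   spacing: tuple[float, float, float] = DEFAULT_SPACING,
                   mask: np.ndarray | None = None,
                   scan_id: str = "") -> VolumeStack:
    """Assemble per-channel grids into a :class:`VolumeStack` in config order."""
    missing = [c for c in config.channels if c not in volumes]
    if missing:
        raise ChannelMismatchError(f"missing channel(s): {missing}")
    shapes = {c: np.asarray(volumes[c]).shape for c in config.channels}
    ref = shapes[config.channels[0]]
    bad = {c: s for c, s in shapes.items() if s != ref}
    if bad:
        raise ChannelMismatchError(f"shape mismatch vs {ref}: {bad}")
    data = np.stack([np.asarray(volumes[c], dtype=np.float32) for c in config.channels])
    return VolumeStack(config.channels, data, spacing=spacing, mask=mask,
                       scan_id=scan_id)


def iter_slices(stack: VolumeStack) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
    """Yield ``(slice_index, (C,R,Col) image, (R,Col) mask)`` in slice order.

    The mask is all-zero when the stack carries none, so re-stacking the
    yielded masks always reproduces a valid 3D mask.
    """
    mask = stack.mask
    if mask is None:
        mask = np.zeros(stack.spatial_shape, dtype=np.uint8)
    for s in range(stack.n_slices):
        yield s, stack.data[:, s], mask[s]
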