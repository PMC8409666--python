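"""Synthetic multi-contrast brain phantoms with ground-truth enhancing lesions.

The generator emulates the structure of a preprocessed clinical scan in
template space: five co-registered MRI contrasts (T1 post/pre-contrast,
FLAIR, T2, PD) plus five tissue-probability channels, with enhancing
lesions spanning roughly 5 to >100 voxels in ovoid and ring-enhancing
morphologies.  The brain is rendered as nested ellipsoids (CSF rim,
cortical gray matter, white matter, two lateral ventricles); smoothing the
tissue indicators yields the probability channels, and a smoothed
periventricular shell provides the lesion prior.  Protocol variability of
routine (non-standardized) MRI is emulated by per-scan, per-channel
gain/offset jitter.  No MR physics is simulated.

Enhancing lesions are hyperintense on T1 post-contrast relative to T1
pre-contrast and hyperintense on FLAIR/T2; ring-enhancing lesions carry a
hypointense (non-enhancing) core on T1 post-contrast whose voxels are not
part of the ground-truth mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgio import (ALL_CHANNELS, DEFAULT_SPACING, MRI_CHANNELS, ContrastConfig,
                    VolumeStack, stack_channels)

#: Lesion-size strata in voxels (inclusive bounds; the last is open-ended,
#: sampled up to an internal cap).
SIZE_GROUP_BOUNDS = {
    "5-10": (5, 10),
    "11-20": (11, 20),
    "21-50": (21, 50),
    "51-100": (51, 100),
    ">100": (101, 160),
}

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # face adjacency


class PhantomError(ValueError):
    """Requested phantom is infeasible (lesions cannot be placed disjointly)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic scan.

    ``size_groups`` maps stratum name to the number of lesions drawn from
    it; when empty, sizes are sampled uniformly across all strata for
    ``n_lesions`` lesions.  ``lesion_intensity`` is the T1 post-contrast
    enhancement added inside lesions (arbitrary normalized-intensity
    units); ``noise_sd`` is the per-channel Gaussian noise scale and
    ``contrast_jitter`` the SD of the per-scan multiplicative gain applied
    to each MRI channel.
    """

    shape: tuple[int, int, int] = (64, 256, 256)
    n_lesions: int = 3
    size_groups: tuple[tuple[str, int], ...] = ()
    ring_fraction: float = 0.3
    noise_sd: float = 0.05
    contrast_jitter: float = 0.1
    lesion_intensity: float = 0.5
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        for name, _ in self.size_groups:
            if name not in SIZE_GROUP_BOUNDS:
                raise ValueError(f"unknown size group {name!r}")
        if self.size_groups:
            total = sum(n for _, n in self.size_groups)
            if total != self.n_lesions:
                raise ValueError(
                    f"size_groups total {total} != n_lesions {self.n_lesions}")
        if not (0.0 <= self.ring_fraction <= 1.0):
            raise ValueError("ring_fraction must be in [0, 1]")


@dataclass
class Phantom:
    """One generated scan: channel stack, ground truth, and lesion table."""

    stack: VolumeStack
    mask: np.ndarray
    lesions: pd.DataFrame  # lesion_id, size, kind, group, centroid_{z,y,x}

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)


# ---------------------------------------------------------------------------
# anatomy

def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray,
               semiaxes: np.ndarray) -> np.ndarray:
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    q = (((zz - center[0]) / semiaxes[0]) ** 2
         + ((yy - center[1]) / semiaxes[1]) ** 2
         + ((xx - center[2]) / semiaxes[2]) ** 2)
    return q <= 1.0


def _anatomy(shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    c = np.array(shape) / 2.0
    dims = np.array(shape)
    brain = _ellipsoid(shape, c, dims * 0.45)
    inner = _ellipsoid(shape, c, dims * 0.41)
    wm_r = _ellipsoid(shape, c, dims * 0.33)
    vent_ax = np.maximum(dims * np.array([0.10, 0.14, 0.05]), 1.2)
    off = max(dims[2] * 0.09, 1.5)
    vents = (_ellipsoid(shape, c + [0, 0, off], vent_ax)
             | _ellipsoid(shape, c - [0, 0, off], vent_ax))
    vents &= wm_r
    csf = (brain & ~inner) | vents
    gm = inner & ~wm_r
    wm = wm_r & ~vents
    return {"brain": brain, "csf": csf, "gm": gm, "wm": wm, "vents": vents}


def _probability_maps(tissues: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    sig = (0.6, 1.2, 1.2)  # less smoothing along the thick slice axis
    p = {k: ndimage.gaussian_filter(tissues[k].astype(np.float32), sig)
         for k in ("gm", "wm", "csf", "vents")}
    s = p["gm"] + p["wm"] + p["csf"]
    over = s > 1.0
    for k in ("gm", "wm", "csf"):
        p[k][over] /= s[over]
    # periventricular lesion prior: dilated ventricular shell inside WM
    shell = ndimage.binary_dilation(tissues["vents"], _STRUCT6, iterations=3)
    shell = shell & tissues["wm"]
    p_les = ndimage.gaussian_filter(shell.astype(np.float32), (0.8, 2.0, 2.0))
    m = p_les.max()
    if m > 0:
        p_les *= 0.7 / m
    return {"p_gm": p["gm"], "p_wm": p["wm"], "p_csf": p["csf"],
            "p_vent": np.clip(p["vents"], 0, 1), "p_lesion": p_les}


# ---------------------------------------------------------------------------
# lesion shapes

def _lesion_voxels(center: np.ndarray, size: int, ring: bool, shape, rng
                   ) -> tuple[np.ndarray, np.ndarray] | None:
    """Return (shell voxel array Nx3, core voxel array Mx3) or None if the
    shape leaves the grid / comes out disconnected."""
    # anisotropic quadratic form; mild axis ratios keep level sets connected
    ax = np.exp(rng.uniform(-0.5, 0.5, size=3))
    ax /= ax.prod() ** (1 / 3)
    r = int(np.ceil(2.5 * (size * ax.max() ** 2) ** (1 / 3))) + 2
    lo = np.maximum(np.round(center).astype(int) - r, 0)
    hi = np.minimum(np.round(center).astype(int) + r + 1, np.array(shape))
    if np.any(hi - lo < 2):
        return None
    zz, yy, xx = np.meshgrid(*(np.arange(lo[i], hi[i]) for i in range(3)),
                             indexing="ij")
    q = (((zz - center[0]) / ax[0]) ** 2 + ((yy - center[1]) / ax[1]) ** 2
         + ((xx - center[2]) / ax[2]) ** 2).ravel()
    coords = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    n_core = max(1, int(round(0.35 * size))) if ring else 0
    n_total = size + n_core
    if n_total > len(q):
        return None
    order = np.argsort(q, kind="stable")[:n_total]
    core = coords[order[:n_core]]
    shell = coords[order[n_core:]]
    # reject shapes clipped by the bounding window (touching its border)
    sel = coords[order]
    if (sel.min(axis=0) <= lo).any() or (sel.max(axis=0) >= hi - 1).any():
        if (sel.min(axis=0) == 0).any() or (sel.max(axis=0) == np.array(shape) - 1).any():
            return None
    vol = np.zeros(shape, dtype=bool)
    vol[tuple(shell.T)] = True
    _, n_comp = ndimage.label(vol, structure=_STRUCT6)
    if n_comp != 1:
        return None
    return shell, core


def _sample_sizes(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[int, str]]:
    sizes: list[tuple[int, str]] = []
    if spec.size_groups:
        for name, n in spec.size_groups:
            lo, hi = SIZE_GROUP_BOUNDS[name]
            sizes += [(int(rng.integers(lo, hi + 1)), name) for _ in range(n)]
    else:
        names = list(SIZE_GROUP_BOUNDS)
        for _ in range(spec.n_lesions):
            name = names[rng.integers(len(names))]
            lo, hi = SIZE_GROUP_BOUNDS[name]
            sizes.append((int(rng.integers(lo, hi + 1)), name))
    return sizes


# tissue base intensities (csf, gm, wm) per MRI contrast, then lesion deltas
_TISSUE_BASE = {
    "t1_post": (0.15, 0.55, 0.70),
    "t1_pre": (0.15, 0.55, 0.70),
    "flair": (0.08, 0.60, 0.48),
    "t2": (0.90, 0.55, 0.40),
    "pd": (0.70, 0.65, 0.55),
}
_LESION_DELTA = {"t1_pre": 0.05, "flair": 0.40, "t2": 0.35, "pd": 0.20}
_RING_CORE_T1POST = -0.25  # core darker than surrounding white matter


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one 10-channel phantom scan, deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    tissues = _anatomy(shape)
    pmaps = _probability_maps(tissues)

    # -- place lesions -----------------------------------------------------
    sizes = _sample_sizes(spec, rng)
    interior = ndimage.binary_erosion(tissues["wm"], _STRUCT6, iterations=2)
    cand = np.argwhere(interior)
    if spec.n_lesions and len(cand) == 0:
        raise PhantomError("white-matter region too small for any lesion")
    weights = pmaps["p_lesion"][tuple(cand.T)] + 0.05
    weights = weights / weights.sum() if spec.n_lesions else weights
    mask = np.zeros(shape, dtype=np.uint8)
    occupied_dil = np.zeros(shape, dtype=bool)
    rows = []
    cores: list[np.ndarray] = []
    for lesion_id, (size, group) in enumerate(sizes):
        ring = bool(rng.random() < spec.ring_fraction) and size >= 15
        placed = False
        for _ in range(200):
            center = cand[rng.choice(len(cand), p=weights)].astype(float)
            center += rng.uniform(-0.4, 0.4, size=3)
            out = _lesion_voxels(center, size, ring, shape, rng)
            if out is None:
                continue
            shell, core = out
            allv = np.vstack([shell, core]) if len(core) else shell
            if not tissues["brain"][tuple(allv.T)].all():
                continue
            if occupied_dil[tuple(allv.T)].any():
                continue
            mask[tuple(shell.T)] = 1
            lesion_vol = np.zeros(shape, dtype=bool)
            lesion_vol[tuple(allv.T)] = True
            occupied_dil |= ndimage.binary_dilation(lesion_vol, _STRUCT6)
            cores.append(core)
            rows.append({"lesion_id": lesion_id, "size": size, "group": group,
                         "kind": "ring" if ring else "ovoid",
                         "centroid_z": float(shell[:, 0].mean()),
                         "centroid_y": float(shell[:, 1].mean()),
                         "centroid_x": float(shell[:, 2].mean())})
            placed = True
            break
        if not placed:
            raise PhantomError(
                f"could not place lesion of size {size} disjointly in shape {shape}")

    # -- render channels ---------------------------------------------------
    volumes: dict[str, np.ndarray] = dict(pmaps)
    background = 0.02
    for ch in MRI_CHANNELS:
        b_csf, b_gm, b_wm = _TISSUE_BASE[ch]
        img = np.full(shape, background, dtype=np.float32)
        img += (pmaps["p_csf"] * b_csf + pmaps["p_gm"] * b_gm
                + pmaps["p_wm"] * b_wm)
        delta = spec.lesion_intensity if ch == "t1_post" else _LESION_DELTA[ch]
        img[mask > 0] += delta
        for core, row in zip(cores, rows):
            if len(core) == 0:
                continue
            if ch == "t1_post":
                img[tuple(core.T)] += _RING_CORE_T1POST
            else:
                img[tuple(core.T)] += _LESION_DELTA.get(ch, 0.0) * 0.5
        gain = 1.0 + spec.contrast_jitter * rng.normal()
        offset = 0.1 * spec.contrast_jitter * rng.normal()
        img = img * gain + offset
        img += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
        volumes[ch] = img.astype(np.float32)

    stack = stack_channels(volumes, ContrastConfig.full(), spacing=spec.spacing,
                           mask=mask, scan_id=f"phantom-{spec.seed}")
    table = pd.DataFrame(rows, columns=["lesion_id", "size", "group", "kind",
                                        "centroid_z", "centroid_y", "centroid_x"])
    return Phantom(stack=stack, mask=mask, lesions=table)


def categorize_scan(n_lesions: int) -> str:
    """Per-scan count category: '0', '1' or '>=2'."""
    if n_lesions < 0:
        raise ValueError("lesion count must be >= 0")
    return "0" if n_lesions == 0 else ("1" if n_lesions == 1 else ">=2")


def generate_cohort(n_scans: int, lesion_prevalence: float, template: PhantomSpec,
                    seed: int = 0) -> tuple[list[Phantom], list[str]]:
    """Generate a cohort; each scan carries lesions with the given prevalence.

    Lesion-bearing scans realize the template's lesion load (count and size
    strata, sizes resampled per scan); the rest are lesion-free.  Returns
    the phantoms and their per-scan count categories.
    """
    if not (0.0 <= lesion_prevalence <= 1.0):
        raise ValueError("lesion_prevalence must be in [0, 1]")
    master = np.random.default_rng(seed)
    phantoms, categories = [], []
    for i in range(n_scans):
        child_seed = int(master.integers(0, 2**31 - 1))
        has_lesions = bool(master.random() < lesion_prevalence)
        if has_lesions:
            sp = replace(template, seed=child_seed)
        else:
            sp = replace(template, seed=child_seed, n_lesions=0, size_groups=())
        ph = generate_phantom(sp)
        ph.stack.scan_id = f"cohort-{seed}-{i:04d}"
        phantoms.append(ph)
        categories.append(categorize_scan(ph.n_lesions))
    return phantoms, categories
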