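"""Candidate-lesion extraction: 6-connected components and 75-feature vectors.

After the voxel classifier produces a binarized 3D mask, each 6-connected
component (face adjacency only) of at least 5 voxels becomes a candidate
lesion.  Each candidate is described by 75 features consumed by the
random-forest false-positive filter:

* 9 location: centroid (x, y, z), bounding-box start (x, y, z), bounding-box
  extent (x, y, z) — voxel units on the 0-based grid, half-open boxes;
  the grid axes map as z = slice axis, y = row, x = column, so "slice
  location" is the z centroid/start;
* 1 scan-level: number of candidates in the scan (after size filtering);
* 5 shape: size in voxels; mean and SD of the eigenvalues of the
  second-central-moment matrix of voxel coordinates in millimetres; axial
  "diffusivity" (largest eigenvalue) and radial "diffusivity" (mean of the
  two smaller) — DTI vocabulary borrowed as shape descriptors;
* 60 intensity: mean, SD and sum of intensities inside the candidate and
  in its surrounding shell (one-voxel face-adjacent dilation minus the
  candidate, clipped to the grid), for each of the 10 channels.

Channels absent from a reduced contrast configuration are zero-filled so
the 75-length layout is stable across experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgio import ALL_CHANNELS, VolumeStack

MIN_LESION_SIZE = 5

_STRUCT6 = ndimage.generate_binary_structure(3, 1)

N_FEATURES = 75


def _feature_names() -> tuple[str, ...]:
    names = ["centroid_x", "centroid_y", "centroid_z",
             "bbox_start_x", "bbox_start_y", "bbox_start_z",
             "bbox_extent_x", "bbox_extent_y", "bbox_extent_z",
             "n_candidates_in_scan",
             "size_voxels", "eig_mean", "eig_sd", "axial_diffusivity",
             "radial_diffusivity"]
    for ch in ALL_CHANNELS:
        for region in ("inside", "shell"):
            for stat in ("mean", "sd", "sum"):
                names.append(f"{region}_{stat}_{ch}")
    return tuple(names)


#: Fixed, documented feature order; index of each named feature is stable.
FEATURE_NAMES: tuple[str, ...] = _feature_names()
assert len(FEATURE_NAMES) == N_FEATURES


@dataclass
class CandidateLesion:
    """One 6-connected candidate with its feature vector and labels."""

    scan_id: str
    component_id: int
    voxels: np.ndarray  # (n, 3) 0-based (z, y, x) triples
    features: np.ndarray = field(default_factory=lambda: np.empty(0))
    rf_score: float | None = None
    label: bool | None = None  # True lesion vs false positive

    @property
    def size_voxels(self) -> int:
        return len(self.voxels)


def connected_components_6(mask: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Label a binary 3D mask under 6-connectivity.

    Returns the labeled grid (0 = background, components numbered from 1)
    and the per-component voxel arrays; two voxels share a label iff they
    are joined by a face-adjacent foreground path.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    uniq = np.unique(mask)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"mask must be binary 0/1, found values {uniq}")
    labels, n = ndimage.label(mask, structure=_STRUCT6)
    comps = [np.argwhere(labels == i + 1) for i in range(n)]
    return labels, comps


def filter_min_size(components: list[np.ndarray],
                    min_size: int = MIN_LESION_SIZE) -> list[np.ndarray]:
    """Keep only components with at least ``min_size`` voxels (inclusive)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [c for c in components if len(c) >= min_size]


def _shape_tensor_eigs(voxels: np.ndarray, spacing) -> np.ndarray:
    """Descending eigenvalues of the mm-coordinate second-central-moment matrix."""
    mm = voxels.astype(np.float64) * np.asarray(spacing, dtype=np.float64)
    centered = mm - mm.mean(axis=0)
    cov = centered.T @ centered / len(mm)
    eigs = np.linalg.eigvalsh(cov)[::-1]
    return np.clip(eigs, 0.0, None)


def _shell_voxels(voxels: np.ndarray, shape, width: int = 1) -> np.ndarray:
    vol = np.zeros(shape, dtype=bool)
    vol[tuple(voxels.T)] = True
    dil = ndimage.binary_dilation(vol, _STRUCT6, iterations=width)
    return np.argwhere(dil & ~vol)


def extract_features(voxels: np.ndarray, stack: VolumeStack,
                     n_candidates_in_scan: int, shell_width: int = 1) -> np.ndarray:
    """Compute the ordered 75-feature vector for one candidate component."""
    voxels = np.asarray(voxels)
    if len(voxels) == 0:
        raise ValueError("empty component")
    shape = stack.spatial_shape
    if (voxels < 0).any() or (voxels >= np.array(shape)).any():
        raise ValueError("component voxels outside stack bounds")

    # (z, y, x) array axes -> reported (x, y, z) = (col, row, slice)
    cz, cy, cx = voxels.mean(axis=0)
    lo = voxels.min(axis=0)
    hi = voxels.max(axis=0) + 1  # half-open
    ext = hi - lo

    eigs = _shape_tensor_eigs(voxels, stack.spacing)
    shape_feats = [float(len(voxels)), float(eigs.mean()), float(eigs.std()),
                   float(eigs[0]), float((eigs[1] + eigs[2]) / 2.0)]

    shell = _shell_voxels(voxels, shape, shell_width)
    inside_idx = tuple(voxels.T)
    shell_idx = tuple(shell.T) if len(shell) else None

    feats = [cx, cy, cz,
             float(lo[2]), float(lo[1]), float(lo[0]),
             float(ext[2]), float(ext[1]), float(ext[0]),
             float(n_candidates_in_scan)] + shape_feats

    data = {ch: stack.data[i] for i, ch in enumerate(stack.channels)}
    for ch in ALL_CHANNELS:
        grid = data.get(ch)
        for idx in (inside_idx, shell_idx):
            if grid is None or idx is None:
                feats += [0.0, 0.0, 0.0]
                continue
            vals = grid[idx].astype(np.float64)
            feats += [float(vals.mean()), float(vals.std()), float(vals.sum())]
    out = np.asarray(feats, dtype=np.float64)
    assert out.shape == (N_FEATURES,)
    return out


def extract_candidates(pred_mask: np.ndarray, stack: VolumeStack,
                       min_size: int = MIN_LESION_SIZE,
                       shell_width: int = 1) -> list[CandidateLesion]:
    """Full candidate extraction for one scan: label, size-filter, featurize.

    The scan-level candidate-count feature equals the number of components
    surviving the size filter and is identical across the scan's candidates.
    """
    _, comps = connected_components_6(pred_mask)
    comps = filter_min_size(comps, min_size)
    n = len(comps)
    out = []
    for i, vox in enumerate(comps):
        feats = extract_features(vox, stack, n, shell_width=shell_width)
        out.append(CandidateLesion(scan_id=stack.scan_id, component_id=i,
                                   voxels=vox, features=feats))
    return out


def candidates_to_frame(cands: list[CandidateLesion]) -> pd.DataFrame:
    """Tabulate candidates: scan_id, component_id, size, 75 named features,
    rf_score, label."""
    rows = []
    for c in cands:
        row = {"scan_id": c.scan_id, "component_id": c.component_id,
               "size_voxels_total": c.size_voxels}
        row.update(dict(zip(FEATURE_NAMES, c.features)))
        row["rf_score"] = np.nan if c.rf_score is None else c.rf_score
        row["label"] = None if c.label is None else bool(c.label)
        rows.append(row)
    cols = ["scan_id", "component_id", "size_voxels_total", *FEATURE_NAMES,
            "rf_score", "label"]
    return pd.DataFrame(rows, columns=cols)


def candidates_mask(cands: list[CandidateLesion], shape) -> np.ndarray:
    """Union of candidate components as a binary mask."""
    mask = np.zeros(shape, dtype=np.uint8)
    for c in cands:
        mask[tuple(c.voxels.T)] = 1
    return mask
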