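"""Lesion-wise and voxel-wise evaluation, and lesion-count confusion matrices.

Lesion-level matching uses a one-voxel overlap rule on 6-connected
components of at least 5 voxels: a manual lesion is a true positive (TP)
if any predicted component overlaps it in >= 1 voxel, else a false
negative (FN); a predicted component overlapping no manual lesion is a
false positive (FP).  TP and FN are counted over manual lesions (carrying
the manual lesion's size), FP over predicted components (carrying the
predicted size) — the hybrid convention under which the printed
sensitivity TP/(TP+FN) and false detection ratio FP/(FP+TP) are exactly
recomputable from the stratified counts.

Lesion counts per scan are categorized as 0, 1 or >=2 (radiology-report
granularity) and compared in a 3x3 confusion matrix with column
(true-category) normalization; overall accuracy is the diagonal sum over
the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .candidates import MIN_LESION_SIZE, connected_components_6, filter_min_size

#: Size strata in voxels, inclusive bounds; together they partition [5, inf).
DEFAULT_SIZE_GROUPS: tuple[tuple[str, int, float], ...] = (
    ("5-10", 5, 10), ("11-20", 11, 20), ("21-50", 21, 50),
    ("51-100", 51, 100), (">100", 101, np.inf),
)

COUNT_CATEGORIES = ("0", "1", ">=2")


def size_group(size: int,
               groups: Sequence[tuple[str, int, float]] = DEFAULT_SIZE_GROUPS) -> str:
    for name, lo, hi in groups:
        if lo <= size <= hi:
            return name
    raise ValueError(f"size {size} below the minimum stratum")


# ---------------------------------------------------------------------------
# lesion matching

def match_lesions(pred_mask: np.ndarray, manual_mask: np.ndarray,
                  min_size: int = MIN_LESION_SIZE) -> pd.DataFrame:
    """Per-lesion match table for one scan.

    Both masks are decomposed into 6-connected components and filtered at
    ``min_size``.  Returns a frame with one row per manual lesion (status
    TP or FN, size = manual size) and one row per unmatched predicted
    component (status FP, size = predicted size).
    """
    pred_mask = np.asarray(pred_mask)
    manual_mask = np.asarray(manual_mask)
    if pred_mask.shape != manual_mask.shape:
        raise ValueError(
            f"grid mismatch: {pred_mask.shape} vs {manual_mask.shape}")
    _, pred_comps = connected_components_6((pred_mask > 0).astype(np.uint8))
    _, man_comps = connected_components_6((manual_mask > 0).astype(np.uint8))
    pred_comps = filter_min_size(pred_comps, min_size)
    man_comps = filter_min_size(man_comps, min_size)

    pred_vol = np.zeros(pred_mask.shape, dtype=np.int32)
    for i, vox in enumerate(pred_comps):
        pred_vol[tuple(vox.T)] = i + 1

    rows = []
    matched_pred: set[int] = set()
    for vox in man_comps:
        hits = np.unique(pred_vol[tuple(vox.T)])
        hits = hits[hits > 0]
        matched_pred.update(int(h) for h in hits)
        rows.append({"status": "TP" if len(hits) else "FN", "size": len(vox)})
    for i, vox in enumerate(pred_comps):
        if (i + 1) not in matched_pred:
            rows.append({"status": "FP", "size": len(vox)})
    return pd.DataFrame(rows, columns=["status", "size"])


@dataclass
class LesionEvalReport:
    """Size-stratified lesion-detection counts with sensitivity/FDR/Dice.

    ``table`` has one row per size group plus a ``total`` row with columns
    tp, fn, fp, sensitivity, fdr.  Undefined ratios (0/0) are NaN, never 0
    or 1.  ``dice_per_image`` and ``mean_dice`` are filled when voxel
    overlap is evaluated alongside detection.
    """

    table: pd.DataFrame
    dice_per_image: list[float] = field(default_factory=list)
    mean_dice: float = float("nan")

    def row(self, group: str) -> pd.Series:
        return self.table.loc[group]

    @property
    def sensitivity(self) -> float:
        return float(self.table.loc["total", "sensitivity"])

    @property
    def fdr(self) -> float:
        return float(self.table.loc["total", "fdr"])


def _ratio(num: int, den: int) -> float:
    return float("nan") if den == 0 else num / den


def lesion_metrics(match_tables: Sequence[pd.DataFrame],
                   groups: Sequence[tuple[str, int, float]] = DEFAULT_SIZE_GROUPS,
                   dice_per_image: Sequence[float] = ()) -> LesionEvalReport:
    """Aggregate per-scan match tables into the stratified report.

    sensitivity = TP/(TP+FN) and FDR = FP/(FP+TP), per size group and in
    total; totals equal the sums over groups because the strata partition
    the admissible sizes.
    """
    all_rows = (pd.concat(match_tables, ignore_index=True) if len(match_tables)
                else pd.DataFrame(columns=["status", "size"]))
    recs = {}
    group_names = [g[0] for g in groups]
    for name, lo, hi in groups:
        sub = all_rows[(all_rows["size"] >= lo) & (all_rows["size"] <= hi)]
        counts = sub["status"].value_counts()
        recs[name] = {s: int(counts.get(s, 0)) for s in ("TP", "FN", "FP")}
    recs["total"] = {s: sum(recs[g][s] for g in group_names)
                     for s in ("TP", "FN", "FP")}
    rows = []
    for name, c in recs.items():
        rows.append({"group": name, "tp": c["TP"], "fn": c["FN"], "fp": c["FP"],
                     "sensitivity": _ratio(c["TP"], c["TP"] + c["FN"]),
                     "fdr": _ratio(c["FP"], c["FP"] + c["TP"])})
    table = pd.DataFrame(rows).set_index("group")
    dpi = [d for d in dice_per_image]
    finite = [d for d in dpi if not np.isnan(d)]
    return LesionEvalReport(table=table, dice_per_image=dpi,
                            mean_dice=float(np.mean(finite)) if finite else float("nan"))


def dice_3d(pred_mask: np.ndarray, manual_mask: np.ndarray) -> float:
    """3D Dice overlap 2|A∩B|/(|A|+|B|); NaN when both masks are empty."""
    a = np.asarray(pred_mask) > 0
    b = np.asarray(manual_mask) > 0
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    den = int(a.sum()) + int(b.sum())
    if den == 0:
        return float("nan")
    return 2.0 * int((a & b).sum()) / den


def dice_by_size_group(pred_mask: np.ndarray, manual_mask: np.ndarray,
                       min_size: int = MIN_LESION_SIZE,
                       groups: Sequence[tuple[str, int, float]] = DEFAULT_SIZE_GROUPS
                       ) -> dict[str, float]:
    """Restricted-mask Dice per size stratum.

    For each group, the manual sub-mask is the union of that group's manual
    lesions and the predicted sub-mask is the union of predicted components
    overlapping any of them; Dice is computed between the two sub-masks.
    Groups with no manual lesion are NaN.  This restricted definition is a
    modelling choice — there is no canonical group-wise Dice.
    """
    pred_mask = np.asarray(pred_mask) > 0
    manual_mask = np.asarray(manual_mask) > 0
    if pred_mask.shape != manual_mask.shape:
        raise ValueError("grid mismatch")
    _, pred_comps = connected_components_6(pred_mask.astype(np.uint8))
    _, man_comps = connected_components_6(manual_mask.astype(np.uint8))
    pred_comps = filter_min_size(pred_comps, min_size)
    man_comps = filter_min_size(man_comps, min_size)
    pred_vol = np.zeros(pred_mask.shape, dtype=np.int32)
    for i, vox in enumerate(pred_comps):
        pred_vol[tuple(vox.T)] = i + 1
    out: dict[str, float] = {}
    for name, lo, hi in groups:
        members = [v for v in man_comps if lo <= len(v) <= hi]
        if not members:
            out[name] = float("nan")
            continue
        man_sub = np.zeros(pred_mask.shape, dtype=bool)
        hit_ids: set[int] = set()
        for vox in members:
            man_sub[tuple(vox.T)] = True
            ids = np.unique(pred_vol[tuple(vox.T)])
            hit_ids.update(int(i) for i in ids if i > 0)
        pred_sub = np.isin(pred_vol, sorted(hit_ids)) if hit_ids else \
            np.zeros_like(man_sub)
        out[name] = dice_3d(pred_sub, man_sub)
    return out


def mean_dice_3d(pred_masks: Sequence[np.ndarray],
                 manual_masks: Sequence[np.ndarray]) -> float:
    """Mean per-image 3D Dice over images with at least one manual lesion.

    Lesion-free images (0/0 Dice) are excluded from the average so the
    mean stays finite on cohorts that include them.
    """
    vals = []
    for p, m in zip(pred_masks, manual_masks):
        if np.asarray(m).sum() > 0:
            vals.append(dice_3d(p, m))
    return float(np.mean(vals)) if vals else float("nan")


def evaluate_scans(pred_masks: Sequence[np.ndarray],
                   manual_masks: Sequence[np.ndarray],
                   min_size: int = MIN_LESION_SIZE,
                   groups: Sequence[tuple[str, int, float]] = DEFAULT_SIZE_GROUPS
                   ) -> LesionEvalReport:
    """Convenience: match + stratify + per-image Dice for a scan list."""
    tables = [match_lesions(p, m, min_size) for p, m in zip(pred_masks, manual_masks)]
    dpi = [dice_3d(p, m) if np.asarray(m).sum() > 0 else float("nan")
           for p, m in zip(pred_masks, manual_masks)]
    return lesion_metrics(tables, groups, dice_per_image=dpi)


# ---------------------------------------------------------------------------
# count categorization

def categorize_count(n_lesions: int) -> str:
    """Bin a per-scan lesion count into {0, 1, >=2}."""
    if n_lesions < 0:
        raise ValueError("lesion count must be >= 0")
    return "0" if n_lesions == 0 else ("1" if n_lesions == 1 else ">=2")


@dataclass
class CountConfusion:
    """3x3 lesion-count confusion matrix (predicted x true categories).

    ``normalized`` holds column percentages (each true-category column sums
    to 100); ``accuracy`` is the percentage of scans on the diagonal.
    """

    matrix: pd.DataFrame  # rows: predicted, cols: true

    def __post_init__(self) -> None:
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("confusion entries must be >= 0")

    @property
    def n_scans(self) -> int:
        return int(self.matrix.to_numpy().sum())

    @property
    def normalized(self) -> pd.DataFrame:
        m = self.matrix.to_numpy(dtype=float)
        col = m.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * m / col
        return pd.DataFrame(pct, index=self.matrix.index, columns=self.matrix.columns)

    @property
    def accuracy(self) -> float:
        """Overall accuracy in percent: 100 * trace / total."""
        m = self.matrix.to_numpy()
        return 100.0 * np.trace(m) / m.sum()

    @classmethod
    def from_counts(cls, matrix: np.ndarray) -> "CountConfusion":
        m = np.asarray(matrix, dtype=int)
        if m.shape != (3, 3):
            raise ValueError("expected a 3x3 matrix")
        df = pd.DataFrame(m, index=list(COUNT_CATEGORIES),
                          columns=list(COUNT_CATEGORIES))
        df.index.name, df.columns.name = "predicted", "true"
        return cls(df)


def count_confusion(pred_categories: Sequence[str], true_categories: Sequence[str],
                    group_by: Sequence | None = None
                    ) -> CountConfusion | dict[object, CountConfusion]:
    """Confusion matrix over count categories, optionally per subgroup.

    ``group_by``, when given, is a per-scan attribute (e.g. field strength,
    vendor, acquisition format) and one matrix is returned per distinct
    value.
    """
    if len(pred_categories) != len(true_categories):
        raise ValueError("category lists must have equal length")
    for c in (*pred_categories, *true_categories):
        if c not in COUNT_CATEGORIES:
            raise ValueError(f"unknown category {c!r}")
    if group_by is not None:
        if len(group_by) != len(true_categories):
            raise ValueError("group_by must match the scan list length")
        out = {}
        for g in dict.fromkeys(group_by):  # first-seen order
            idx = [i for i, v in enumerate(group_by) if v == g]
            out[g] = count_confusion([pred_categories[i] for i in idx],
                                     [true_categories[i] for i in idx])
        return out
    m = np.zeros((3, 3), dtype=int)
    pos = {c: i for i, c in enumerate(COUNT_CATEGORIES)}
    for p, t in zip(pred_categories, true_categories):
        m[pos[p], pos[t]] += 1
    return CountConfusion.from_counts(m)


def format_report(report: LesionEvalReport, ndigits: int = 3) -> str:
    """Human-readable stratified table (rows TP/sensitivity/FP/FDR)."""
    t = report.table
    lines = ["group      TP   FN   FP   sens    FDR"]
    for g, r in t.iterrows():
        sens = "n/a" if np.isnan(r["sensitivity"]) else f"{r['sensitivity']:.{ndigits}f}"
        fdr = "n/a" if np.isnan(r["fdr"]) else f"{r['fdr']:.{ndigits}f}"
        lines.append(f"{g:<9} {int(r['tp']):4d} {int(r['fn']):4d} {int(r['fp']):4d}"
                     f"  {sens:>6} {fdr:>6}")
    if not np.isnan(report.mean_dice):
        lines.append(f"mean 3D Dice over lesion-bearing images: {report.mean_dice:.{ndigits}f}")
    return "\n".join(lines)
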