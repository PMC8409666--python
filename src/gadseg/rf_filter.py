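"""Random-forest false-positive filter over candidate-lesion features.

Candidates surviving the size filter are labeled true lesion vs false
positive by the same one-voxel overlap rule used at evaluation time, a
random forest is fit on the 75-feature vectors, and at application time a
candidate is kept iff its forest score reaches the decision threshold.
Filtering only ever removes components, so the filtered mask is a subset
of the input mask and lesion-wise sensitivity can only decrease while the
false detection ratio is expected to improve.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .candidates import FEATURE_NAMES, CandidateLesion, candidates_mask


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters; none are prescribed by the two-stage design,
    so standard defaults are used and all are configurable."""

    n_trees: int = 100
    max_depth: int | None = None
    class_weighting: str | None = "balanced"
    score_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 < self.score_threshold < 1.0):
            raise ValueError("score_threshold must be in (0, 1)")


def label_candidates(candidates: Sequence[CandidateLesion],
                     manual_mask: np.ndarray) -> list[CandidateLesion]:
    """Label each candidate: true lesion iff it overlaps the manual mask in
    at least one voxel, else false positive.  Mutates and returns the list."""
    manual = np.asarray(manual_mask) > 0
    for c in candidates:
        if (c.voxels >= np.array(manual.shape)).any() or (c.voxels < 0).any():
            raise ValueError("candidate voxels outside the manual-mask grid")
        c.label = bool(manual[tuple(c.voxels.T)].any())
    return list(candidates)


@dataclass
class FittedRF:
    """Trained classifier with its embedded feature layout."""

    model: RandomForestClassifier
    feature_names: tuple[str, ...]
    config: RFConfig

    def scores(self, features: np.ndarray) -> np.ndarray:
        """Probability of the true-lesion class for each feature row."""
        pos = list(self.model.classes_).index(True)
        return self.model.predict_proba(features)[:, pos]

    @property
    def importances(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature": self.feature_names,
                           "importance": self.model.feature_importances_})
        return df.sort_values("importance", ascending=False, ignore_index=True)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "FittedRF":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, FittedRF):
            raise TypeError(f"{path} does not hold a fitted filter")
        return obj


def fit_rf(candidates: Sequence[CandidateLesion], cfg: RFConfig = RFConfig(),
           feature_names: tuple[str, ...] = FEATURE_NAMES) -> FittedRF:
    """Fit the forest on labeled candidates; deterministic given cfg.seed."""
    unlabeled = [c for c in candidates if c.label is None]
    if unlabeled:
        raise ValueError(f"{len(unlabeled)} candidates are unlabeled")
    if not candidates:
        raise ValueError("no candidates to train on")
    X = np.vstack([c.features for c in candidates])
    if X.shape[1] != len(feature_names):
        raise ValueError(f"feature layout mismatch: {X.shape[1]} columns vs "
                         f"{len(feature_names)} names")
    y = np.array([c.label for c in candidates], dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("training candidates contain a single class; "
                         "need both true lesions and false positives")
    model = RandomForestClassifier(n_estimators=cfg.n_trees,
                                   max_depth=cfg.max_depth,
                                   class_weight=cfg.class_weighting,
                                   random_state=cfg.seed)
    model.fit(X, y)
    return FittedRF(model=model, feature_names=tuple(feature_names), config=cfg)


def apply_rf(fitted: FittedRF, candidates: Sequence[CandidateLesion],
             shape: tuple[int, int, int],
             score_threshold: float | None = None
             ) -> tuple[list[CandidateLesion], np.ndarray]:
    """Score candidates and keep those with rf_score >= threshold.

    Returns the retained candidates (scores recorded on every input
    candidate) and the filtered binary mask, the union of kept components.
    """
    thr = fitted.config.score_threshold if score_threshold is None else score_threshold
    if not candidates:
        return [], np.zeros(shape, dtype=np.uint8)
    X = np.vstack([c.features for c in candidates])
    if X.shape[1] != len(fitted.feature_names):
        raise ValueError("candidate feature layout does not match the classifier")
    scores = fitted.scores(X)
    kept = []
    for c, s in zip(candidates, scores):
        c.rf_score = float(s)
        if s >= thr:
            kept.append(c)
    return kept, candidates_mask(kept, shape)
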