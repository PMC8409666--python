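"""Segmentation training losses: Dice, cross-entropy, bootstrapped cross-entropy.

All losses treat the prediction as voxelwise foreground probabilities in
(0, 1) and the target as a binary mask.  Bootstrapped cross-entropy averages
only the K hardest voxels of a batch (the K largest per-voxel losses),
which emphasizes boundary voxels and small lesions during training.

Each ``*_loss`` has a matching ``*_grad`` returning d(loss)/d(probability),
used by the NumPy training loop.
"""

from __future__ import annotations

import numpy as np

#: Probability clamp for numerical stability of the logarithms.
EPS_CLAMP = 1e-7


def _check_shapes(x: np.ndarray, x_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: target {x.shape} vs prediction {x_hat.shape}")
    return x, x_hat


def dice_loss(x: np.ndarray, x_hat: np.ndarray, smooth: float = 0.0) -> float:
    """1 - 2*sum(x*x_hat) / (sum(x) + sum(x_hat)), the soft Dice loss.

    ``smooth`` is an optional epsilon added to numerator and denominator;
    with smooth=0 and both inputs empty the ratio is undefined and a
    ``ZeroDivisionError`` is raised.
    """
    x, x_hat = _check_shapes(x, x_hat)
    num = 2.0 * float((x * x_hat).sum()) + smooth
    den = float(x.sum() + x_hat.sum()) + smooth
    if den == 0.0:
        raise ZeroDivisionError("Dice loss undefined: both masks empty and smooth=0")
    return 1.0 - num / den


def dice_grad(x: np.ndarray, x_hat: np.ndarray, smooth: float = 1.0) -> np.ndarray:
    """Gradient of :func:`dice_loss` with respect to each predicted probability."""
    x, x_hat = _check_shapes(x, x_hat)
    num = 2.0 * (x * x_hat).sum() + smooth
    den = x.sum() + x_hat.sum() + smooth
    # d/dp [1 - num/den] = -(2*x*den - num) / den^2
    return (num - 2.0 * x * den) / (den * den)


def per_voxel_ce(x: np.ndarray, x_hat: np.ndarray) -> np.ndarray:
    """Per-voxel binary cross-entropy p_j = -x log(x_hat) - (1-x) log(1-x_hat)."""
    x, x_hat = _check_shapes(x, x_hat)
    p = np.clip(x_hat, EPS_CLAMP, 1.0 - EPS_CLAMP)
    return -(x * np.log(p) + (1.0 - x) * np.log1p(-p))


def cross_entropy_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean over all N voxels of the per-voxel cross-entropy."""
    return float(per_voxel_ce(x, x_hat).mean())


def cross_entropy_grad(x: np.ndarray, x_hat: np.ndarray) -> np.ndarray:
    x, x_hat = _check_shapes(x, x_hat)
    p = np.clip(x_hat, EPS_CLAMP, 1.0 - EPS_CLAMP)
    return (-x / p + (1.0 - x) / (1.0 - p)) / x.size


def _topk_mask(p_j: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask selecting exactly k largest entries (stable index order).

    The selection threshold is the (k+1)-th largest loss; ties at the
    threshold are broken by ascending voxel index so exactly k voxels are
    kept and the 1/K normalization stays well defined.
    """
    flat = p_j.ravel()
    # argsort is stable; descending order via negation keeps earliest index
    # first among ties.
    order = np.argsort(-flat, kind="stable")[:k]
    mask = np.zeros(flat.size, dtype=bool)
    mask[order] = True
    return mask.reshape(p_j.shape)


def bootstrapped_ce(x: np.ndarray, x_hat: np.ndarray, k: int) -> float:
    """Mean of the K largest per-voxel cross-entropies over the batch.

    Selection is over the full batch's N voxels; when K >= N this equals
    the plain mean cross-entropy.
    """
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")
    p_j = per_voxel_ce(x, x_hat)
    n = p_j.size
    if k >= n:
        return float(p_j.mean())
    sel = _topk_mask(p_j, k)
    return float(p_j[sel].sum() / k)


def bootstrapped_ce_grad(x: np.ndarray, x_hat: np.ndarray, k: int) -> np.ndarray:
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")
    x, x_hat = _check_shapes(x, x_hat)
    p = np.clip(x_hat, EPS_CLAMP, 1.0 - EPS_CLAMP)
    p_j = -(x * np.log(p) + (1.0 - x) * np.log1p(-p))
    n = p_j.size
    k_eff = min(k, n)
    sel = _topk_mask(p_j, k_eff) if k_eff < n else np.ones(p_j.shape, dtype=bool)
    g = (-x / p + (1.0 - x) / (1.0 - p)) / k_eff
    g[~sel] = 0.0
    return g


_LOSS_FNS = {
    "dice": lambda x, p, cfg: dice_loss(x, p, smooth=cfg.get("smooth", 1.0)),
    "ce": lambda x, p, cfg: cross_entropy_loss(x, p),
    "bootstrap_ce": lambda x, p, cfg: bootstrapped_ce(x, p, cfg["k"]),
}
_GRAD_FNS = {
    "dice": lambda x, p, cfg: dice_grad(x, p, smooth=cfg.get("smooth", 1.0)),
    "ce": lambda x, p, cfg: cross_entropy_grad(x, p),
    "bootstrap_ce": lambda x, p, cfg: bootstrapped_ce_grad(x, p, cfg["k"]),
}


def get_loss(name: str, **params):
    """Return ``(loss_fn, grad_fn)`` closures for a loss selected by name.

    Names: ``dice`` (optional ``smooth``, default 1.0 when training),
    ``ce``, ``bootstrap_ce`` (requires integer ``k``).
    """
    if name not in _LOSS_FNS:
        raise KeyError(f"unknown loss {name!r}; choose from {sorted(_LOSS_FNS)}")
    if name == "bootstrap_ce" and "k" not in params:
        raise ValueError("bootstrap_ce requires parameter k")
    loss = _LOSS_FNS[name]
    grad = _GRAD_FNS[name]
    return (lambda x, p: loss(x, p, params)), (lambda x, p: grad(x, p, params))
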