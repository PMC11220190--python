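"""Training objectives for multi-consistency semi-supervised segmentation.

The objective has two parts.  On labeled crops the primary decoder is trained
with cross-entropy plus soft Dice against the ground-truth mask,

    L_s = L_CE(y_seg, Y) + L_dice(y_seg, Y).

On unlabeled crops every decoder produces a probability map; each map is turned
into a pseudo-label by the Soft-Hard process — sharpen the tumor probability
with temperature ``T``,

    P_S = p^(1/T) / (p^(1/T) + (1 - p)^(1/T)),

then take the argmax, ``P_H = [P_S > 0.5]``.  The multi-consistency loss sums
CE + Dice over every ordered decoder pair (i, j), i != j, using decoder j's
pseudo-label as the target for decoder i's map.  The total loss is

    L = lambda * L_s + beta(t) * L_u,

where ``beta`` follows the Gaussian warm-up schedule
``0.001 * exp(-5 * (1 - t/t_max)^2)`` so that early, unreliable pseudo-labels
carry almost no weight.

All probability maps here are channel-last ``(H, W, 2)`` arrays with channel 0
the normal class and channel 1 the tumor class.  Functions whose name ends in
``_grad`` additionally return the gradient with respect to the probability
map; pseudo-label targets never receive gradient (they are plain arrays,
detached by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PseudoLabels",
    "LossWeights",
    "cross_entropy_loss",
    "dice_loss",
    "supervised_loss",
    "sharpen",
    "hard_label",
    "make_pseudo_labels",
    "multi_consistency_loss",
    "warmup_beta",
    "total_loss",
]

#: floor/ceiling applied to probabilities inside the log of the cross-entropy
CE_CLIP = 1e-7
#: smoothing constant in the soft Dice denominator/numerator
DICE_EPS = 1e-5


@dataclass
class PseudoLabels:
    """Soft and hard pseudo-labels derived from one decoder's output.

    ``soft`` is the sharpened tumor probability P_S in [0, 1]; ``hard`` is the
    thresholded class map P_H in {0, 1} (ties at exactly 0.5 break toward the
    normal class).  ``source`` records which decoder produced them.
    """

    soft: np.ndarray
    hard: np.ndarray
    source: int = 0


@dataclass
class LossWeights:
    """Hyperparameters of the total objective.

    lam
        Weight of the supervised term (default 0.5).
    temperature
        Sharpening temperature T > 0 (default 0.5; T < 1 sharpens).
    beta_amplitude, beta_shape
        The warm-up schedule ``amplitude * exp(-shape * (1 - t/t_max)^2)``.
    consistency_mode
        'hard' targets decoder pairs with P_H (the default), 'soft' with the
        two-channel soft label (1 - P_S, P_S).
    """

    lam: float = 0.5
    temperature: float = 0.5
    beta_amplitude: float = 0.001
    beta_shape: float = 5.0
    consistency_mode: str = "hard"
    t: int = 0
    t_max: int = 1

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if self.consistency_mode not in ("hard", "soft"):
            raise ValueError(f"unknown consistency mode {self.consistency_mode!r}")


def _check_probs_target(probs: np.ndarray, target: np.ndarray) -> None:
    probs = np.asarray(probs)
    target = np.asarray(target)
    if probs.ndim != 3 or probs.shape[-1] != 2:
        raise ValueError(f"expected (H, W, 2) probability map, got {probs.shape}")
    if target.shape != probs.shape[:-1]:
        raise ValueError(
            f"target shape {target.shape} does not match map {probs.shape[:-1]}"
        )


def _target_to_channels(target: np.ndarray) -> np.ndarray:
    """Class map {0,1} or soft tumor probability -> (H, W, 2) channel weights."""
    t = np.asarray(target, dtype=np.float64)
    return np.stack([1.0 - t, t], axis=-1)


def cross_entropy_loss(probs: np.ndarray, target: np.ndarray) -> float:
    """Mean pixel cross-entropy of a normalized map against a class map.

    ``target`` may be an integer {0,1} mask or a soft (H, W, 2)-compatible
    tumor-probability map; probabilities are clipped to [1e-7, 1 - 1e-7].
    """
    return _cross_entropy_grad(probs, target, want_grad=False)[0]


def _cross_entropy_grad(probs, target, want_grad=True):
    _check_probs_target(np.asarray(probs), np.asarray(target))
    probs = np.asarray(probs, dtype=np.float64)
    tch = _target_to_channels(target)
    clipped = np.clip(probs, CE_CLIP, 1.0 - CE_CLIP)
    n_pix = probs.shape[0] * probs.shape[1]
    value = float(-(tch * np.log(clipped)).sum() / n_pix)
    if not want_grad:
        return value, None
    # d/dp of -t*log(clip(p)); zero where the clip is active
    grad = np.where(
        (probs > CE_CLIP) & (probs < 1.0 - CE_CLIP), -tch / clipped / n_pix, 0.0
    )
    return value, grad


def dice_loss(probs: np.ndarray, target: np.ndarray) -> float:
    """Soft Dice loss averaged over the two classes.

    For each class c: ``1 - (2 * sum(p_c y_c) + eps) / (sum p_c + sum y_c + eps)``
    with eps = 1e-5; the probabilities are used as-is (not thresholded).
    """
    return _dice_grad(probs, target, want_grad=False)[0]


def _dice_grad(probs, target, want_grad=True):
    _check_probs_target(np.asarray(probs), np.asarray(target))
    probs = np.asarray(probs, dtype=np.float64)
    tch = _target_to_channels(target)
    num = 2.0 * (probs * tch).sum(axis=(0, 1)) + DICE_EPS  # per class
    den = probs.sum(axis=(0, 1)) + tch.sum(axis=(0, 1)) + DICE_EPS
    value = float(np.mean(1.0 - num / den))
    if not want_grad:
        return value, None
    # d(1 - num/den)/dp_c = -(2*y_c*den - num)/den^2, then mean over classes
    grad = -(2.0 * tch * den - num) / (den**2) / 2.0
    return value, grad


def supervised_loss(primary_probs: np.ndarray, target: np.ndarray) -> float:
    """CE + Dice of the primary decoder's map against the ground-truth mask."""
    return cross_entropy_loss(primary_probs, target) + dice_loss(primary_probs, target)


def _supervised_grad(primary_probs, target):
    ce, g_ce = _cross_entropy_grad(primary_probs, target)
    dc, g_dc = _dice_grad(primary_probs, target)
    return ce + dc, g_ce + g_dc


def sharpen(p: np.ndarray, temperature: float) -> np.ndarray:
    """Temperature-sharpen a tumor probability: p^(1/T) / (p^(1/T)+(1-p)^(1/T)).

    T = 1 is the identity; T < 1 pushes probabilities toward {0, 1}
    (entropy minimization); p = 0.5 is a fixed point for every T.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    inv_t = 1.0 / temperature
    num = np.power(p, inv_t)
    den = num + np.power(1.0 - p, inv_t)
    # p in {0,1} can give 0/0 under extreme 1/T; resolve by the limit value
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    out = np.where(den > 0, out, np.where(p > 0.5, 1.0, 0.0))
    return out


def hard_label(soft: np.ndarray) -> np.ndarray:
    """Argmax of a soft pseudo-label: 1 where P_S > 0.5, else 0 (tie -> 0)."""
    return (np.asarray(soft) > 0.5).astype(np.int64)


def make_pseudo_labels(
    probs: np.ndarray, temperature: float, source: int = 0
) -> PseudoLabels:
    """Run the Soft-Hard process on one decoder's (H, W, 2) probability map."""
    p_tumor = np.asarray(probs)[..., 1]
    soft = sharpen(p_tumor, temperature)
    return PseudoLabels(soft=soft, hard=hard_label(soft), source=source)


def multi_consistency_loss(
    maps: list[np.ndarray],
    pseudo: list[PseudoLabels],
    mode: str = "hard",
) -> float:
    """Sum of CE + Dice over all ordered decoder pairs (i, j), i != j.

    Decoder j's pseudo-label (hard P_H by default, soft (1-P_S, P_S) in
    ``mode='soft'``) is the target for decoder i's probability map.  Returns 0
    for a single decoder (empty pair sum).  Targets carry no gradient.
    """
    return _multi_consistency_grad(maps, pseudo, mode, want_grad=False)[0]


def _multi_consistency_grad(maps, pseudo, mode="hard", want_grad=True):
    if len(maps) == 0:
        raise ValueError("need at least one probability map")
    if len(maps) != len(pseudo):
        raise ValueError(f"{len(maps)} maps but {len(pseudo)} pseudo-label sets")
    if mode not in ("hard", "soft"):
        raise ValueError(f"unknown consistency mode {mode!r}")
    total = 0.0
    grads = [np.zeros_like(np.asarray(m, dtype=np.float64)) for m in maps] if want_grad else None
    for i, m in enumerate(maps):
        for j, pl in enumerate(pseudo):
            if i == j:
                continue
            target = pl.hard if mode == "hard" else pl.soft
            ce, g_ce = _cross_entropy_grad(m, target, want_grad=want_grad)
            dc, g_dc = _dice_grad(m, target, want_grad=want_grad)
            total += ce + dc
            if want_grad:
                grads[i] += g_ce + g_dc
    return total, grads


def warmup_beta(
    t: int, t_max: int, amplitude: float = 0.001, shape: float = 5.0
) -> float:
    """Gaussian warm-up weight ``amplitude * exp(-shape * (1 - t/t_max)^2)``.

    Monotone non-decreasing in t; equals ``amplitude`` at t = t_max.
    """
    if t_max <= 0:
        raise ValueError(f"t_max must be > 0, got {t_max}")
    if not 0 <= t <= t_max:
        raise ValueError(f"t={t} outside [0, {t_max}]")
    return float(amplitude * np.exp(-shape * (1.0 - t / t_max) ** 2))


def total_loss(l_s: float, l_u: float, weights: LossWeights) -> float:
    """Weighted total ``lambda * L_s + beta(t, t_max) * L_u``."""
    if not (np.isfinite(l_s) and np.isfinite(l_u)):
        raise ValueError(f"non-finite loss components: L_s={l_s}, L_u={l_u}")
    beta = warmup_beta(
        weights.t, weights.t_max, weights.beta_amplitude, weights.beta_shape
    )
    return float(weights.lam * l_s + beta * l_u)
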