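"""Objective functions.

Source training uses a smoothed soft Dice loss.  Adaptation combines three
unsupervised terms on the predicted foreground-probability map ``P``:

* an entropy term, the mean two-class Shannon entropy of ``(P, 1 - P)``;
* a symmetric shape term, the symmetrized KL divergence between the
  predicted soft foreground ratio and a source-domain class-ratio prior,
  each ratio read as a two-outcome (foreground/background) distribution;
* a refine term, the mean squared difference between ``P`` and the
  reconstruction of ``P`` by a frozen refine model.

All losses accept either plain arrays or autodiff tensors and return a
scalar tensor (use ``.item()`` for the float value).  Natural logarithms
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Tuple

import numpy as np

from .nn import Tensor

__all__ = [
    "ClassRatioPrior",
    "LossWeights",
    "LOSS_COMBINATIONS",
    "parse_ablation",
    "entropy_loss",
    "foreground_class_ratio",
    "shape_aware_loss",
    "refine_loss",
    "total_loss",
    "dice_loss",
]

#: clamp for voxel probabilities inside the entropy (keeps 0*log0 = 0 to ~1e-11
#: while bounding gradients)
_PROB_EPS = 1e-12
#: clamp for scalar class ratios before logarithms
_RATIO_EPS = 1e-6
#: Dice smoothing
_DICE_SMOOTH = 1e-5

#: The six ablation combinations: each is a frozenset of enabled terms.
LOSS_COMBINATIONS: Dict[str, frozenset] = {
    "en": frozenset({"en"}),
    "sh": frozenset({"sh"}),
    "re": frozenset({"re"}),
    "en+sh": frozenset({"en", "sh"}),
    "sh+re": frozenset({"sh", "re"}),
    "total": frozenset({"en", "sh", "re"}),
}


def parse_ablation(flag) -> frozenset:
    """Normalize an ablation flag ('en+sh', iterable, or frozenset)."""
    if isinstance(flag, str):
        if flag in LOSS_COMBINATIONS:
            return LOSS_COMBINATIONS[flag]
        parts = flag.split("+")
        if not all(p in ("en", "sh", "re") for p in parts):
            raise ValueError(f"unknown loss combination {flag!r}")
        key = "+".join(sorted(parts, key=("en", "sh", "re").index))
        if key not in LOSS_COMBINATIONS:
            raise ValueError(f"unknown loss combination {flag!r}")
        return LOSS_COMBINATIONS[key]
    terms = frozenset(flag)
    if not terms or not terms <= {"en", "sh", "re"}:
        raise ValueError(f"invalid loss term set {set(flag)!r}")
    return terms


@dataclass(frozen=True)
class ClassRatioPrior:
    """Mean foreground voxel fraction of the source training labels."""

    ratio: float

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio < 1.0:
            raise ValueError(f"class-ratio prior must lie in (0, 1), got {self.ratio}")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the entropy (lambda1) and shape (lambda2) terms.

    The refine term's weight is fixed at 1.
    """

    lambda1: float = 0.5
    lambda2: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


def _as_prob_tensor(prediction) -> Tensor:
    pred = prediction if isinstance(prediction, Tensor) else Tensor(np.asarray(prediction, dtype=float))
    if pred.size == 0:
        raise ValueError("empty prediction")
    data = pred.data
    if np.min(data) < 0.0 or np.max(data) > 1.0:
        raise ValueError(
            f"probabilities must lie in [0, 1]; got range "
            f"[{np.min(data)}, {np.max(data)}]"
        )
    return pred


def entropy_loss(prediction) -> Tensor:
    """Mean two-class Shannon entropy of the probability map, in [0, log 2]."""
    p = _as_prob_tensor(prediction).clip(_PROB_EPS, 1.0 - _PROB_EPS)
    q = 1.0 - p
    return (-(p * p.log() + q * q.log())).mean()


def foreground_class_ratio(prediction) -> Tensor:
    """Soft foreground fraction: the mean voxel probability."""
    return _as_prob_tensor(prediction).mean()


def _bernoulli_kl(a: Tensor, b: Tensor) -> Tensor:
    return a * (a.log() - b.log()) + (1.0 - a) * ((1.0 - a).log() - (1.0 - b).log())


def shape_aware_loss(prediction, prior: ClassRatioPrior) -> Tensor:
    """Symmetrized Bernoulli KL between predicted ratio and the prior.

    Zero iff the soft foreground ratio equals the prior; ratios are clamped
    to ``[1e-6, 1 - 1e-6]`` before the logarithms.
    """
    if not isinstance(prior, ClassRatioPrior):
        prior = ClassRatioPrior(float(prior))
    fs = foreground_class_ratio(prediction).clip(_RATIO_EPS, 1.0 - _RATIO_EPS)
    fhat = Tensor(np.clip(prior.ratio, _RATIO_EPS, 1.0 - _RATIO_EPS))
    return 0.5 * (_bernoulli_kl(fs, fhat) + _bernoulli_kl(fhat, fs))


def refine_loss(prediction, refine_model) -> Tensor:
    """Mean squared error between the prediction and its refined version.

    Gradients flow through both the direct and the refined path into the
    prediction; the refine model's own parameters receive no gradient (they
    are expected to be non-trainable at adaptation time).
    """
    pred = _as_prob_tensor(prediction)
    refined = refine_model(pred)
    flat_pred = pred.reshape(-1)
    flat_ref = refined.reshape(-1)
    if flat_pred.size != flat_ref.size:
        raise ValueError(
            f"refine output has {flat_ref.size} voxels, prediction has {flat_pred.size}"
        )
    return ((flat_ref - flat_pred) ** 2).mean()


def total_loss(
    prediction,
    prior: ClassRatioPrior,
    refine_model,
    weights: LossWeights = LossWeights(),
    ablation: Iterable[str] = ("en", "sh", "re"),
) -> Tuple[Tensor, Dict[str, float]]:
    """Weighted hybrid objective restricted to the enabled terms.

    Returns the scalar total and a per-term breakdown (unweighted values,
    plus the weighted ``total``).
    """
    terms = parse_ablation(ablation)
    breakdown: Dict[str, float] = {"L_en": 0.0, "L_sh": 0.0, "L_re": 0.0}
    total: Tensor | None = None

    def accumulate(value: Tensor, weight: float) -> None:
        nonlocal total
        contribution = weight * value
        total = contribution if total is None else total + contribution

    if "en" in terms:
        value = entropy_loss(prediction)
        breakdown["L_en"] = value.item()
        accumulate(value, weights.lambda1)
    if "sh" in terms:
        value = shape_aware_loss(prediction, prior)
        breakdown["L_sh"] = value.item()
        accumulate(value, weights.lambda2)
    if "re" in terms:
        value = refine_loss(prediction, refine_model)
        breakdown["L_re"] = value.item()
        accumulate(value, 1.0)
    assert total is not None
    breakdown["L_total"] = total.item()
    return total, breakdown


def dice_loss(prediction, label) -> Tensor:
    """Soft Dice loss ``1 - (2*sum(p*y) + s) / (sum(p) + sum(y) + s)``."""
    pred = prediction if isinstance(prediction, Tensor) else Tensor(np.asarray(prediction, dtype=float))
    y = np.asarray(label, dtype=float)
    if pred.shape not in (y.shape, (1,) + y.shape):
        raise ValueError(f"prediction shape {pred.shape} does not match label shape {y.shape}")
    flat = pred.reshape(-1)
    y_flat = Tensor(y.reshape(-1))
    intersection = (flat * y_flat).sum()
    denom = flat.sum() + y_flat.sum() + _DICE_SMOOTH
    return 1.0 - (2.0 * intersection + _DICE_SMOOTH) / denom
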