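"""Training and single-sample test-time adaptation.

The pipeline has four stages:

1. supervised source training of the segmenter with the Dice loss (all
   parameters trainable, batch size 1, SGD);
2. generation of "undertrained" segmentations: snapshots of an
   early-stopped training run predict on the training set, producing
   realistic broken masks paired with their ground-truth labels;
3. supervised training of the refine model to map broken masks to labels;
4. per-sample adaptation: starting fresh from the source checkpoint for
   every test volume, only the sub-band attention and batch-norm affine
   parameters are optimized for a fixed number of gradient steps on the
   hybrid unsupervised objective, then the adapted model segments the
   sample.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import losses as L
from . import metrics as M
from .models import RefineNet, WaVNet, partition_parameters
from .nn import SGD, no_grad

__all__ = [
    "SourceTrainingConfig",
    "UndertrainedSchedule",
    "TTAConfig",
    "SourceTrainingResult",
    "AdaptationResult",
    "AdaptationError",
    "train_source",
    "generate_undertrained_segmentations",
    "train_refine",
    "adapt_single_sample",
    "run_ablation",
    "trace_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SourceTrainingConfig:
    epochs: int = 2000
    batch_size: int = 1
    learning_rate: float = 5e-4
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size != 1:
            raise ValueError("training operates at batch size 1")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")


@dataclass(frozen=True)
class UndertrainedSchedule:
    stop_epochs: Tuple[int, ...] = (30, 40, 50, 60, 70, 80)

    def validate(self, total_epochs: int) -> None:
        if list(self.stop_epochs) != sorted(set(self.stop_epochs)):
            raise ValueError(f"stop epochs must be strictly increasing: {self.stop_epochs}")
        if not self.stop_epochs:
            raise ValueError("schedule is empty")
        if self.stop_epochs[-1] > total_epochs:
            raise ValueError(
                f"stop epoch {self.stop_epochs[-1]} exceeds the training length {total_epochs}"
            )


@dataclass(frozen=True)
class TTAConfig:
    iterations: int = 200
    learning_rate: float = 5e-4
    momentum: float = 0.0
    weights: L.LossWeights = field(default_factory=L.LossWeights)
    ablation: str = "total"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0 (0 = no-adaptation baseline)")


@dataclass
class SourceTrainingResult:
    state: Dict[str, np.ndarray]
    prior: L.ClassRatioPrior
    history: List[float]
    snapshots: Dict[int, Dict[str, np.ndarray]]


@dataclass
class AdaptationResult:
    prediction: np.ndarray
    baseline_prediction: np.ndarray
    adapted_state: Dict[str, np.ndarray]
    trace: List[Dict[str, float]]


class AdaptationError(RuntimeError):
    """Non-finite loss during training or adaptation."""


def compute_class_ratio_prior(labels: Sequence[np.ndarray]) -> L.ClassRatioPrior:
    """Mean of per-sample foreground voxel fractions over the labels."""
    ratios = [float(np.asarray(lbl, dtype=float).mean()) for lbl in labels]
    return L.ClassRatioPrior(float(np.mean(ratios)))


def train_source(
    model: WaVNet,
    volumes: Sequence[np.ndarray],
    labels: Sequence[np.ndarray],
    config: SourceTrainingConfig,
    snapshot_epochs: Sequence[int] = (),
) -> SourceTrainingResult:
    """Supervised Dice-loss training of the segmenter, batch size 1.

    ``snapshot_epochs`` captures deep copies of the parameter state after
    the given epochs (used to harvest undertrained models from a single
    seeded run).  With ``epochs == 0`` the returned state is the
    initialization; the class-ratio prior is computed regardless.
    """
    if len(volumes) == 0 or len(volumes) != len(labels):
        raise ValueError("need at least one labeled source sample")
    prior = compute_class_ratio_prior(labels)
    rng = np.random.default_rng(config.seed)
    optimizer = SGD(model.parameters(), lr=config.learning_rate, momentum=config.momentum)
    for p in model.parameters():
        p.requires_grad = True
    model.train()
    pyramids = [model.compute_pyramid(v) for v in volumes]

    history: List[float] = []
    snapshots: Dict[int, Dict[str, np.ndarray]] = {}
    snapshot_set = set(snapshot_epochs)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(volumes))
        epoch_losses = []
        for idx in order:
            pred = model.forward(volumes[idx], pyramid=pyramids[idx])
            loss = L.dice_loss(pred, labels[idx])
            value = loss.item()
            if not np.isfinite(value):
                raise AdaptationError(
                    f"non-finite Dice loss at epoch {epoch}, sample {idx}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)
        history.append(float(np.mean(epoch_losses)))
        logger.info("source epoch %d: dice loss %.4f", epoch, history[-1])
        if epoch in snapshot_set:
            snapshots[epoch] = model.state_dict()
    return SourceTrainingResult(
        state=model.state_dict(), prior=prior, history=history, snapshots=snapshots
    )


def generate_undertrained_segmentations(
    model: WaVNet,
    volumes: Sequence[np.ndarray],
    labels: Sequence[np.ndarray],
    schedule: UndertrainedSchedule,
    config: SourceTrainingConfig,
    snapshots: Optional[Dict[int, Dict[str, np.ndarray]]] = None,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """(noisy segmentation, label) pairs from early-stopped models.

    By default the snapshots come from a single seeded training run stopped
    at ``max(schedule)`` epochs; precomputed ``snapshots`` (e.g. from
    :func:`train_source`) are reused when given.  The corpus has
    ``len(schedule) * len(volumes)`` pairs.
    """
    schedule.validate(config.epochs if snapshots else max(schedule.stop_epochs))
    if snapshots is None:
        short = replace(config, epochs=max(schedule.stop_epochs))
        result = train_source(
            model, volumes, labels, short, snapshot_epochs=schedule.stop_epochs
        )
        snapshots = result.snapshots
    missing = [e for e in schedule.stop_epochs if e not in snapshots]
    if missing:
        raise ValueError(f"no snapshots for stop epochs {missing}")
    corpus: List[Tuple[np.ndarray, np.ndarray]] = []
    restore = model.state_dict()
    try:
        for epoch in schedule.stop_epochs:
            model.load_state_dict(snapshots[epoch])
            for vol, lbl in zip(volumes, labels):
                pred = model.predict(vol)
                corpus.append((pred, np.asarray(lbl, dtype=float)))
    finally:
        model.load_state_dict(restore)
    return corpus


def train_refine(
    refine_model: RefineNet,
    corpus: Sequence[Tuple[np.ndarray, np.ndarray]],
    epochs: int = 1000,
    learning_rate: float = 5e-4,
    momentum: float = 0.9,
    seed: int = 0,
) -> Dict[str, np.ndarray]:
    """MSE training of the refine model on (noisy mask, label) pairs."""
    if len(corpus) == 0:
        raise ValueError("refine corpus is empty")
    rng = np.random.default_rng(seed)
    optimizer = SGD(refine_model.parameters(), lr=learning_rate, momentum=momentum)
    refine_model.train()
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(corpus))
        epoch_losses = []
        for idx in order:
            noisy, label = corpus[idx]
            out = refine_model(noisy)
            diff = out.reshape(-1) - np.asarray(label, dtype=float).reshape(-1)
            loss = (diff**2).mean()
            value = loss.item()
            if not np.isfinite(value):
                raise AdaptationError(f"non-finite refine loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)
        logger.info("refine epoch %d: mse %.5f", epoch, float(np.mean(epoch_losses)))
    return refine_model.state_dict()


def adapt_single_sample(
    model: WaVNet,
    source_state: Dict[str, np.ndarray],
    prior: L.ClassRatioPrior,
    refine_model: RefineNet,
    test_volume: np.ndarray,
    config: TTAConfig,
) -> AdaptationResult:
    """Adapt the segmenter to one unlabeled volume and segment it.

    The model is reset to ``source_state`` first, so successive calls are
    independent.  Only the parameters in the adaptable partition (sub-band
    attention + batch-norm affine) are updated; every frozen parameter is
    bit-identical afterwards.  Batch-norm layers normalize with the test
    sample's own statistics during adaptation and for the final prediction;
    running buffers are never modified.  With ``iterations == 0`` the
    source model's (evaluation-mode) prediction is returned unchanged.
    """
    model.load_state_dict(source_state)
    baseline = model.predict(test_volume)
    if config.iterations == 0:
        return AdaptationResult(
            prediction=baseline,
            baseline_prediction=baseline,
            adapted_state=model.state_dict(),
            trace=[],
        )

    partition = partition_parameters(model)
    named = dict(model.named_parameters())
    for name, param in named.items():
        param.requires_grad = name in partition.adaptable
    refine_model.eval()
    for p in refine_model.parameters():
        p.requires_grad = False

    model.train()
    model.set_bn_running_updates(False)
    pyramid = model.compute_pyramid(test_volume)
    optimizer = SGD(
        [named[n] for n in sorted(partition.adaptable)],
        lr=config.learning_rate,
        momentum=config.momentum,
    )
    trace: List[Dict[str, float]] = []
    try:
        for iteration in range(config.iterations):
            pred = model.forward(test_volume, pyramid=pyramid)
            total, breakdown = L.total_loss(
                pred, prior, refine_model, config.weights, config.ablation
            )
            bad = [k for k, v in breakdown.items() if not np.isfinite(v)]
            if bad:
                raise AdaptationError(
                    f"non-finite loss term(s) {bad} at iteration {iteration}"
                )
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            row = {"iteration": float(iteration), **breakdown}
            trace.append(row)
            logger.info(
                "tta iter %d: en=%.5f sh=%.5f re=%.5f total=%.5f",
                iteration,
                breakdown["L_en"],
                breakdown["L_sh"],
                breakdown["L_re"],
                breakdown["L_total"],
            )
        prediction = model.predict(test_volume, pyramid=pyramid, use_batch_stats=True)
    finally:
        for param in model.parameters():
            param.requires_grad = True
        model.set_bn_running_updates(True)
    return AdaptationResult(
        prediction=prediction,
        baseline_prediction=baseline,
        adapted_state=model.state_dict(),
        trace=trace,
    )


def trace_to_frame(trace: List[Dict[str, float]]) -> pd.DataFrame:
    """Loss trace as a DataFrame (iteration, L_en, L_sh, L_re, L_total)."""
    return pd.DataFrame(trace, columns=["iteration", "L_en", "L_sh", "L_re", "L_total"])


def run_ablation(
    model: WaVNet,
    source_state: Dict[str, np.ndarray],
    prior: L.ClassRatioPrior,
    refine_model: RefineNet,
    test_samples: Sequence[Tuple[np.ndarray, np.ndarray]],
    config: TTAConfig,
    combinations: Sequence[str] = tuple(L.LOSS_COMBINATIONS),
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Adapt every sample under each loss combination; summary table.

    ``test_samples`` are (volume, label) pairs; the label is used only for
    evaluation.  Returns one row per combination with mean/SD DSC (%) and
    HD95 (mm).
    """
    rows = []
    for combo in combinations:
        per_sample = []
        for volume, label in test_samples:
            result = adapt_single_sample(
                model,
                source_state,
                prior,
                refine_model,
                volume,
                replace(config, ablation=combo),
            )
            pred_mask = M.binarize(result.prediction)
            per_sample.append(
                (
                    M.dice_coefficient(pred_mask, label),
                    M.hd95(pred_mask, label, spacing=spacing),
                )
            )
        summary = M.summarize(per_sample)
        rows.append(
            {
                "combination": combo,
                "dsc_mean": summary.dsc_mean,
                "dsc_sd": summary.dsc_sd,
                "hd95_mean": summary.hd95_mean,
                "hd95_sd": summary.hd95_sd,
                "n": summary.n_samples,
            }
        )
    return pd.DataFrame(rows)
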