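"""Training loop (focal loss + Adam) and evaluation metrics.

The focal loss ``FL(p_t) = −α_t (1 − p_t)^γ log p_t`` down-weights
well-classified samples (γ, the focusing exponent) and re-weights classes
(α, one weight per class), which counters class imbalance in voxel-wise
tissue classification.  With γ = 0 and uniform α it reduces to ordinary
cross-entropy, the default for balanced tasks.

Evaluation reports the confusion matrix, overall accuracy, per-class
accuracy (recall) and per-class Dice overlap — the standard segmentation
metrics.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "EvalReport",
    "focal_loss",
    "focal_loss_grad",
    "train",
    "evaluate",
]

_P_EPS = 1e-8  # clamp for log(p) in the focal loss


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.005
    epochs: int = 200
    focal_gamma: float = 0.0
    focal_alpha: tuple | None = None  # None = uniform weights of 1
    batch_size: int = 32
    seed: int = 0
    early_stop_class: int | None = None  # monitored class for validation recall
    patience: int = 5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")
        if self.focal_gamma < 0:
            raise ValueError("focal gamma must be >= 0")
        if self.focal_alpha is not None and any(
            not 0 < a <= 1 for a in self.focal_alpha
        ):
            raise ValueError("focal alpha entries must be in (0, 1]")


def _alpha_vector(alpha, n_classes: int) -> np.ndarray:
    if alpha is None:
        return np.ones(n_classes)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (n_classes,):
        raise ValueError("focal alpha must have one entry per class")
    return alpha


def focal_loss(
    probabilities: np.ndarray,
    labels: np.ndarray,
    gamma: float = 0.0,
    alpha=None,
) -> float:
    """Mean focal loss ``−α_t (1 − p_t)^γ log p_t`` over a batch.

    ``probabilities`` is (batch, n_classes) on the simplex (a single sample
    may be passed as a 1-d vector); ``p_t`` is clamped at 1e-8.
    """
    probabilities = np.atleast_2d(np.asarray(probabilities, dtype=float))
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    a = _alpha_vector(alpha, probabilities.shape[1])
    pt = np.clip(probabilities[np.arange(len(labels)), labels], _P_EPS, 1.0)
    return float(np.mean(-a[labels] * (1.0 - pt) ** gamma * np.log(pt)))


def focal_loss_grad(
    probabilities: np.ndarray, labels: np.ndarray, gamma: float, alpha=None
) -> np.ndarray:
    """Gradient of the mean focal loss w.r.t. the softmax logits.

    With ``g = dFL/dp_t = −α_t [ (1−p_t)^γ / p_t − γ (1−p_t)^{γ−1} log p_t ]``
    and softmax Jacobian ``dp_t/dz_j = p_t (δ_tj − p_j)``, the logit gradient
    is ``g · p_t (δ_tj − p_j) / batch``.  For γ = 0, α = 1 this is the familiar
    ``(p − onehot) / batch`` of cross-entropy.
    """
    p = np.atleast_2d(np.asarray(probabilities, dtype=float))
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    B, n = p.shape
    a = _alpha_vector(alpha, n)[labels]
    idx = np.arange(B)
    pt = np.clip(p[idx, labels], _P_EPS, 1.0)
    one_m = 1.0 - pt
    g = one_m**gamma / pt
    if gamma > 0:
        safe = np.where(one_m > 0, one_m, 1.0)
        g += -gamma * (one_m > 0) * safe ** (gamma - 1.0) * np.log(pt)
    g *= -a
    grad = g[:, None] * pt[:, None] * (-p)
    grad[idx, labels] += g * pt
    return grad / B


@dataclass
class EvalReport:
    confusion_matrix: np.ndarray
    overall_accuracy: float
    per_class_accuracy: list  # recall; None where the class is absent in truth
    per_class_dice: list

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion_matrix.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "per_class_dice": self.per_class_dice,
        }


def evaluate(model, features: np.ndarray, labels: np.ndarray, n_classes: int | None = None) -> EvalReport:
    """Confusion matrix, overall accuracy, per-class recall and Dice.

    ``recall_c = TP_c / (TP_c + FN_c)``; ``Dice_c = 2 TP_c / (2 TP_c + FP_c +
    FN_c)``.  A class absent from the truth gets recall ``None`` (undefined)
    rather than 0.
    """
    labels = np.asarray(labels, dtype=int)
    preds = predict(model, features)
    n = n_classes if n_classes is not None else int(max(labels.max(), preds.max())) + 1
    cm = np.zeros((n, n), dtype=int)
    np.add.at(cm, (labels, preds), 1)
    overall = float(np.trace(cm)) / float(cm.sum())
    recall, dice = [], []
    for c in range(n):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        recall.append(float(tp / (tp + fn)) if (tp + fn) > 0 else None)
        denom = 2 * tp + fp + fn
        dice.append(float(2 * tp / denom) if denom > 0 else None)
    return EvalReport(cm, overall, recall, dice)


def predict(model, features: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Argmax class predictions, computed in chunks."""
    out = []
    for lo in range(0, len(features), chunk):
        probs, _ = model.forward_batch(features[lo : lo + chunk])
        out.append(probs.argmax(axis=1))
    return np.concatenate(out)


class _Adam:
    """Adam with the standard defaults (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def train(
    model,
    features: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    validation: tuple | None = None,
) -> list[dict]:
    """Seeded minibatch focal-loss training with Adam.

    ``features`` is the model's featurized input (the resampling onto the
    chart is a fixed linear map, so it is precomputed once).  Returns the
    per-epoch history (loss, and validation metrics when a validation set is
    given).  When ``config.early_stop_class`` is set, training stops once the
    monitored class's validation recall has not improved for
    ``config.patience`` epochs.
    """
    labels = np.asarray(labels, dtype=int)
    if len(features) == 0:
        raise ValueError("empty training set")
    if len(features) != len(labels):
        raise ValueError("features and labels length mismatch")
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate)
    history: list[dict] = []
    best_monitor, since_best = -np.inf, 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(labels))
        losses = []
        for lo in range(0, len(order), config.batch_size):
            sel = order[lo : lo + config.batch_size]
            probs, cache = model.forward_batch(features[sel])
            losses.append(
                focal_loss(probs, labels[sel], config.focal_gamma, config.focal_alpha)
            )
            grad = focal_loss_grad(
                probs, labels[sel], config.focal_gamma, config.focal_alpha
            )
            opt.step(model.params, model.backward_batch(cache, grad))
        rec = {"epoch": epoch, "loss": float(np.mean(losses))}
        if validation is not None:
            rep = evaluate(model, validation[0], np.asarray(validation[1], dtype=int))
            rec["val_accuracy"] = rep.overall_accuracy
            rec["val_per_class_accuracy"] = rep.per_class_accuracy
        history.append(rec)
        logger.debug("epoch %d loss %.5f", epoch, rec["loss"])
        if config.early_stop_class is not None:
            if validation is None:
                raise ValueError("early stopping requires a validation set")
            monitor = rec["val_per_class_accuracy"][config.early_stop_class]
            monitor = -np.inf if monitor is None else monitor
            if monitor > best_monitor:
                best_monitor, since_best = monitor, 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    logger.info("early stop at epoch %d", epoch)
                    break
    return history


def write_history_csv(history: list[dict], path: str) -> None:
    """Per-epoch training log as CSV."""
    if not history:
        return
    keys = list(history[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        for rec in history:
            writer.writerow({k: rec.get(k) for k in keys})
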