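"""Semi-supervised classification of behavior segments.

A fully connected softmax head sits on top of the encoder's latent vector.
Re-training after each annotation round minimizes

    CE(labeled segments) + lambda * reconstruction MSE(all train segments)

jointly over encoder, decoder and classifier, so the sparse annotations
reshape the latent space while the reconstruction term keeps it anchored to
the movement dynamics of the unlabeled pool.  ``reconstruction_weight = 0``
recovers plain fine-tuning of encoder + classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SegmentDataset
from .model import TrainedModel
from .nn import Adam, masked_mse, masked_mse_grad

__all__ = [
    "ClassifierConfig",
    "Prediction",
    "train_semisupervised",
    "classify",
    "accuracy",
    "confusion_matrix",
    "write_predictions",
]


@dataclass
class ClassifierConfig:
    """Settings for the classifier head and the joint re-training step."""

    hidden: tuple[int, ...] = (128,)
    epochs: int = 60
    learning_rate: float = 3e-3
    reconstruction_weight: float = 1.0  # lambda; 0 = pure fine-tuning
    batch_size: int = 64
    class_weighting: bool = False  # inverse-frequency CE weights
    freeze_decoder: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.reconstruction_weight < 0:
            raise ValueError("reconstruction_weight must be >= 0")
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training settings")


@dataclass
class Prediction:
    """Class posteriors and argmax labels for a set of segments."""

    class_probs: np.ndarray  # N x C, rows sum to 1
    predicted: np.ndarray  # length N; ties broken toward the lowest index
    segment_ids: list[str]

    def __post_init__(self) -> None:
        p = np.asarray(self.class_probs, dtype=np.float64)
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities outside [0, 1]")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("probability rows must sum to 1")
        self.class_probs = p
        self.predicted = np.asarray(self.predicted, dtype=int)


def train_semisupervised(
    model: TrainedModel,
    dataset: SegmentDataset,
    config: ClassifierConfig,
) -> TrainedModel:
    """Re-train encoder (+decoder) with the classifier on current labels.

    Requires at least one labeled segment; warns when only one distinct
    class is labeled.  Appends per-epoch cross-entropy and reconstruction
    losses to ``model.history``; runs are reproducible under
    ``config.seed`` (which also initializes the head on first call).
    """
    config.validate()
    labeled = dataset.labeled_mask
    if not labeled.any():
        raise ValueError(
            "no labeled segments; run an active-learning selection and "
            "annotate before training the classifier"
        )
    labels = dataset.labels
    uniq = np.unique(labels[labeled])
    if uniq.size < 2:
        warnings.warn(
            "only one distinct class is labeled; the classifier cannot "
            "discriminate yet"
        )
    rng = np.random.default_rng(config.seed)
    if model.classifier is None:
        model.classifier_hidden = tuple(config.hidden)
        model.add_classifier(dataset.n_classes, rng)

    ce_weights = np.ones(dataset.n_classes)
    if config.class_weighting:
        counts = np.bincount(labels[labeled], minlength=dataset.n_classes)
        ce_weights = np.where(counts > 0, labeled.sum() / np.maximum(counts, 1), 0.0)
        ce_weights *= (counts > 0).sum() / max(ce_weights[counts > 0].sum(), 1e-12)

    lam = config.reconstruction_weight
    X, mask = dataset.padded_arrays()
    target = model._target(X, mask)
    opt = Adam(
        model.params(include_decoder=(lam > 0 and not config.freeze_decoder)),
        lr=config.learning_rate,
        grad_clip=model.config.grad_clip,
    )
    N = X.shape[0]
    model.history.setdefault("cross_entropy", [])
    model.history.setdefault("semisupervised_reconstruction", [])
    for _ in range(config.epochs):
        order = rng.permutation(N)
        ce_sum = ce_n = 0.0
        rec_losses, rec_w = [], []
        for start in range(0, N, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, mb, tb = X[idx], mask[idx], target[idx]
            lab_rows = np.flatnonzero(labeled[idx])
            opt.zero_grad()
            z = model.encoder.forward(xb, mb)
            dz = np.zeros_like(z)
            if lam > 0:
                y = model.decoder.forward_cond(z, model.decoder_inputs(tb), mb)
                rec = masked_mse(y, tb, mb)
                dz += model.decoder.backward(lam * masked_mse_grad(y, tb, mb))
                rec_losses.append(rec)
                rec_w.append(len(idx))
            if lam > 0 and config.freeze_decoder:
                for p in model.decoder.params("dec").values():
                    p.zero_grad()  # frozen: keep unused accumulators clean
            if lab_rows.size:
                yl = labels[idx][lab_rows]
                probs = model.classifier.forward(z[lab_rows])
                w = ce_weights[yl]
                ce = float(-(w * np.log(probs[np.arange(len(yl)), yl] + 1e-300)).mean())
                dz_l = _weighted_ce_backward(model.classifier, probs, yl, w)
                dz[lab_rows] += dz_l
                ce_sum += ce * len(yl)
                ce_n += len(yl)
            if not np.isfinite(dz).all():
                raise FloatingPointError("non-finite gradients; lower the learning rate")
            model.encoder.backward(dz)
            opt.step()
        model.history["cross_entropy"].append(ce_sum / max(ce_n, 1))
        model.history["semisupervised_reconstruction"].append(
            float(np.average(rec_losses, weights=rec_w)) if rec_losses else 0.0
        )
    return model


def _weighted_ce_backward(head, probs, labels, weights):
    """Gradient of mean weighted CE through the classifier head."""
    n = probs.shape[0]
    dlogits = probs * weights[:, None]
    dlogits[np.arange(n), labels] -= weights
    dlogits /= n
    da = head.linears[-1].backward(dlogits)
    for l, pre in zip(reversed(head.linears[:-1]), reversed(head._relu_in)):
        da = da * (pre > 0)
        da = l.backward(da)
    return da


def classify(model: TrainedModel, dataset: SegmentDataset) -> Prediction:
    """Predict behavior classes for every segment (deterministic)."""
    if model.classifier is None:
        raise ValueError(
            "model has no classifier head; run train_semisupervised first"
        )
    z = model.encode(dataset)
    probs = model.classifier.forward(z.values)
    # np.argmax returns the first maximum -> ties break toward lowest index
    predicted = np.argmax(probs, axis=1)
    return Prediction(probs, predicted, dataset.segment_ids)


def accuracy(pred: Prediction | np.ndarray, truth: np.ndarray) -> float:
    """Percentage of segments assigned their ground-truth class, in [0, 100]."""
    yhat = pred.predicted if isinstance(pred, Prediction) else np.asarray(pred)
    truth = np.asarray(truth)
    if yhat.shape[0] != truth.shape[0]:
        raise ValueError("prediction/truth length mismatch")
    return 100.0 * float(np.mean(yhat == truth))


def confusion_matrix(
    pred: Prediction | np.ndarray, truth: np.ndarray, n_classes: int
) -> np.ndarray:
    """C x C count matrix; rows index the true class, columns the predicted."""
    yhat = pred.predicted if isinstance(pred, Prediction) else np.asarray(pred)
    truth = np.asarray(truth)
    if yhat.shape[0] != truth.shape[0]:
        raise ValueError("prediction/truth length mismatch")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (truth, yhat), 1)
    return cm


def write_predictions(
    pred: Prediction, class_names: list[str], path
) -> None:
    """Predictions CSV: segment_id, predicted class name, one prob per class."""
    df = pd.DataFrame(
        {
            "segment_id": pred.segment_ids,
            "predicted_class_name": [class_names[i] for i in pred.predicted],
        }
    )
    for ci, cname in enumerate(class_names):
        df[f"p_{cname}"] = pred.class_probs[:, ci]
    df.to_csv(path, index=False)
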