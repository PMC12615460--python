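"""Encoder-decoder sequence model for unsupervised segment clustering.

The encoder is a (stack of) bidirectional GRU layer(s) that reads a keypoint
segment frame by frame; the concatenated final hidden states of the two
directions, linearly mapped to m dimensions, are the segment's latent vector.
The decoder is a unidirectional GRU initialized from the latent that
reconstructs the input sequence; by default it is input-free (fixed-state
decoding: the latent alone drives reconstruction), with classic teacher
forcing available as a config option.  Unsupervised pretraining minimizes
the mean squared
reconstruction error over valid (unpadded) frames, which organizes the
latent space so that segments with similar movement dynamics land close
together — the source of the Cluster Map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data import PreprocessStats, SegmentDataset
from .nn import (
    Adam,
    BiGRUEncoder,
    ClassifierHead,
    GRUDecoder,
    masked_mse,
    masked_mse_grad,
    reverse_valid,
)

__all__ = [
    "ModelConfig",
    "LatentMatrix",
    "TrainedModel",
    "pretrain",
    "encode",
    "reconstruct",
    "reconstruction_loss",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the sequence autoencoder.

    ``latent_dim`` is the dimension m of the latent representation;
    ``hidden_size`` is the per-direction GRU width (the latent projection
    maps the 2*hidden_size concatenated final states to m).
    ``reversed_output`` makes the decoder reconstruct the sequence in
    reverse time order instead of input order.  ``decoder_conditioning``
    picks how the decoder is driven during training: ``"zeros"``
    (input-free / fixed-state decoding — the latent alone must carry the
    whole segment, which markedly improves how well the latent space
    clusters) or ``"teacher"`` (classic teacher forcing on the previous
    true frame).
    """

    input_dim: int
    latent_dim: int = 64
    hidden_size: int = 32
    decoder_hidden: int = 64
    encoder_layers: int = 1
    decoder_layers: int = 1
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    reversed_output: bool = False
    decoder_conditioning: str = "zeros"
    grad_clip: float = 5.0

    def validate(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        for name in ("input_dim", "hidden_size", "decoder_hidden",
                     "encoder_layers", "decoder_layers", "epochs", "batch_size"):
            if getattr(self, name) < (0 if name == "epochs" else 1):
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.decoder_conditioning not in ("zeros", "teacher"):
            raise ValueError(
                "decoder_conditioning must be 'zeros' or 'teacher', "
                f"got {self.decoder_conditioning!r}"
            )


@dataclass
class LatentMatrix:
    """Per-segment latent vectors (N x m), rows aligned with segment_ids."""

    values: np.ndarray
    segment_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.segment_ids):
            raise ValueError("row count does not match segment_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite latent entries")


class TrainedModel:
    """Encoder-decoder parameters (+ optional classifier head) and the
    preprocessing statistics needed to reproduce encodings."""

    def __init__(
        self,
        config: ModelConfig,
        stats: PreprocessStats | None = None,
        n_classes: int | None = None,
        classifier_hidden: tuple[int, ...] = (128,),
        rng: np.random.Generator | None = None,
    ):
        config.validate()
        self.config = config
        self.stats = stats
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.encoder = BiGRUEncoder(
            rng, config.input_dim, config.hidden_size, config.latent_dim,
            config.encoder_layers,
        )
        self.decoder = GRUDecoder(
            rng, config.input_dim, config.decoder_hidden, config.latent_dim,
            config.decoder_layers,
        )
        self.classifier: ClassifierHead | None = None
        self.classifier_hidden = tuple(classifier_hidden)
        self.n_classes = n_classes
        if n_classes is not None:
            self.classifier = ClassifierHead(
                rng, config.latent_dim, n_classes, self.classifier_hidden
            )
        self.history: dict[str, list[float]] = {"reconstruction": []}

    # -- parameter plumbing -------------------------------------------------
    def params(self, include_decoder: bool = True, include_classifier: bool = True):
        out = dict(self.encoder.params("enc"))
        if include_decoder:
            out.update(self.decoder.params("dec"))
        if include_classifier and self.classifier is not None:
            out.update(self.classifier.params("cls"))
        return out

    def add_classifier(self, n_classes: int, rng: np.random.Generator) -> None:
        if self.classifier is None:
            self.n_classes = n_classes
            self.classifier = ClassifierHead(
                rng, self.config.latent_dim, n_classes, self.classifier_hidden
            )

    # -- inference ----------------------------------------------------------
    def _check_input(self, dataset: SegmentDataset) -> None:
        if dataset.n_features != self.config.input_dim:
            raise ValueError(
                f"feature count mismatch: model expects F={self.config.input_dim}, "
                f"dataset has F={dataset.n_features}"
            )

    def encode(self, dataset: SegmentDataset) -> LatentMatrix:
        """Map each segment to its latent vector (deterministic)."""
        self._check_input(dataset)
        X, mask = dataset.padded_arrays()
        z = self.encoder.forward(X, mask)
        return LatentMatrix(z, dataset.segment_ids)

    def decoder_inputs(self, target: np.ndarray) -> np.ndarray:
        """Per-step decoder inputs under the configured conditioning."""
        if self.config.decoder_conditioning == "zeros":
            return np.zeros_like(target)
        return self.decoder.teacher_inputs(target)

    def reconstruct(self, dataset: SegmentDataset) -> tuple[np.ndarray, np.ndarray]:
        """Inference-time reconstruction; returns (N, T_max, F) and the mask.

        Input-free conditioning decodes from the latent alone (as in
        training); teacher conditioning runs the decoder free-running on
        its own outputs, since the true frames are not fed at inference.
        """
        self._check_input(dataset)
        X, mask = dataset.padded_arrays()
        z = self.encoder.forward(X, mask)
        if self.config.decoder_conditioning == "zeros":
            y = self.decoder.forward_cond(z, np.zeros_like(X), mask)
        else:
            y = self.decoder.forward_free(z, X.shape[1])
        return y, mask

    def reconstruction_loss(self, dataset: SegmentDataset) -> float:
        """Masked MSE between the free-running reconstruction and the input."""
        X, mask = dataset.padded_arrays()
        y, _ = self.reconstruct(dataset)
        target = self._target(X, mask)
        return masked_mse(y, target, mask)

    def _target(self, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        if not self.config.reversed_output:
            return X
        lengths = mask.sum(axis=1).astype(int)
        return reverse_valid(X, lengths)


def pretrain(
    dataset: SegmentDataset,
    config: ModelConfig,
    stats: PreprocessStats | None = None,
) -> TrainedModel:
    """Unsupervised pretraining of the encoder-decoder.

    Minimizes masked reconstruction MSE with Adam; every
    source of randomness (weight init, shuffling) derives from
    ``config.seed``, so identical calls give identical histories.  With
    ``epochs=0`` the model is returned freshly initialized with an empty
    history.
    """
    if not dataset.segments:
        raise ValueError("cannot pretrain on an empty dataset")
    config.validate()
    if config.input_dim != dataset.n_features:
        raise ValueError(
            f"config.input_dim={config.input_dim} but dataset F={dataset.n_features}"
        )
    rng = np.random.default_rng(config.seed)
    model = TrainedModel(config, stats=stats, rng=rng)
    model.history = {"reconstruction": []}
    if config.epochs == 0:
        return model
    X, mask = dataset.padded_arrays()
    target = model._target(X, mask)
    opt = Adam(model.params(include_classifier=False), lr=config.learning_rate,
               grad_clip=config.grad_clip)
    N = X.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(N)
        losses, weights = [], []
        for start in range(0, N, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, mb, tb = X[idx], mask[idx], target[idx]
            opt.zero_grad()
            z = model.encoder.forward(xb, mb)
            y = model.decoder.forward_cond(z, model.decoder_inputs(tb), mb)
            loss = masked_mse(y, tb, mb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "non-finite reconstruction loss; lower the learning rate"
                )
            dz = model.decoder.backward(masked_mse_grad(y, tb, mb))
            model.encoder.backward(dz)
            opt.step()
            losses.append(loss)
            weights.append(len(idx))
        model.history["reconstruction"].append(
            float(np.average(losses, weights=weights))
        )
    return model


# Functional wrappers mirroring the method surface --------------------------

def encode(model: TrainedModel, dataset: SegmentDataset) -> LatentMatrix:
    return model.encode(dataset)


def reconstruct(model: TrainedModel, dataset: SegmentDataset) -> np.ndarray:
    return model.reconstruct(dataset)[0]


def reconstruction_loss(model: TrainedModel, dataset: SegmentDataset) -> float:
    return model.reconstruction_loss(dataset)


# ---------------------------------------------------------------------------
# Checkpointing

_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize parameters + config + stats + history to one .npz archive."""
    arrays = {f"param::{k}": p.value for k, p in model.params().items()}
    meta = {
        "format_version": _FORMAT_VERSION,
        "config": asdict(model.config),
        "n_classes": model.n_classes,
        "classifier_hidden": list(model.classifier_hidden),
        "history": model.history,
        "stats": None
        if model.stats is None
        else {
            "mean": model.stats.mean.tolist(),
            "std": model.stats.std.tolist(),
            "max_length": model.stats.max_length,
            "mode": model.stats.mode,
            "constant_features": model.stats.constant_features.tolist(),
        },
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(Path(path), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    """Restore a checkpoint; encodings of the restored model are bit-identical
    to the saved one."""
    with np.load(Path(path)) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode("utf-8"))
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        config = ModelConfig(**meta["config"])
        stats = None
        if meta["stats"] is not None:
            s = meta["stats"]
            stats = PreprocessStats(
                mean=np.array(s["mean"]),
                std=np.array(s["std"]),
                max_length=s["max_length"],
                mode=s["mode"],
                constant_features=np.array(s["constant_features"], dtype=int),
            )
        model = TrainedModel(
            config,
            stats=stats,
            n_classes=meta["n_classes"],
            classifier_hidden=tuple(meta["classifier_hidden"]),
        )
        model.history = meta["history"]
        params = model.params()
        for k, p in params.items():
            p.value[...] = npz[f"param::{k}"]
    return model
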