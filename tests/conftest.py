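"""Shared fixtures: small synthetic datasets and a quickly pretrained model.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk.
"""

import numpy as np
import pytest

import ethoclust as ec


@pytest.fixture(scope="session")
def tiny_config():
    # 3 classes x 15 segments of 10 frames, 3 keypoints: fast but non-trivial
    return ec.SynthConfig(
        n_classes=3,
        segments_per_class=15,
        frames=10,
        keypoints=3,
        noise_sd=0.05,
        length_jitter=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return ec.generate(tiny_config)


@pytest.fixture(scope="session")
def tiny_prepared(tiny_dataset):
    train, test = tiny_dataset
    train_p, stats = ec.preprocess(train)
    test_p = ec.apply_preprocess(test, stats)
    return train_p, test_p, stats


@pytest.fixture(scope="session")
def tiny_model_config(tiny_prepared):
    train_p, _, _ = tiny_prepared
    return ec.ModelConfig(
        input_dim=train_p.n_features,
        latent_dim=16,
        hidden_size=8,
        decoder_hidden=16,
        epochs=12,
        batch_size=16,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_prepared, tiny_model_config):
    train_p, _, stats = tiny_prepared
    return ec.pretrain(train_p, tiny_model_config, stats=stats)


def make_segments(arrays, class_names=("a", "b"), labels=None, split="train"):
    """Build a SegmentDataset from a list of T x F arrays."""
    segs = []
    for i, arr in enumerate(arrays):
        segs.append(
            ec.KeypointSegment(
                frames=np.asarray(arr, dtype=float),
                segment_id=f"s{i:03d}",
                label=None if labels is None else labels[i],
            )
        )
    return ec.SegmentDataset(segs, list(class_names), split)
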