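"""Synthetic labeled keypoint segments for end-to-end testing.

The generator emulates the statistical shape of real pose-tracking
datasets — N temporal segments of T frames, K keypoints in D coordinates,
C behavior classes — without any biomechanical realism.  Each class c is a
distinct motion primitive: a class-specific base pose plus per-keypoint
sinusoidal motion

    x_{k,d}(t) = base_{c,k,d} + A_c * sin(2*pi*f_c*t/T + phi_{c,k,d})
                 + drift_c * t/T + eps,   eps ~ N(0, sigma^2)

so classes differ in oscillation frequency, amplitude, drift and pose.
Each segment additionally receives a random global phase offset (the clip
starts at an arbitrary point of the movement cycle), a random in-plane
rotation and translation (body-orientation and position nuisance the
encoder must absorb) and optional length jitter.  Everything derives from one seed, so
identical configs give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data import KeypointSegment, SegmentDataset

__all__ = ["SynthConfig", "generate", "separability_report", "truth_oracle"]


@dataclass
class SynthConfig:
    """Shape and noise parameters of the synthetic behavior dataset.

    Defaults give 4 classes x 250 segments of 20 frames with 8 keypoints in
    2-D (F = 16), frame noise sd 0.1, random segment rotation/translation
    and +-3 frames of length jitter; the 80/20 stratified split yields 800
    train and 200 test segments.
    """

    n_classes: int = 4
    segments_per_class: int = 250
    frames: int = 20
    keypoints: int = 8
    dims: int = 2
    noise_sd: float = 0.1
    length_jitter: int = 3
    rotation: bool = True
    translation_sd: float = 0.5
    phase_jitter: bool = True  # per-segment global phase offset
    train_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_classes", "segments_per_class", "frames", "keypoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.noise_sd < 0 or self.length_jitter < 0 or self.translation_sd < 0:
            raise ValueError("noise_sd, length_jitter, translation_sd must be >= 0")
        if self.length_jitter >= self.frames:
            raise ValueError("length_jitter must be smaller than frames")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")

    @property
    def n_features(self) -> int:
        return self.keypoints * self.dims


def _class_params(config: SynthConfig, rng: np.random.Generator):
    """Deterministic per-class motion primitives (from the dataset seed)."""
    C, K, D = config.n_classes, config.keypoints, config.dims
    # base pose: keypoints on a circle, radius varying per class
    angles = 2 * np.pi * np.arange(K) / K
    base = np.zeros((C, K, D))
    for c in range(C):
        radius = 1.0 + 0.3 * c
        base[c, :, 0] = radius * np.cos(angles)
        base[c, :, 1] = radius * np.sin(angles)
        if D == 3:
            base[c, :, 2] = 0.2 * c
    freq = 0.5 + np.arange(C)  # cycles per segment: 0.5, 1.5, 2.5, ...
    amp = 0.6 + 0.2 * np.arange(C)
    drift = 0.4 * (np.arange(C) - (C - 1) / 2.0)
    phase = rng.uniform(0, 2 * np.pi, size=(C, K, D))
    return base, freq, amp, drift, phase


def _make_segment(
    config: SynthConfig,
    c: int,
    params,
    rng: np.random.Generator,
    apply_rotation: bool = True,
) -> np.ndarray:
    base, freq, amp, drift, phase = params
    T = config.frames
    if config.length_jitter:
        T = T + int(rng.integers(-config.length_jitter, config.length_jitter + 1))
    t = np.arange(T)[:, None, None]  # T x 1 x 1
    phase_off = rng.uniform(0, 2 * np.pi) if config.phase_jitter else 0.0
    traj = (
        base[c][None]
        + amp[c] * np.sin(
            2 * np.pi * freq[c] * t / config.frames + phase[c][None] + phase_off
        )
        + drift[c] * t / config.frames
    )  # T x K x D
    if apply_rotation and config.rotation:
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        traj[..., :2] = traj[..., :2] @ rot.T  # x-y plane only for D=3
    if config.translation_sd:
        traj += rng.normal(0, config.translation_sd, size=(1, 1, config.dims))
    if config.noise_sd:
        traj += rng.normal(0, config.noise_sd, size=traj.shape)
    return traj.reshape(T, config.n_features)  # keypoint-major x1,y1,x2,y2,...


def generate(config: SynthConfig) -> tuple[SegmentDataset, SegmentDataset]:
    """Generate labeled (train, test) splits, stratified per class."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = _class_params(config, rng)
    class_names = [f"behavior_{c}" for c in range(config.n_classes)]
    train_segs: list[KeypointSegment] = []
    test_segs: list[KeypointSegment] = []
    for c in range(config.n_classes):
        n = config.segments_per_class
        n_train = int(round(config.train_fraction * n))
        for j in range(n):
            frames = _make_segment(config, c, params, rng)
            seg = KeypointSegment(
                frames=frames,
                segment_id=f"synth_c{c}_s{j:04d}",
                label=c,
            )
            (train_segs if j < n_train else test_segs).append(seg)
    # interleave classes in dataset order via a seeded shuffle
    order_rng = np.random.default_rng(config.seed + 1)
    order_rng.shuffle(train_segs)
    order_rng.shuffle(test_segs)
    fnames = [
        f"kp{k}_{'xyz'[d]}" for k in range(config.keypoints) for d in range(config.dims)
    ]
    train = SegmentDataset(train_segs, class_names, "train", feature_names=fnames)
    test = SegmentDataset(test_segs, class_names, "test", feature_names=fnames)
    return train, test


def truth_oracle(dataset: SegmentDataset):
    """Ground-truth label provider for the annotation loop (tests/demos).

    Captures the dataset's labels before they are hidden; call on the
    labeled dataset, then run the loop on ``dataset.without_labels()``.
    """
    truth = dataset.labels.copy()
    if np.any(truth < 0):
        raise ValueError("oracle requires a fully labeled dataset")

    def oracle(i: int) -> int:
        return int(truth[i])

    return oracle


def _flatten_padded(dataset: SegmentDataset) -> np.ndarray:
    X, mask = dataset.padded_arrays()
    return (X * mask[:, :, None]).reshape(X.shape[0], -1)


def separability_report(dataset: SegmentDataset) -> dict:
    """Mean within- vs between-class distances of flattened segments.

    With zero noise and rotations disabled every between-class mean exceeds
    every within-class mean; rising noise shrinks that gap.  Single-class
    datasets have no between-class term (reported as None).
    """
    flat = _flatten_padded(dataset)
    labels = dataset.labels
    classes = np.unique(labels[labels >= 0])
    within = {}
    for c in classes:
        pts = flat[labels == c]
        if pts.shape[0] < 2:
            within[int(c)] = 0.0
            continue
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        within[int(c)] = float(d[np.triu_indices(pts.shape[0], 1)].mean())
    between = {}
    for a, b in combinations(classes, 2):
        pa, pb = flat[labels == a], flat[labels == b]
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        between[(int(a), int(b))] = float(d.mean())
    mean_within = float(np.mean(list(within.values()))) if within else None
    mean_between = float(np.mean(list(between.values()))) if between else None
    separable = (
        all(
            between[(a, b)] > max(within[a], within[b])
            for (a, b) in between
        )
        if between
        else None
    )
    return {
        "within": within,
        "between": between,
        "mean_within": mean_within,
        "mean_between": mean_between,
        "separable": separable,
    }
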