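"""Active-learning selection strategies and the annotation loop.

Three strategies choose which unlabeled segments an annotator should label
next, all operating on the encoder's latent vectors:

* ``top`` (cluster centers): k-means over the unlabeled latents, then the
  actual sample nearest each centroid — representative picks, useful before
  any classifier exists.
* ``cs`` (core-set): greedy k-center / farthest-first traversal, choosing
  the point whose distance to the labeled-plus-chosen set is largest, so the
  chosen set covers the pool with minimal radius.
* ``mi`` (margin/uncertainty): smallest gap between the top-two class
  posteriors of the current classifier.

``random`` uniform sampling is the baseline.  The loop alternates
selection -> annotation -> semi-supervised re-training -> re-encoding until
the annotation budget is spent, recording test accuracy each iteration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.cluster import KMeans

from .classify import ClassifierConfig, accuracy, classify, train_semisupervised
from .data import SegmentDataset
from .model import LatentMatrix, ModelConfig, TrainedModel, pretrain

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "ALConfig",
    "select_top",
    "select_coreset",
    "select_mi",
    "select_random",
    "al_loop",
    "ALHistory",
]

STRATEGIES = ("top", "cs", "mi", "random")


@dataclass
class SelectionResult:
    """Ordered indices chosen for annotation (disjoint from labeled set)."""

    chosen: list[int]
    strategy: str
    iteration: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        if len(set(self.chosen)) != len(self.chosen):
            raise ValueError("chosen indices must be unique")


@dataclass
class ALConfig:
    """Annotation-budget schedule for the iterative loop.

    ``budget_fractions`` are cumulative fractions of the train split to be
    labeled after each stage (defaults 5%, 10%, 20%); each stage may be
    split into several selection/annotation/training iterations.
    """

    strategy: str = "mi"
    budget_fractions: tuple[float, ...] = (0.05, 0.10, 0.20)
    iterations_per_budget: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        fr = self.budget_fractions
        if not fr or any(not (0 < f <= 1) for f in fr):
            raise ValueError("budget fractions must lie in (0, 1]")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("budget fractions must be strictly increasing")
        if self.iterations_per_budget < 1:
            raise ValueError("iterations_per_budget must be >= 1")


def _unlabeled_indices(n: int, labeled) -> np.ndarray:
    labeled = np.asarray(sorted(set(int(i) for i in labeled)), dtype=int)
    mask = np.ones(n, dtype=bool)
    if labeled.size:
        mask[labeled] = False
    return np.flatnonzero(mask)


def _clamp_k(k: int, available: int) -> int:
    if k < 1:
        raise ValueError("k must be positive")
    if k > available:
        warnings.warn(
            f"requested k={k} exceeds {available} unlabeled segments; clamping"
        )
        return available
    return k


def select_top(
    latents: LatentMatrix | np.ndarray,
    labeled,
    k: int,
    seed: int = 0,
    iteration: int = 0,
) -> SelectionResult:
    """Cluster-center selection: one representative per k-means cluster.

    k-means (k-means++ init, 10 restarts, seeded) runs on the unlabeled
    latents; each cluster contributes its member with minimal Euclidean
    distance to the centroid (ties toward the lowest dataset index).
    Results are ordered by cluster id; should a cluster come back empty its
    slot is filled with the unchosen point nearest any centroid.
    """
    Z = latents.values if isinstance(latents, LatentMatrix) else np.asarray(latents)
    pool = _unlabeled_indices(Z.shape[0], labeled)
    k = _clamp_k(k, pool.size)
    Zp = Z[pool]
    if k == pool.size:
        return SelectionResult(list(pool), "top", iteration)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    assign = km.fit_predict(Zp)
    chosen: list[int] = []
    for c in range(k):
        members = np.flatnonzero(assign == c)
        if members.size == 0:
            continue
        d = np.linalg.norm(Zp[members] - km.cluster_centers_[c], axis=1)
        chosen.append(int(pool[members[int(np.argmin(d))]]))
    if len(chosen) < k:  # rare: empty k-means cluster(s)
        remaining = np.setdiff1d(pool, chosen)
        d_any = np.min(
            np.linalg.norm(
                Z[remaining][:, None, :] - km.cluster_centers_[None, :, :], axis=2
            ),
            axis=1,
        )
        fill = remaining[np.argsort(d_any, kind="stable")][: k - len(chosen)]
        chosen.extend(int(i) for i in fill)
    return SelectionResult(chosen, "top", iteration)


def select_coreset(
    latents: LatentMatrix | np.ndarray,
    labeled,
    k: int,
    iteration: int = 0,
) -> SelectionResult:
    """Greedy k-center (farthest-first) core-set selection.

    Repeats k times: pick the unlabeled point maximizing its minimal
    Euclidean distance to the union of labeled and already-chosen points
    (ties toward the lowest index).  With no labeled points, the first pick
    is the point farthest from the dataset mean (bootstrap), then the
    greedy rule continues; the greedy cover radius is within a factor 2 of
    the optimal k-center radius.
    """
    Z = latents.values if isinstance(latents, LatentMatrix) else np.asarray(latents)
    labeled = sorted(set(int(i) for i in labeled))
    pool = _unlabeled_indices(Z.shape[0], labeled)
    k = _clamp_k(k, pool.size)
    chosen: list[int] = []
    if labeled:
        min_d = np.min(
            np.linalg.norm(Z[pool][:, None, :] - Z[labeled][None, :, :], axis=2),
            axis=1,
        )
    else:
        center = Z.mean(axis=0)
        d0 = np.linalg.norm(Z[pool] - center, axis=1)
        first = int(np.argmax(d0))  # first max -> lowest index on ties
        chosen.append(int(pool[first]))
        min_d = np.linalg.norm(Z[pool] - Z[pool[first]], axis=1)
        min_d[first] = -np.inf
    while len(chosen) < k:
        j = int(np.argmax(min_d))
        chosen.append(int(pool[j]))
        d_new = np.linalg.norm(Z[pool] - Z[pool[j]], axis=1)
        min_d = np.minimum(min_d, d_new)
        min_d[j] = -np.inf
    return SelectionResult(chosen, "cs", iteration)


def select_mi(
    probs: np.ndarray,
    unlabeled_indices,
    k: int,
    iteration: int = 0,
    method: str = "margin",
) -> SelectionResult:
    """Uncertainty selection by smallest top-1/top-2 posterior margin.

    ``probs`` holds the classifier posteriors for the unlabeled pool (rows
    aligned with ``unlabeled_indices``).  Returns the k most uncertain
    samples in ascending margin order (ties toward the lowest index).
    ``method='entropy'`` ranks by descending predictive entropy instead.
    """
    probs = np.asarray(probs, dtype=np.float64)
    pool = np.asarray(list(unlabeled_indices), dtype=int)
    if probs.shape[0] != pool.size:
        raise ValueError("probs rows must align with unlabeled_indices")
    k = _clamp_k(k, pool.size)
    if method == "margin":
        part = np.sort(probs, axis=1)
        score = part[:, -1] - part[:, -2]
    elif method == "entropy":
        score = -(-(probs * np.log(probs + 1e-300)).sum(axis=1))
    else:
        raise ValueError(f"unknown uncertainty method {method!r}")
    order = np.lexsort((pool, score))  # ascending score, then lowest index
    chosen = [int(pool[i]) for i in order[:k]]
    return SelectionResult(chosen, "mi", iteration)


def select_random(
    n_or_indices,
    labeled,
    k: int,
    seed: int = 0,
    iteration: int = 0,
) -> SelectionResult:
    """Uniform sample of unlabeled indices without replacement (baseline)."""
    if np.isscalar(n_or_indices):
        pool = _unlabeled_indices(int(n_or_indices), labeled)
    else:
        pool = _unlabeled_indices(len(n_or_indices), labeled)
    k = _clamp_k(k, pool.size)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=k, replace=False)
    return SelectionResult([int(i) for i in chosen], "random", iteration)


@dataclass
class ALHistory:
    """Per-iteration record of the annotation loop."""

    iterations: list[dict] = field(default_factory=list)

    def add(self, **kw) -> None:
        self.iterations.append(kw)

    @property
    def final_accuracy(self) -> float:
        return self.iterations[-1]["test_accuracy"]

    def to_rows(self) -> list[dict]:
        return list(self.iterations)


def al_loop(
    train: SegmentDataset,
    test: SegmentDataset,
    model_config: ModelConfig,
    cls_config: ClassifierConfig,
    al_config: ALConfig,
    oracle: Callable[[int], int],
    model: TrainedModel | None = None,
) -> tuple[TrainedModel, ALHistory]:
    """Run the full iterative clustering -> selection -> training workflow.

    1. unsupervised pretraining of the encoder-decoder (skipped if a
       ``model`` is supplied);
    2. per iteration: select k unlabeled segments with the configured
       strategy (uncertainty-based ``mi`` falls back to ``top`` while no
       classifier exists), query the ``oracle`` for their labels,
       re-train semi-supervised, re-encode latents, and record test
       accuracy.

    The per-iteration k is the gap to the next cumulative budget fraction
    divided over the stage's iterations (floored, minimum 1).  The oracle
    maps a train-split index to a class index.
    """
    al_config.validate()
    N = len(train)
    if model is None:
        model = pretrain(train, model_config)
    history = ALHistory()
    latents = model.encode(train)
    truth_test = test.labels
    if np.any(truth_test < 0):
        raise ValueError("test split must be fully labeled for evaluation")
    iteration = 0
    for frac in al_config.budget_fractions:
        target_n = int(np.floor(frac * N))
        if target_n > N:
            warnings.warn("budget exceeds dataset size; clamping")
            target_n = N
        for sub in range(al_config.iterations_per_budget):
            labeled_idx = np.flatnonzero(train.labeled_mask)
            remaining_iters = al_config.iterations_per_budget - sub
            gap = target_n - labeled_idx.size
            if gap <= 0:
                continue
            k = max(1, gap // remaining_iters)
            k = min(k, N - labeled_idx.size)
            if k == 0:
                break
            iteration += 1
            strategy = al_config.strategy
            if strategy == "mi" and model.classifier is None:
                logger.info(
                    "iteration %d: no classifier yet, falling back from mi to top",
                    iteration,
                )
                strategy = "top"
            if strategy == "top":
                sel = select_top(latents, labeled_idx, k,
                                 seed=al_config.seed, iteration=iteration)
            elif strategy == "cs":
                sel = select_coreset(latents, labeled_idx, k, iteration=iteration)
            elif strategy == "mi":
                pool = _unlabeled_indices(N, labeled_idx)
                probs = model.classifier.forward(latents.values[pool])
                sel = select_mi(probs, pool, k, iteration=iteration)
            else:
                sel = select_random(N, labeled_idx, k,
                                    seed=al_config.seed + iteration,
                                    iteration=iteration)
            for i in sel.chosen:
                train.set_label(i, int(oracle(i)))
            model = train_semisupervised(model, train, cls_config)
            latents = model.encode(train)
            pred = classify(model, test)
            acc = accuracy(pred, truth_test)
            history.add(
                iteration=iteration,
                n_labeled=int(train.labeled_mask.sum()),
                frac_labeled=float(train.labeled_mask.sum() / N),
                strategy=sel.strategy,
                test_accuracy=acc,
            )
    return model, history
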