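"""End-to-end optimization: minibatch BCE with negative sampling, Adam,
early stopping on validation AUPRC with best-checkpoint restore.

Each step re-encodes the full training graph (one |V| x d* matrix per layer),
gathers the rows for the batch pairs, decodes them and backpropagates. The
message-passing adjacency is built from the *training* positives only, so
neither validation nor test edges influence the embeddings.

The loss is the batch mean of per-pair binary cross-entropy
-A_ij log p_ij - (1 - A_ij) log(1 - p_ij); the mean (rather than a raw sum
over all interactions) keeps the learning rate independent of batch size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import auprc, auroc
from .graph_io import (
    EdgeSplit,
    InteractionGraph,
    LabeledEdgeSet,
    build_normalized_adjacency,
    sample_negatives,
    sample_split_negatives,
)
from .model import (
    ModelConfig,
    backward_pairs,
    forward_pairs,
    init_parameters,
    predict_pairs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "EarlyStopping",
    "AdamOptimizer",
    "bce_loss",
    "fit_labeled",
    "train",
    "derive_seeds",
]

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults: Adam at a fixed learning rate 5e-4, minibatches of 256, at most
    50 epochs, early stopping after 10 epochs without validation improvement.
    """

    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 5e-4
    patience: int = 10
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    resample_train_negatives: bool = False

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.patience) < 1:
            raise ValueError("epochs, batch_size and patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.patience > self.epochs:
            raise ValueError("patience cannot exceed the epoch budget")


@dataclass
class TrainHistory:
    """Per-epoch training loss and validation metrics."""

    train_loss: list[float] = field(default_factory=list)
    val_auprc: list[float] = field(default_factory=list)
    val_auroc: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


class EarlyStopping:
    """Stop when the monitored score fails to improve for `patience` epochs."""

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best_score = -np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, score: float) -> bool:
        """Record an epoch score; returns True when training should stop."""
        if score > self.best_score:
            self.best_score = score
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


class AdamOptimizer:
    """Adam with bias correction over a flat name -> array parameter dict."""

    def __init__(self, params, lr=5e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def bce_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy; probabilities clamped away from 0/1."""
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    y = np.asarray(labels, dtype=np.float64).ravel()
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    if np.any((p <= 0) | (p >= 1)):
        logger.warning("clamping %d probabilities at the boundary", int(np.sum((p <= 0) | (p >= 1))))
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(np.mean(-y * np.log(p) - (1.0 - y) * np.log1p(-p)))


def derive_seeds(master_seed: int, n: int = 4) -> list[int]:
    """Derive independent sub-seeds (split, negatives, init, shuffle) from one
    master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def fit_labeled(
    graph: InteractionGraph,
    train_set: LabeledEdgeSet,
    val_set: LabeledEdgeSet,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    features: np.ndarray | None = None,
    adjacency_edges: np.ndarray | None = None,
):
    """Core loop over explicit labeled train/validation sets.

    The message-passing adjacency is built from ``adjacency_edges`` (default:
    the positive pairs of the training set). Returns (params, history, adj).
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be nonempty")
    _, _, init_seed, shuffle_seed = derive_seeds(train_config.seed)
    pos_train = train_set.pairs[train_set.labels == 1]
    if adjacency_edges is None:
        adjacency_edges = pos_train
    adj = build_normalized_adjacency(graph.with_edges(adjacency_edges))
    n_inputs = graph.n_nodes if features is None else features.shape[1]
    params = init_parameters(model_config, n_inputs, seed=init_seed)
    optimizer = AdamOptimizer(
        params,
        lr=train_config.learning_rate,
        beta1=train_config.beta1,
        beta2=train_config.beta2,
        eps=train_config.adam_eps,
    )

    rng = np.random.default_rng(shuffle_seed)
    stopper = EarlyStopping(train_config.patience)
    history = TrainHistory()
    best_params = {k: v.copy() for k, v in params.items()}

    for epoch in range(train_config.epochs):
        pairs, labels = train_set.pairs, train_set.labels
        if train_config.resample_train_negatives and epoch > 0:
            fresh = sample_negatives(
                graph, len(pos_train), seed=int(rng.integers(2**31))
            )
            pairs = np.concatenate([pos_train, fresh.pairs])
            labels = np.concatenate(
                [np.ones(len(pos_train), dtype=np.int64), fresh.labels]
            )
        order = rng.permutation(len(labels))
        pairs, labels = pairs[order], labels[order]

        epoch_losses = []
        for start in range(0, len(labels), train_config.batch_size):
            b_pairs = pairs[start : start + train_config.batch_size]
            b_labels = labels[start : start + train_config.batch_size]
            p, cache = forward_pairs(
                adj, params, model_config, b_pairs, features,
                train_mode=True, rng=rng, want_cache=True,
            )
            loss = bce_loss(p, b_labels)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {start}"
                )
            grads = backward_pairs(adj, params, model_config, cache, b_labels)
            optimizer.step(params, grads)
            epoch_losses.append(loss)

        val_p = predict_pairs(adj, params, model_config, val_set.pairs, features)
        v_auprc = auprc(val_p, val_set.labels)
        v_auroc = auroc(val_p, val_set.labels)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_auprc.append(v_auprc)
        history.val_auroc.append(v_auroc)
        logger.info(
            "epoch %d: loss %.4f, val AUPRC %.4f, val AUROC %.4f",
            epoch, history.train_loss[-1], v_auprc, v_auroc,
        )
        improved = v_auprc > stopper.best_score
        stop = stopper.update(epoch, v_auprc)
        if improved:
            best_params = {k: v.copy() for k, v in params.items()}
        if stop:
            logger.info("early stop at epoch %d (best %d)", epoch, stopper.best_epoch)
            break

    history.best_epoch = stopper.best_epoch
    return best_params, history, adj


def train(
    graph: InteractionGraph,
    split: EdgeSplit,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    negatives: dict[str, LabeledEdgeSet] | None = None,
    features: np.ndarray | None = None,
):
    """Fit HOGCN on an edge split; returns (params, history, adj).

    Negatives default to one frozen, disjoint 1:1 pool per split (sampled
    from the complement of ALL positive edges). Fully deterministic for fixed
    seeds: two identical calls return identical parameters and history.
    """
    train_config = train_config or TrainConfig()
    if len(split.train) == 0 or len(split.validation) == 0:
        raise ValueError("train and validation splits must be nonempty")
    if negatives is None:
        _, neg_seed, _, _ = derive_seeds(train_config.seed)
        negatives = sample_split_negatives(graph, split, seed=neg_seed)
    train_set = LabeledEdgeSet.from_positive_negative(
        split.train, negatives["train"].pairs
    )
    val_set = LabeledEdgeSet.from_positive_negative(
        split.validation, negatives["validation"].pairs
    )
    return fit_labeled(
        graph,
        train_set,
        val_set,
        model_config=model_config,
        train_config=train_config,
        features=features,
        adjacency_edges=split.train,
    )
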