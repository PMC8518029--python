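"""Experiment harnesses: single train+evaluate runs and (k, fraction) sweeps.

The sweep mirrors two standard robustness analyses: varying the maximum
neighborhood order k with P = {0, ..., k}, and varying the fraction of edges
used for training (network sparsity). For a training fraction f, the
remaining edges are split 10% validation / 90% test.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .evaluation import EvalReport, evaluate
from .graph_io import (
    EdgeSplit,
    InteractionGraph,
    sample_split_negatives,
    split_edges,
)
from .model import ModelConfig, PowerSet, predict_pairs
from .training import TrainConfig, derive_seeds, train

logger = logging.getLogger(__name__)

__all__ = ["train_and_evaluate", "run_sweep"]


def train_and_evaluate(
    graph: InteractionGraph,
    split: EdgeSplit,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    features: np.ndarray | None = None,
    n_bins: int = 10,
):
    """Train on a split and score the held-out test edges.

    Test pairs are the test positives plus an equal number of frozen
    negatives (disjoint from the train/validation negative pools). Returns
    ``(report, params, history, adj)``.
    """
    train_config = train_config or TrainConfig()
    _, neg_seed, _, _ = derive_seeds(train_config.seed)
    negatives = sample_split_negatives(graph, split, seed=neg_seed)
    params, history, adj = train(
        graph, split, model_config, train_config, negatives=negatives,
        features=features,
    )
    test_pairs = np.concatenate([split.test, negatives["test"].pairs])
    test_labels = np.concatenate(
        [np.ones(len(split.test), dtype=np.int64), negatives["test"].labels]
    )
    probs = predict_pairs(adj, params, model_config or ModelConfig(), test_pairs,
                          features=features)
    report = evaluate(probs, test_labels, n_bins=n_bins)
    return report, params, history, adj


def _cell_split(graph: InteractionGraph, fraction: float, seed: int) -> EdgeSplit:
    rest = 1.0 - fraction
    return split_edges(graph, (fraction, 0.1 * rest, 0.9 * rest), seed=seed)


def run_sweep(
    graph: InteractionGraph,
    k_values: list[int],
    fractions: list[float],
    seeds: list[int],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    features: np.ndarray | None = None,
) -> pd.DataFrame:
    """Train one model per (k, fraction, seed) cell; tidy results table.

    A failing cell is recorded with ``status='error'`` and the sweep
    continues. Columns: k, train_fraction, seed, auprc, auroc, brier,
    n_train_edges, n_test_pairs, best_epoch, status.
    """
    if not (k_values and fractions and seeds):
        raise ValueError("k_values, fractions and seeds must be nonempty")
    base_model = model_config or ModelConfig()
    base_train = train_config or TrainConfig()
    rows = []
    for k in k_values:
        for fraction in fractions:
            for seed in seeds:
                row = {
                    "k": int(k),
                    "train_fraction": float(fraction),
                    "seed": int(seed),
                }
                try:
                    mc = replace(base_model, powers=PowerSet.up_to(int(k)))
                    tc = replace(base_train, seed=int(seed))
                    split = _cell_split(graph, float(fraction), seed=int(seed))
                    report, _, history, _ = train_and_evaluate(
                        graph, split, mc, tc, features=features
                    )
                    row.update(
                        auprc=report.auprc,
                        auroc=report.auroc,
                        brier=report.brier,
                        n_train_edges=len(split.train),
                        n_test_pairs=report.n_pairs,
                        best_epoch=history.best_epoch,
                        status="ok",
                    )
                except Exception as exc:  # record and continue
                    logger.exception("sweep cell failed: k=%s f=%s seed=%s", k, fraction, seed)
                    row.update(
                        auprc=np.nan, auroc=np.nan, brier=np.nan,
                        n_train_edges=np.nan, n_test_pairs=np.nan,
                        best_epoch=-1, status=f"error: {exc}",
                    )
                rows.append(row)
    return pd.DataFrame(rows)
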