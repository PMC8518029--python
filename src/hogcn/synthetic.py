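"""Seeded synthetic interaction networks for end-to-end testing and benchmarks.

Two generators cover the topologies of typical biomedical link-prediction
datasets:

* :func:`generate_sbm` — a stochastic block model standing in for unipartite
  networks (protein-protein, drug-drug). Block co-membership is recoverable
  from higher-order neighborhoods, so held-out links are predictable from
  topology alone and higher adjacency powers genuinely help.
* :func:`generate_bipartite` — a latent-factor bipartite graph standing in
  for drug-target / gene-disease networks: edge probability is a sigmoid of
  the inner product of r-dimensional latent vectors, with the offset
  calibrated by bisection to hit a target density.

Neither models degree heterogeneity (hubs), degree-correlated noise, or node
features beyond one-hot; conclusions drawn on them speak to topology-driven
predictability only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_io import InteractionGraph, canonicalize_edges

__all__ = [
    "SBMSpec",
    "BipartiteLatentSpec",
    "generate_sbm",
    "generate_bipartite",
    "toy_fixture",
    "TOY_FIXTURES",
]


@dataclass(frozen=True)
class SBMSpec:
    """Stochastic block model with equal-size blocks.

    Every unordered within-block pair is an edge with probability ``p_in``,
    every cross-block pair with probability ``p_out`` <= ``p_in``.
    """

    n_nodes: int = 300
    n_blocks: int = 2
    p_in: float = 0.08
    p_out: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < self.n_blocks or self.n_blocks < 1:
            raise ValueError("need at least one node per block")
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out <= p_in <= 1")


@dataclass(frozen=True)
class BipartiteLatentSpec:
    """Bipartite latent-factor graph with calibrated density."""

    n_a: int = 150
    n_b: int = 100
    latent_dim: int = 4
    density: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b) < 1:
            raise ValueError("both parts need at least one node")
        if self.latent_dim < 1:
            raise ValueError("latent dimension must be >= 1")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie strictly in (0, 1)")


def generate_sbm(spec: SBMSpec) -> InteractionGraph:
    """Sample a simple undirected SBM graph; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    block = np.arange(n) * spec.n_blocks // n  # equal-size contiguous blocks
    ii, jj = np.triu_indices(n, k=1)
    prob = np.where(block[ii] == block[jj], spec.p_in, spec.p_out)
    keep = rng.random(len(prob)) < prob
    edges = np.stack([ii[keep], jj[keep]], axis=1)
    node_ids = [f"n{b}_{i}" for i, b in zip(range(n), block)]
    return InteractionGraph(node_ids=node_ids, edges=edges)


def _bipartite_density(logits: np.ndarray, offset: float) -> float:
    return float(np.mean(1.0 / (1.0 + np.exp(-(logits + offset)))))


def generate_bipartite(spec: BipartiteLatentSpec) -> InteractionGraph:
    """Sample a bipartite latent-factor graph hitting the target density.

    The sigmoid offset c in P(edge) = sigmoid(u_a . v_b + c) is found by
    bisection so the expected density matches ``spec.density`` (realized
    density is within ~10% for reasonably sized graphs).
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.standard_normal((spec.n_a, spec.latent_dim))
    v = rng.standard_normal((spec.n_b, spec.latent_dim))
    logits = u @ v.T
    lo, hi = -50.0, 50.0
    if not (
        _bipartite_density(logits, lo) <= spec.density <= _bipartite_density(logits, hi)
    ):
        raise ValueError("target density unreachable for these latent factors")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _bipartite_density(logits, mid) < spec.density:
            lo = mid
        else:
            hi = mid
    offset = 0.5 * (lo + hi)
    prob = 1.0 / (1.0 + np.exp(-(logits + offset)))
    keep = rng.random(prob.shape) < prob
    a_idx, b_idx = np.nonzero(keep)
    edges = np.stack([a_idx, b_idx + spec.n_a], axis=1)
    node_ids = [f"a{i}" for i in range(spec.n_a)] + [f"b{i}" for i in range(spec.n_b)]
    node_type = np.array(["A"] * spec.n_a + ["B"] * spec.n_b)
    return InteractionGraph(node_ids=node_ids, edges=edges, node_type=node_type)


def _make_toy(name: str) -> InteractionGraph:
    if name == "path3":
        return InteractionGraph(["a", "b", "c"], [(0, 1), (1, 2)])
    if name == "triangle":
        return InteractionGraph(["a", "b", "c"], [(0, 1), (1, 2), (0, 2)])
    if name == "l3_demo":
        # x-a, a-b, b-y, a-c, c-y: two degree-normalized length-3 paths x->y
        ids = ["x", "a", "b", "c", "y"]
        edges = [(0, 1), (1, 2), (2, 4), (1, 3), (3, 4)]
        return InteractionGraph(ids, edges)
    if name == "bipartite_2x2":
        return InteractionGraph(
            ["a1", "a2", "b1", "b2"],
            [(0, 2)],
            node_type=np.array(["A", "A", "B", "B"]),
        )
    raise KeyError(name)


TOY_FIXTURES = ("path3", "triangle", "l3_demo", "bipartite_2x2")


def toy_fixture(name: str) -> InteractionGraph:
    """Hand-coded miniature graphs used throughout the unit tests."""
    if name not in TOY_FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(TOY_FIXTURES)}"
        )
    return _make_toy(name)
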