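"""Network-similarity baselines: common-neighbor (TCP) and L3 path scores.

TCP (triadic closure principle) scores a candidate pair by its number of
shared neighbors, the (i, j) entry of A². The L3 score counts length-3 paths
between the pair, each path i-u-v-j down-weighted by the degrees of its two
intermediate nodes:

    L3(i, j) = sum_{u,v} A_iu * A_uv * A_vj / sqrt(d_u * d_v)

with degrees taken from the raw graph (no self-loops). The square-root
degree normalization follows the published form of the heuristic; a plain
"normalized by the degree" phrasing is ambiguous, so the convention is
stated here once and used everywhere.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .graph_io import InteractionGraph

__all__ = ["tcp_score", "l3_score", "score_pairs", "all_non_edge_scores"]


def _resolve(graph: InteractionGraph, node) -> int:
    if isinstance(node, str):
        return graph.index_of(node)
    idx = int(node)
    if not 0 <= idx < graph.n_nodes:
        raise KeyError(f"node index {idx} out of range")
    return idx


def tcp_score(graph: InteractionGraph, i, j) -> int:
    """Number of shared neighbors |N(i) ∩ N(j)| = (A²)_ij for i ≠ j."""
    a = graph.adjacency()
    ii, jj = _resolve(graph, i), _resolve(graph, j)
    return int(a.getrow(ii).multiply(a.getrow(jj)).sum())


def l3_score(graph: InteractionGraph, i, j) -> float:
    """Degree-normalized length-3 path count between i and j."""
    a = graph.adjacency()
    ii, jj = _resolve(graph, i), _resolve(graph, j)
    deg = np.asarray(a.sum(axis=1)).ravel()
    w = np.zeros_like(deg)
    nz = deg > 0
    w[nz] = 1.0 / np.sqrt(deg[nz])
    # sum_{u,v} (A_iu w_u) A_uv (w_v A_vj)
    x = a.getrow(ii).toarray().ravel() * w
    y = a.getrow(jj).toarray().ravel() * w
    return float(x @ (a @ y))


def score_pairs(
    graph: InteractionGraph, pairs: np.ndarray, method: str = "l3"
) -> np.ndarray:
    """Vectorized heuristic scores for an (n, 2) array of index pairs."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    a = graph.adjacency()
    if method == "tcp":
        scored = a @ a
        return np.asarray(scored[pairs[:, 0], pairs[:, 1]]).ravel().astype(float)
    if method == "l3":
        deg = np.asarray(a.sum(axis=1)).ravel()
        w = np.zeros_like(deg)
        nz = deg > 0
        w[nz] = 1.0 / np.sqrt(deg[nz])
        d_half = sp.diags(w)
        scored = a @ (d_half @ a @ d_half) @ a
        return np.asarray(scored[pairs[:, 0], pairs[:, 1]]).ravel().astype(float)
    raise ValueError(f"unknown heuristic method {method!r} (expected 'tcp' or 'l3')")


def all_non_edge_scores(
    graph: InteractionGraph, method: str = "l3"
) -> tuple[np.ndarray, np.ndarray]:
    """Scores for every candidate non-edge, ties broken by canonical pair order.

    Returns ``(pairs, scores)`` sorted by descending score then ascending
    (i, j), for deterministic top-N lists. Bipartite graphs restrict
    candidates to cross-type pairs.
    """
    n = graph.n_nodes
    if graph.is_bipartite:
        idx_a = np.flatnonzero(graph.node_type == "A")
        idx_b = np.flatnonzero(graph.node_type == "B")
        ii, jj = np.meshgrid(idx_a, idx_b, indexing="ij")
        cand = np.stack([ii.ravel(), jj.ravel()], axis=1)
        cand = np.stack([cand.min(axis=1), cand.max(axis=1)], axis=1)
    else:
        ii, jj = np.triu_indices(n, k=1)
        cand = np.stack([ii, jj], axis=1)
    codes = cand[:, 0] * n + cand[:, 1]
    pos = np.fromiter(graph._edge_codes, dtype=np.int64, count=graph.n_edges)
    cand = cand[~np.isin(codes, pos)]
    scores = score_pairs(graph, cand, method=method)
    order = np.lexsort((cand[:, 1], cand[:, 0], -scores))
    return cand[order], scores[order]
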