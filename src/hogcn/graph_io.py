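"""Edge-list I/O, adjacency normalization, edge splits and negative sampling.

An interaction network is an undirected simple graph over string-identified
nodes (proteins, drugs, genes, diseases ...). Edges are stored canonically as
``(min, max)`` 0-based index pairs; node order is first appearance in the
input so adjacency matrices are byte-for-byte reproducible.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionGraph",
    "NormalizedAdjacency",
    "EdgeSplit",
    "LabeledEdgeSet",
    "EdgeListFormatError",
    "NegativeSamplingError",
    "read_edge_list",
    "write_edge_list",
    "read_feature_table",
    "build_normalized_adjacency",
    "split_edges",
    "sample_negatives",
    "sample_split_negatives",
    "average_degree",
    "average_degree_from_counts",
    "save_split",
    "load_split",
]


class EdgeListFormatError(ValueError):
    """Raised for malformed or empty edge-list files."""


class NegativeSamplingError(ValueError):
    """Raised when the non-edge complement cannot supply the requested count."""


def canonicalize_edges(pairs: np.ndarray) -> np.ndarray:
    """Sort each pair to (min, max), drop duplicates, sort lexicographically."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    lo = pairs.min(axis=1)
    hi = pairs.max(axis=1)
    canon = np.stack([lo, hi], axis=1)
    if canon.shape[0] == 0:
        return canon
    return np.unique(canon, axis=0)


@dataclass
class InteractionGraph:
    """Undirected simple interaction network G = (V, E, X).

    Parameters
    ----------
    node_ids : list of str
        Node identifiers in a fixed order (defines the 0-based index).
    edges : ndarray of shape (n_edges, 2)
        Canonical (min, max) index pairs, unique, no self-loops.
    node_type : ndarray of 'A'/'B' or None
        Per-node part labels for bipartite networks (drug-target,
        gene-disease). ``None`` for unipartite networks (PPI, DDI).
    features : ndarray of shape (n_nodes, F) or None
        Optional node feature matrix X. ``None`` means one-hot identity
        features, realized implicitly by the model for memory.
    """

    node_ids: list[str]
    edges: np.ndarray
    node_type: np.ndarray | None = None
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.edges = canonicalize_edges(np.asarray(self.edges, dtype=np.int64))
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node identifiers")
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge endpoint out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loops are not allowed")
        if self.node_type is not None:
            self.node_type = np.asarray(self.node_type)
            if self.node_type.shape != (n,):
                raise ValueError("node_type must have one entry per node")
            if self.edges.size:
                ta = self.node_type[self.edges[:, 0]]
                tb = self.node_type[self.edges[:, 1]]
                if np.any(ta == tb):
                    raise ValueError("bipartite graph has a within-type edge")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=np.float64)
            if self.features.shape[0] != n:
                raise ValueError("feature matrix must have one row per node")
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}
        self._edge_codes = frozenset(
            (self.edges[:, 0] * n + self.edges[:, 1]).tolist()
        )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def is_bipartite(self) -> bool:
        return self.node_type is not None

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"unknown node identifier: {node_id!r}") from None

    def has_edge(self, i: int, j: int) -> bool:
        if i == j:
            return False
        lo, hi = (i, j) if i < j else (j, i)
        return lo * self.n_nodes + hi in self._edge_codes

    def adjacency(self) -> sp.csr_matrix:
        """Binary symmetric adjacency matrix A (no self-loops)."""
        n = self.n_nodes
        if self.n_edges == 0:
            return sp.csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * self.n_edges)
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def degrees(self) -> np.ndarray:
        """Node degrees of the raw graph (self-loops never counted)."""
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def with_edges(self, edges: np.ndarray) -> "InteractionGraph":
        """Same node set and metadata, different edge set."""
        return InteractionGraph(
            node_ids=self.node_ids,
            edges=edges,
            node_type=self.node_type,
            features=self.features,
        )


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Symmetrically normalized adjacency with self-loops.

    ``matrix`` is the sparse Â = D^{-1/2} (A + I) D^{-1/2} where D counts
    degrees after adding self-loops; ``degrees`` caches that degree vector.
    """

    matrix: sp.csr_matrix
    degrees: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def build_normalized_adjacency(graph: InteractionGraph) -> NormalizedAdjacency:
    """Â = D^{-1/2}(A + I)D^{-1/2}; isolated nodes get Â_ii = 1."""
    if graph.n_nodes < 1:
        raise ValueError("graph must have at least one node")
    a = graph.adjacency()
    a_self = a + sp.identity(graph.n_nodes, format="csr")
    deg = np.asarray(a_self.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    d_mat = sp.diags(d_inv_sqrt)
    norm = (d_mat @ a_self @ d_mat).tocsr()
    return NormalizedAdjacency(matrix=norm, degrees=deg)


@dataclass(frozen=True)
class EdgeSplit:
    """Disjoint train/validation/test partition of the positive edge set."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    ratios: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        for name in ("train", "validation", "test"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=np.int64).reshape(-1, 2)
            )

    @property
    def n_total(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


@dataclass(frozen=True)
class LabeledEdgeSet:
    """Node-pair list with binary interaction labels."""

    pairs: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int64).ravel())
        if self.pairs.shape[0] != self.labels.shape[0]:
            raise ValueError("pairs and labels length mismatch")
        if self.labels.size and not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return self.pairs.shape[0]

    @staticmethod
    def from_positive_negative(
        positives: np.ndarray, negatives: np.ndarray
    ) -> "LabeledEdgeSet":
        positives = np.asarray(positives, dtype=np.int64).reshape(-1, 2)
        negatives = np.asarray(negatives, dtype=np.int64).reshape(-1, 2)
        pairs = np.concatenate([positives, negatives], axis=0)
        labels = np.concatenate(
            [np.ones(len(positives), dtype=np.int64), np.zeros(len(negatives), dtype=np.int64)]
        )
        return LabeledEdgeSet(pairs, labels)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def _sniff_delimiter(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace split


def read_edge_list(
    path: str | os.PathLike,
    delimiter: str | None = None,
    bipartite: bool = False,
) -> InteractionGraph:
    """Read a two-column edge list (TSV/CSV) into an :class:`InteractionGraph`.

    Lines starting with ``#`` are comments. Duplicate rows and reversed
    duplicates collapse to one undirected edge; self-loop rows are dropped
    with a warning. Node order is first appearance. With ``bipartite=True``
    first-column nodes are type A, second-column type B; a node appearing in
    both columns is an error.
    """
    node_ids: list[str] = []
    index: dict[str, int] = {}
    types: dict[str, str] = {}
    pairs: list[tuple[int, int]] = []

    def intern(name: str, col_type: str) -> int:
        if name not in index:
            index[name] = len(node_ids)
            node_ids.append(name)
        if bipartite:
            prev = types.setdefault(name, col_type)
            if prev != col_type:
                raise EdgeListFormatError(
                    f"node {name!r} appears in both columns of a bipartite edge list"
                )
        return index[name]

    n_self_loops = 0
    with open(path, "rt", encoding="utf-8") as fh:
        delim = delimiter
        saw_data = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            fields = line.split(delim) if delim else line.split()
            fields = [f.strip() for f in fields if f.strip() != ""]
            if len(fields) < 2:
                raise EdgeListFormatError(
                    f"{path}: line {lineno}: expected at least 2 columns, got {len(fields)}"
                )
            saw_data = True
            a = intern(fields[0], "A")
            b = intern(fields[1], "B")
            if a == b:
                n_self_loops += 1
                continue
            pairs.append((a, b))
    if not saw_data:
        raise EdgeListFormatError(f"{path}: empty edge list")
    if n_self_loops:
        logger.warning("%s: dropped %d self-loop row(s)", path, n_self_loops)
    node_type = None
    if bipartite:
        node_type = np.array([types[n] for n in node_ids])
    edges = canonicalize_edges(np.array(pairs, dtype=np.int64).reshape(-1, 2))
    return InteractionGraph(node_ids=node_ids, edges=edges, node_type=node_type)


def write_edge_list(
    graph: InteractionGraph,
    path: str | os.PathLike,
    delimiter: str = "\t",
    pairs: np.ndarray | None = None,
) -> None:
    """Write edges (default: all graph edges) as a two-column text file."""
    edges = graph.edges if pairs is None else np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    with open(path, "wt", encoding="utf-8") as fh:
        for i, j in edges:
            fh.write(f"{graph.node_ids[i]}{delimiter}{graph.node_ids[j]}\n")


def read_feature_table(path: str | os.PathLike, graph: InteractionGraph) -> np.ndarray:
    """Read a TSV feature table (first column node id) aligned to graph order."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    table.index = table.index.astype(str)
    missing = [n for n in graph.node_ids if n not in table.index]
    if missing:
        raise EdgeListFormatError(
            f"{path}: missing features for {len(missing)} node(s), e.g. {missing[:3]}"
        )
    return table.loc[graph.node_ids].to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------------
# Splits and negatives
# ---------------------------------------------------------------------------

def split_edges(
    graph: InteractionGraph,
    ratios: Sequence[float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> EdgeSplit:
    """Partition the positive edges into train/validation/test.

    Sizes are floor(r_train·m), floor(r_val·m) and the remainder; the shuffle
    is a seeded permutation so the split is deterministic.
    """
    r = tuple(float(x) for x in ratios)
    if len(r) != 3 or any(x <= 0 for x in r):
        raise ValueError("ratios must be three positive proportions")
    if abs(sum(r) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(r)}")
    m = graph.n_edges
    n_train = math.floor(r[0] * m)
    n_val = math.floor(r[1] * m)
    n_test = m - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split {r} of {m} edges leaves an empty subset; use a larger graph"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    shuffled = graph.edges[perm]
    return EdgeSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        ratios=r,
        seed=int(seed),
    )


def _complement_size(graph: InteractionGraph, bipartite: bool) -> int:
    n = graph.n_nodes
    if bipartite:
        n_a = int(np.sum(graph.node_type == "A"))
        n_b = n - n_a
        total = n_a * n_b
    else:
        total = n * (n - 1) // 2
    return total - graph.n_edges


def _enumerate_complement(graph: InteractionGraph, bipartite: bool) -> np.ndarray:
    n = graph.n_nodes
    if bipartite:
        idx_a = np.flatnonzero(graph.node_type == "A")
        idx_b = np.flatnonzero(graph.node_type == "B")
        ii, jj = np.meshgrid(idx_a, idx_b, indexing="ij")
        cand = np.stack([ii.ravel(), jj.ravel()], axis=1)
        lo = cand.min(axis=1)
        hi = cand.max(axis=1)
        cand = np.stack([lo, hi], axis=1)
    else:
        ii, jj = np.triu_indices(n, k=1)
        cand = np.stack([ii, jj], axis=1)
    codes = cand[:, 0] * n + cand[:, 1]
    pos = np.fromiter(graph._edge_codes, dtype=np.int64, count=len(graph._edge_codes))
    keep = ~np.isin(codes, pos)
    return cand[keep]


def sample_negatives(
    graph: InteractionGraph,
    count: int,
    seed: int = 0,
    bipartite: bool | None = None,
) -> LabeledEdgeSet:
    """Draw ``count`` distinct non-edges (label 0) from the complement set.

    All known positive edges (the full graph, i.e. train+validation+test) are
    excluded so evaluation negatives can never leak a positive. For bipartite
    graphs only cross-type pairs are drawn by default.
    """
    if bipartite is None:
        bipartite = graph.is_bipartite
    if bipartite and not graph.is_bipartite:
        raise ValueError("bipartite sampling requested on a graph without node types")
    available = _complement_size(graph, bipartite)
    if count > available:
        raise NegativeSamplingError(
            f"requested {count} negatives but only {available} non-edges exist"
        )
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    total_pairs = available + graph.n_edges
    # Exact enumeration when the candidate space is small or densely requested;
    # otherwise seeded rejection sampling.
    if total_pairs <= 2_000_000 or count * 2 > available:
        comp = _enumerate_complement(graph, bipartite)
        # keep the draw order random: callers partition this pool into splits
        pick = rng.choice(len(comp), size=count, replace=False)
        negs = comp[pick]
    else:
        chosen: list[tuple[int, int]] = []
        seen: set[int] = set()
        if bipartite:
            idx_a = np.flatnonzero(graph.node_type == "A")
            idx_b = np.flatnonzero(graph.node_type == "B")
        while len(chosen) < count:
            draw = max(1024, 2 * (count - len(chosen)))
            if bipartite:
                a = idx_a[rng.integers(0, len(idx_a), size=draw)]
                b = idx_b[rng.integers(0, len(idx_b), size=draw)]
            else:
                a = rng.integers(0, n, size=draw)
                b = rng.integers(0, n, size=draw)
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            for x, y in zip(lo.tolist(), hi.tolist()):
                if x == y:
                    continue
                code = x * n + y
                if code in graph._edge_codes or code in seen:
                    continue
                seen.add(code)
                chosen.append((x, y))
                if len(chosen) == count:
                    break
        negs = np.array(chosen, dtype=np.int64)
    return LabeledEdgeSet(pairs=negs, labels=np.zeros(count, dtype=np.int64))


def sample_split_negatives(
    graph: InteractionGraph,
    split: EdgeSplit,
    seed: int = 0,
    bipartite: bool | None = None,
) -> dict[str, LabeledEdgeSet]:
    """One frozen, disjoint negative pool partitioned across the three splits.

    Each split gets as many negatives as it has positives (1:1), and no
    negative pair is shared between splits.
    """
    counts = {
        "train": len(split.train),
        "validation": len(split.validation),
        "test": len(split.test),
    }
    pool = sample_negatives(graph, sum(counts.values()), seed=seed, bipartite=bipartite)
    out: dict[str, LabeledEdgeSet] = {}
    start = 0
    for name, cnt in counts.items():
        out[name] = LabeledEdgeSet(
            pairs=pool.pairs[start : start + cnt],
            labels=np.zeros(cnt, dtype=np.int64),
        )
        start += cnt
    return out


def average_degree(graph: InteractionGraph) -> float:
    """Average interactions per entity, 2|E|/|V|."""
    return average_degree_from_counts(graph.n_nodes, graph.n_edges)


def average_degree_from_counts(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 1:
        raise ValueError("need at least one node")
    return 2.0 * n_edges / n_nodes


# ---------------------------------------------------------------------------
# Split persistence: three edge-list files plus a JSON sidecar
# ---------------------------------------------------------------------------

_SPLIT_FILES = {"train": "train.tsv", "validation": "validation.tsv", "test": "test.tsv"}


def save_split(graph: InteractionGraph, split: EdgeSplit, out_dir: str | os.PathLike) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for name, fname in _SPLIT_FILES.items():
        write_edge_list(graph, os.path.join(out_dir, fname), pairs=getattr(split, name))
    sidecar = {"ratios": list(split.ratios), "seed": split.seed}
    with open(os.path.join(out_dir, "split.json"), "wt", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2)


def load_split(graph: InteractionGraph, in_dir: str | os.PathLike) -> EdgeSplit:
    with open(os.path.join(in_dir, "split.json"), "rt", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    parts = {}
    for name, fname in _SPLIT_FILES.items():
        pairs = []
        with open(os.path.join(in_dir, fname), "rt", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split("\t")[:2]
                pairs.append((graph.index_of(a), graph.index_of(b)))
        arr = np.array(pairs, dtype=np.int64).reshape(-1, 2)
        lo = arr.min(axis=1) if arr.size else arr[:, 0]
        hi = arr.max(axis=1) if arr.size else arr[:, 0]
        parts[name] = np.stack([lo, hi], axis=1) if arr.size else arr
    return EdgeSplit(
        train=parts["train"],
        validation=parts["validation"],
        test=parts["test"],
        ratios=tuple(sidecar["ratios"]),
        seed=int(sidecar["seed"]),
    )
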