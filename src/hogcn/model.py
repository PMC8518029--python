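"""Higher-order graph convolutional encoder and bilinear edge decoder.

The encoder stacks higher-order graph convolution (HOGC) layers

    H^(l) = concat_{j in P} sigma( A_hat^j H^(l-1) W_j^(l) )

over a set of adjacency powers P = {0, 1, ..., k}, where A_hat is the
symmetrically normalized adjacency with self-loops. Powers are never
materialized: A_hat^j H is computed by j iterated sparse-dense products
(right-to-left). With P = {1} a layer reduces to a plain GCN layer; with
P = {1, 2} it reproduces direct-plus-skip aggregation.

The decoder fuses two node embeddings with a learnable bilinear tensor,

    e_ij = ELU(z_i^T W_b z_j + b),    p_ij = sigmoid(FC2(ELU(FC1(e_ij)))),

giving a calibratable interaction probability.

Everything is implemented in NumPy with float64 arithmetic; the companion
backward pass in this module computes exact analytic gradients (checked
against finite differences in the test suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np

from .graph_io import NormalizedAdjacency

__all__ = [
    "PowerSet",
    "ModelConfig",
    "init_parameters",
    "propagate_power",
    "hogc_layer_forward",
    "encode",
    "bilinear_fuse",
    "predict_probability",
    "forward_pairs",
    "backward_pairs",
    "predict_pairs",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Activations (value and derivative from the pre-activation)
# ---------------------------------------------------------------------------

def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _delu(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


_ACTIVATIONS = {
    "elu": (_elu, _delu),
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float)),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
}


def _get_activation(name: str):
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSet:
    """Ordered set of distinct nonnegative adjacency powers."""

    powers: tuple[int, ...]

    def __post_init__(self) -> None:
        p = tuple(int(x) for x in self.powers)
        if len(p) < 1:
            raise ValueError("power set must be nonempty")
        if any(x < 0 for x in p):
            raise ValueError("adjacency powers must be nonnegative")
        if tuple(sorted(set(p))) != p:
            raise ValueError("powers must be sorted, distinct integers")
        object.__setattr__(self, "powers", p)

    @classmethod
    def up_to(cls, k: int) -> "PowerSet":
        """P = {0, 1, ..., k}."""
        if k < 0:
            raise ValueError("k must be nonnegative")
        return cls(tuple(range(k + 1)))

    def __len__(self) -> int:
        return len(self.powers)

    def __iter__(self):
        return iter(self.powers)

    @property
    def k(self) -> int:
        return self.powers[-1]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_dim`` is the per-power width d, so every HOGC layer outputs
    d * |P| columns (d* in the embedding Z). ``edge_dim`` is the bilinear
    edge-representation length, ``head_hidden_dim`` the width of the hidden
    layer in the 2-layer prediction head.
    """

    n_layers: int = 2
    powers: PowerSet = field(default_factory=lambda: PowerSet.up_to(3))
    hidden_dim: int = 32
    edge_dim: int = 64
    head_hidden_dim: int = 32
    dropout: float = 0.1
    activation: str = "elu"

    def __post_init__(self) -> None:
        if isinstance(self.powers, (list, tuple)):
            object.__setattr__(self, "powers", PowerSet(tuple(self.powers)))
        if self.n_layers < 1:
            raise ValueError("need at least one HOGC layer")
        if min(self.hidden_dim, self.edge_dim, self.head_hidden_dim) < 1:
            raise ValueError("all widths must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        _get_activation(self.activation)

    @property
    def d_star(self) -> int:
        """Embedding width d * |P|."""
        return self.hidden_dim * len(self.powers)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["powers"] = list(self.powers.powers)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        d = dict(d)
        d["powers"] = PowerSet(tuple(d["powers"]))
        return cls(**d)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _xavier_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Xavier/Glorot uniform; for 3-D tensors the fans are the trailing dims."""
    if len(shape) == 2:
        fan_in, fan_out = shape
    elif len(shape) == 3:
        fan_in, fan_out = shape[1], shape[2]
    else:
        raise ValueError("xavier init expects 2-D or 3-D shapes")
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_parameters(
    config: ModelConfig, n_inputs: int, seed: int = 0
) -> dict[str, np.ndarray]:
    """Xavier-uniform weights, zero biases, in a flat name -> array dict.

    ``n_inputs`` is the input feature width F (= |V| for one-hot features).
    Identical seeds give bitwise-identical parameters.
    """
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    in_dim = n_inputs
    for layer in range(config.n_layers):
        for j in config.powers:
            params[f"enc/l{layer}/W{j}"] = _xavier_uniform(
                rng, (in_dim, config.hidden_dim)
            )
        in_dim = config.d_star
    d_star, d_e, h = config.d_star, config.edge_dim, config.head_hidden_dim
    params["dec/Wb"] = _xavier_uniform(rng, (d_e, d_star, d_star))
    params["dec/b"] = np.zeros(d_e)
    params["dec/W1"] = _xavier_uniform(rng, (d_e, h))
    params["dec/b1"] = np.zeros(h)
    params["dec/W2"] = _xavier_uniform(rng, (h, 1))
    params["dec/b2"] = np.zeros(1)
    return params


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

def propagate_power(adj: NormalizedAdjacency, h: np.ndarray, j: int) -> np.ndarray:
    """Apply A_hat j times to a feature matrix by iterated sparse products."""
    if j < 0:
        raise ValueError("power must be nonnegative")
    h = np.asarray(h, dtype=np.float64)
    if h.shape[0] != adj.n_nodes:
        raise ValueError(
            f"feature matrix has {h.shape[0]} rows, adjacency expects {adj.n_nodes}"
        )
    out = h
    for _ in range(j):
        out = adj.matrix @ out
    return out


def _dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)


def hogc_layer_forward(
    adj: NormalizedAdjacency,
    h: np.ndarray | None,
    weights: Iterable[np.ndarray],
    powers: PowerSet,
    activation: str = "elu",
    dropout: float = 0.0,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    cache: dict | None = None,
) -> np.ndarray:
    """One HOGC layer: concat_j sigma(A_hat^j H W_j), blocks in ascending j.

    ``h=None`` means the implicit one-hot identity input (first layer on
    featureless graphs): A_hat^j I W_j = A_hat^j W_j, realized as a lookup so
    the |V| x |V| identity is never materialized.
    """
    act, _ = _get_activation(activation)
    weights = list(weights)
    if len(weights) != len(powers):
        raise ValueError("need exactly one weight matrix per adjacency power")
    onehot = h is None
    mask = None
    if train_mode and dropout > 0.0:
        if rng is None:
            raise ValueError("train_mode dropout requires an rng")
        mask = _dropout_mask(rng, adj.n_nodes if onehot else h.shape, dropout)
    if not onehot:
        h = np.asarray(h, dtype=np.float64)
        h_in = h * mask if mask is not None else h
    blocks = []
    pre_acts = []
    for j, w in zip(powers, weights):
        if onehot:
            if w.shape[0] != adj.n_nodes:
                raise ValueError(
                    f"power {j}: one-hot weights must have {adj.n_nodes} rows, "
                    f"got {w.shape[0]}"
                )
            w_eff = w * mask[:, None] if mask is not None else w
            m = propagate_power(adj, w_eff, j)
        else:
            if h_in.shape[1] != w.shape[0]:
                raise ValueError(
                    f"power {j}: input width {h_in.shape[1]} != weight rows {w.shape[0]}"
                )
            m = propagate_power(adj, h_in @ w, j)
        pre_acts.append(m)
        blocks.append(act(m))
    if cache is not None:
        cache.update(
            onehot=onehot,
            mask=mask,
            h_in=None if onehot else h_in,
            pre_acts=pre_acts,
        )
    return np.concatenate(blocks, axis=1)


def encode(
    adj: NormalizedAdjacency,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    features: np.ndarray | None = None,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    caches: list[dict] | None = None,
) -> np.ndarray:
    """Run L HOGC layers; returns the node embedding Z of shape |V| x d*."""
    h = None if features is None else np.asarray(features, dtype=np.float64)
    for layer in range(config.n_layers):
        layer_cache: dict | None = {} if caches is not None else None
        weights = [params[f"enc/l{layer}/W{j}"] for j in config.powers]
        h = hogc_layer_forward(
            adj,
            h,
            weights,
            config.powers,
            activation=config.activation,
            dropout=config.dropout,
            train_mode=train_mode,
            rng=rng,
            cache=layer_cache,
        )
        if caches is not None:
            caches.append(layer_cache)
    return h


def _encoder_backward(
    adj: NormalizedAdjacency,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    caches: list[dict],
    d_z: np.ndarray,
    grads: dict[str, np.ndarray],
) -> None:
    _, dact = _get_activation(config.activation)
    d = config.hidden_dim
    d_out = d_z
    for layer in reversed(range(config.n_layers)):
        cache = caches[layer]
        d_in = None if cache["onehot"] else np.zeros_like(cache["h_in"])
        for idx, j in enumerate(config.powers):
            d_m = d_out[:, idx * d : (idx + 1) * d] * dact(cache["pre_acts"][idx])
            t = propagate_power(adj, d_m, j)  # A_hat symmetric => (A^j)^T = A^j
            name = f"enc/l{layer}/W{j}"
            if cache["onehot"]:
                gw = t if cache["mask"] is None else cache["mask"][:, None] * t
            else:
                gw = cache["h_in"].T @ t
                d_in += t @ params[name].T
            grads[name] = grads.get(name, 0.0) + gw
        if not cache["onehot"]:
            if cache["mask"] is not None:
                d_in = d_in * cache["mask"]
            d_out = d_in
        # onehot layer is necessarily the first; nothing below it


# ---------------------------------------------------------------------------
# Decoder
# ---------------------------------------------------------------------------

def bilinear_fuse(
    z_i: np.ndarray, z_j: np.ndarray, w_b: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Edge representation e_ij = ELU(z_i^T W_b z_j + b).

    Accepts single vectors (d*,) or batches (B, d*); component m is
    ELU(sum_pq z_i[p] W_b[m,p,q] z_j[q] + b[m]).
    """
    single = z_i.ndim == 1
    zi = np.atleast_2d(np.asarray(z_i, dtype=np.float64))
    zj = np.atleast_2d(np.asarray(z_j, dtype=np.float64))
    d_e, d_star = w_b.shape[0], w_b.shape[1]
    if zi.shape[1] != d_star or zj.shape[1] != d_star:
        raise ValueError(
            f"embedding width {zi.shape[1]}/{zj.shape[1]} != bilinear dim {d_star}"
        )
    outer = zi[:, :, None] * zj[:, None, :]
    pre = outer.reshape(zi.shape[0], -1) @ w_b.reshape(d_e, -1).T + b
    e = _elu(pre)
    return e[0] if single else e


def predict_probability(
    e: np.ndarray, w1: np.ndarray, b1: np.ndarray, w2: np.ndarray, b2: np.ndarray
) -> np.ndarray:
    """p = sigmoid(FC2(ELU(FC1(e)))) in (0, 1)."""
    single = e.ndim == 1
    e2 = np.atleast_2d(np.asarray(e, dtype=np.float64))
    if e2.shape[1] != w1.shape[0]:
        raise ValueError(f"edge representation width {e2.shape[1]} != {w1.shape[0]}")
    s = _elu(e2 @ w1 + b1) @ w2 + b2
    p = _sigmoid(s).ravel()
    return float(p[0]) if single else p


# ---------------------------------------------------------------------------
# Full forward / backward over a batch of node pairs
# ---------------------------------------------------------------------------

def forward_pairs(
    adj: NormalizedAdjacency,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    pairs: np.ndarray,
    features: np.ndarray | None = None,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    want_cache: bool = False,
):
    """Predicted probabilities for (B, 2) index pairs; optional backward cache."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    caches: list[dict] | None = [] if want_cache else None
    z = encode(adj, params, config, features, train_mode, rng, caches)
    zi, zj = z[pairs[:, 0]], z[pairs[:, 1]]
    w_b, b = params["dec/Wb"], params["dec/b"]
    d_e = w_b.shape[0]
    outer = zi[:, :, None] * zj[:, None, :]
    e_pre = outer.reshape(len(pairs), -1) @ w_b.reshape(d_e, -1).T + b
    e = _elu(e_pre)
    e_mask = None
    if train_mode and config.dropout > 0.0:
        e_mask = _dropout_mask(rng, e.shape, config.dropout)
        e_drop = e * e_mask
    else:
        e_drop = e
    h_pre = e_drop @ params["dec/W1"] + params["dec/b1"]
    h = _elu(h_pre)
    s = h @ params["dec/W2"] + params["dec/b2"]
    p = _sigmoid(s).ravel()
    if not want_cache:
        return p
    cache = dict(
        pairs=pairs, layer_caches=caches, zi=zi, zj=zj, n_nodes=z.shape[0],
        e_pre=e_pre, e_mask=e_mask, e_drop=e_drop, h_pre=h_pre, h=h, p=p,
    )
    return p, cache


def backward_pairs(
    adj: NormalizedAdjacency,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    cache: dict,
    labels: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of the mean binary cross-entropy w.r.t. every parameter."""
    pairs, p = cache["pairs"], cache["p"]
    y = np.asarray(labels, dtype=np.float64).ravel()
    n = len(y)
    ds = ((p - y) / n)[:, None]  # d(mean BCE)/d(logit), sigmoid fused
    grads: dict[str, np.ndarray] = {}
    grads["dec/W2"] = cache["h"].T @ ds
    grads["dec/b2"] = ds.sum(axis=0)
    dh = (ds @ params["dec/W2"].T) * _delu(cache["h_pre"])
    grads["dec/W1"] = cache["e_drop"].T @ dh
    grads["dec/b1"] = dh.sum(axis=0)
    de = dh @ params["dec/W1"].T
    if cache["e_mask"] is not None:
        de = de * cache["e_mask"]
    de_pre = de * _delu(cache["e_pre"])
    grads["dec/b"] = de_pre.sum(axis=0)
    zi, zj = cache["zi"], cache["zj"]
    d_e = params["dec/Wb"].shape[0]
    d_star = zi.shape[1]
    outer = zi[:, :, None] * zj[:, None, :]
    grads["dec/Wb"] = (de_pre.T @ outer.reshape(n, -1)).reshape(d_e, d_star, d_star)
    g = (de_pre @ params["dec/Wb"].reshape(d_e, -1)).reshape(n, d_star, d_star)
    dzi = np.einsum("bpq,bq->bp", g, zj)
    dzj = np.einsum("bpq,bp->bq", g, zi)
    d_z = np.zeros((cache["n_nodes"], d_star))
    np.add.at(d_z, pairs[:, 0], dzi)
    np.add.at(d_z, pairs[:, 1], dzj)
    _encoder_backward(adj, params, config, cache["layer_caches"], d_z, grads)
    return grads


def predict_pairs(
    adj: NormalizedAdjacency,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    pairs: np.ndarray,
    features: np.ndarray | None = None,
    symmetrize: bool = False,
    chunk_size: int = 2048,
) -> np.ndarray:
    """Deterministic (eval-mode) probabilities, chunked for large pair sets.

    The bilinear tensor is not symmetric, so p_ij != p_ji in general;
    ``symmetrize=True`` averages both orientations.
    """
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    out = np.empty(len(pairs))
    for start in range(0, len(pairs), chunk_size):
        chunk = pairs[start : start + chunk_size]
        p = forward_pairs(adj, params, config, chunk, features)
        if symmetrize:
            p = 0.5 * (p + forward_pairs(adj, params, config, chunk[:, ::-1], features))
        out[start : start + len(chunk)] = p
    return out


# ---------------------------------------------------------------------------
# Checkpoints: one .npz archive with parameter arrays + JSON config
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    meta: Mapping | None = None,
) -> None:
    payload = {k.replace("/", "__"): np.asarray(v) for k, v in params.items()}
    payload["__config__"] = np.array(json.dumps(config.to_dict()))
    payload["__meta__"] = np.array(json.dumps(dict(meta or {})))
    np.savez(path, **payload)


def load_checkpoint(path: str):
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
        meta = json.loads(str(data["__meta__"]))
        params = {
            k.replace("__", "/"): data[k]
            for k in data.files
            if k not in ("__config__", "__meta__")
        }
    return params, config, meta
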