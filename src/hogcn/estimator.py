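"""scikit-learn style estimators for interaction-network link prediction.

:class:`HOGCNLinkPredictor` is the trainable model: a higher-order graph
convolutional encoder with a bilinear edge decoder. X is an (n, 2) array of
node index pairs, y their binary interaction labels; the interaction network
itself is passed to ``fit`` so the estimator composes with sklearn
``clone``/``get_params`` machinery (the graph is data, not a hyperparameter).

:class:`HeuristicLinkPredictor` wraps the deterministic TCP / L3 network
similarity scores behind the same scoring interface for baseline comparisons.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .graph_io import InteractionGraph, LabeledEdgeSet
from .heuristics import score_pairs
from .model import ModelConfig, PowerSet, predict_pairs
from .training import TrainConfig, derive_seeds, fit_labeled

__all__ = ["HOGCNLinkPredictor", "HeuristicLinkPredictor"]


def _check_pairs(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("X must be an (n, 2) array of node index pairs")
    return x


class HOGCNLinkPredictor(ClassifierMixin, BaseEstimator):
    """Higher-order graph convolutional link predictor.

    Parameters
    ----------
    n_layers : int, default=2
        Number of HOGC layers L.
    k : int, default=3
        Maximum adjacency power; each layer mixes P = {0, 1, ..., k}.
    hidden_dim : int, default=32
        Per-power width d; embeddings have width d * (k + 1).
    edge_dim : int, default=64
        Bilinear edge-representation length.
    head_hidden_dim : int, default=32
        Hidden width of the 2-layer prediction head.
    dropout : float, default=0.1
        Dropout rate on layer inputs and the edge representation.
    activation : str, default='elu'
        Nonlinearity in the HOGC layers ('elu', 'relu', 'tanh', 'identity').
    learning_rate, batch_size, max_epochs, patience
        Adam / early-stopping settings (defaults 5e-4, 256, 50, 10); early
        stopping monitors validation AUPRC and restores the best epoch.
    val_fraction : float, default=0.1
        Fraction of the training pairs held out for early stopping when no
        explicit validation set is given to ``fit``.
    symmetrize : bool, default=False
        Average p_ij and p_ji at prediction time.
    random_state : int, default=0
        Master seed; initialization, shuffling and validation carving derive
        from it.

    Attributes
    ----------
    params_ : dict of str -> ndarray
        Trained weights (best validation epoch).
    history_ : TrainHistory
        Per-epoch loss and validation metrics.
    adj_ : NormalizedAdjacency
        Message-passing operator built from the positive training edges.
    classes_ : ndarray
        ``[0, 1]``.
    """

    def __init__(
        self,
        n_layers: int = 2,
        k: int = 3,
        hidden_dim: int = 32,
        edge_dim: int = 64,
        head_hidden_dim: int = 32,
        dropout: float = 0.1,
        activation: str = "elu",
        learning_rate: float = 5e-4,
        batch_size: int = 256,
        max_epochs: int = 50,
        patience: int = 10,
        val_fraction: float = 0.1,
        symmetrize: bool = False,
        random_state: int = 0,
    ):
        self.n_layers = n_layers
        self.k = k
        self.hidden_dim = hidden_dim
        self.edge_dim = edge_dim
        self.head_hidden_dim = head_hidden_dim
        self.dropout = dropout
        self.activation = activation
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.symmetrize = symmetrize
        self.random_state = random_state

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            n_layers=self.n_layers,
            powers=PowerSet.up_to(self.k),
            hidden_dim=self.hidden_dim,
            edge_dim=self.edge_dim,
            head_hidden_dim=self.head_hidden_dim,
            dropout=self.dropout,
            activation=self.activation,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.max_epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            patience=min(self.patience, self.max_epochs),
            seed=self.random_state,
        )

    def fit(self, X, y, graph: InteractionGraph = None, validation=None, features=None):
        """Fit on labeled node pairs.

        Parameters
        ----------
        X : (n, 2) int array of node index pairs.
        y : binary labels (1 = interaction, 0 = sampled non-interaction).
        graph : InteractionGraph, required keyword
            Supplies node count/typing; the message-passing adjacency uses
            only the positive pairs in X, never held-out edges.
        validation : optional (X_val, y_val)
            Explicit early-stopping set; otherwise ``val_fraction`` of X is
            carved out with a seeded shuffle, stratified by label.
        features : optional (|V|, F) node feature matrix (default one-hot).
        """
        if graph is None:
            raise ValueError("fit requires the interaction graph (graph=...)")
        X = _check_pairs(X)
        y = np.asarray(y, dtype=np.int64).ravel()
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if validation is not None:
            x_tr, y_tr = X, y
            x_val, y_val = _check_pairs(validation[0]), np.asarray(validation[1]).ravel()
        else:
            split_seed = derive_seeds(self.random_state)[0]
            rng = np.random.default_rng(split_seed)
            val_mask = np.zeros(len(y), dtype=bool)
            for label in (0, 1):
                idx = np.flatnonzero(y == label)
                n_val = max(1, int(round(self.val_fraction * len(idx))))
                val_mask[rng.permutation(idx)[:n_val]] = True
            x_tr, y_tr = X[~val_mask], y[~val_mask]
            x_val, y_val = X[val_mask], y[val_mask]
        self.params_, self.history_, self.adj_ = fit_labeled(
            graph,
            LabeledEdgeSet(x_tr, y_tr),
            LabeledEdgeSet(x_val, y_val),
            model_config=self._model_config(),
            train_config=self._train_config(),
            features=features,
        )
        self.graph_ = graph
        self.features_ = features
        self.config_ = self._model_config()
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        p = predict_pairs(
            self.adj_,
            self.params_,
            self.config_,
            _check_pairs(X),
            features=self.features_,
            symmetrize=self.symmetrize,
        )
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)


class HeuristicLinkPredictor(BaseEstimator):
    """Deterministic network-similarity baseline (TCP common-neighbor count
    or degree-normalized L3 path score).

    ``fit`` only stores the graph; ``decision_function`` returns raw
    similarity scores (not probabilities), suitable for AUROC/AUPRC ranking.
    """

    def __init__(self, method: str = "l3"):
        self.method = method

    def fit(self, X=None, y=None, graph: InteractionGraph = None):
        if graph is None:
            raise ValueError("fit requires the interaction graph (graph=...)")
        if self.method not in ("tcp", "l3"):
            raise ValueError("method must be 'tcp' or 'l3'")
        self.graph_ = graph
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "graph_")
        return score_pairs(self.graph_, _check_pairs(X), method=self.method)
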