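"""The silencer classifier: a CNN over 21 x 600 linear features, a two-round
GraphSAGE branch over the interaction network, and an MLP head.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``) and the semi-supervised labelling
convention of ``LabelPropagation``: ``y`` covers every node of the graph and
unlabeled nodes carry ``-1``.  Unlabeled nodes never enter the loss but their
descriptors still participate in neighbourhood aggregation, so the graph
branch sees the full network during training.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

__all__ = ["GraphData", "SilenceREINClassifier", "sage_aggregate"]


@dataclass
class GraphData:
    """Node-aligned inputs for the classifier.

    ``linear``: (n, 21, 600) per-node linear feature tensor (may be ``None``
    for estimators that ignore it); ``descriptors``: (n, 10) structural
    descriptors; ``edges``: (m, 2) undirected edge list over node indices,
    self-loops allowed.
    """

    linear: np.ndarray | None
    descriptors: np.ndarray
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=np.float64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.linear is not None:
            self.linear = np.asarray(self.linear, dtype=np.float64)
            if self.linear.ndim != 3 or self.linear.shape[0] != self.n_nodes:
                raise ValueError(
                    f"linear features must be (n_nodes, channels, length); "
                    f"got {self.linear.shape} for {self.n_nodes} nodes"
                )
        if self.edges.size and (
            self.edges.min() < 0 or self.edges.max() >= self.n_nodes
        ):
            raise ValueError("edge endpoint outside node range")

    @property
    def n_nodes(self) -> int:
        return self.descriptors.shape[0]

    def subset(self, idx: Sequence[int]) -> "GraphData":
        """Induced subgraph on ``idx`` (edges with both endpoints kept)."""
        idx = np.asarray(idx, dtype=np.int64)
        pos = -np.ones(self.n_nodes, dtype=np.int64)
        pos[idx] = np.arange(len(idx))
        keep = (pos[self.edges[:, 0]] >= 0) & (pos[self.edges[:, 1]] >= 0)
        edges = pos[self.edges[keep]]
        lin = None if self.linear is None else self.linear[idx]
        return GraphData(lin, self.descriptors[idx], edges)


def sage_aggregate(
    h_self: np.ndarray,
    neighbor_hs: Sequence[np.ndarray],
    W: np.ndarray,
    activation: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """One mean-aggregation update for a single node.

    Returns ``activation(W @ mean({h_self} ∪ neighbor_hs))``; the mean always
    includes the node's own previous representation.  ``activation=None``
    means identity.
    """
    h_self = np.asarray(h_self, dtype=np.float64)
    stack = [h_self] + [np.asarray(h, dtype=np.float64) for h in neighbor_hs]
    dims = {v.shape for v in stack}
    if len(dims) > 1:
        raise ValueError(f"representation dimensions differ: {dims}")
    mean = np.mean(stack, axis=0)
    W = np.asarray(W, dtype=np.float64)
    if W.shape[1] != mean.shape[0]:
        raise ValueError(
            f"weight matrix maps dim {W.shape[1]}, inputs have dim {mean.shape[0]}"
        )
    out = W @ mean
    return out if activation is None else activation(out)


class SilenceREINClassifier(BaseEstimator, ClassifierMixin):
    """CNN + GraphSAGE + MLP node classifier for silencers.

    The CNN branch runs four units of (same-padded convolution, LeakyReLU,
    width-4 max pooling, dropout) over the 21 x 600 linear features, then a
    global max over positions gives a 100-d summary.  The graph branch runs
    two rounds of mean aggregation (self + neighbours) each followed by a
    learned projection, giving a second 100-d embedding.  The concatenated
    200-d vector feeds fully connected layers of 256, 64 and 2 units.

    Training minimizes class-weighted cross-entropy (weight ``class_weight``
    on the silencer class) with Adam, L2 coefficient ``l2``, and multiplies
    the learning rate by ``gamma`` after any epoch whose training loss
    exceeded the previous epoch's.  Early stopping watches a held-out
    validation split of the labelled nodes.

    Parameters largely mirror the published calibration: ``lr=1e-4``,
    ``l2=1e-4``, ``class_weight=1.2``, ``gamma=0.95``, ``dropout=0.2``,
    CNN channels 21->100 then 100->100, SAGE 10->100, MLP 256/64/2.
    """

    def __init__(
        self,
        cnn_channels: int = 100,
        kernel: int = 8,
        pool: int = 4,
        sage_channels: int = 100,
        sage_rounds: int = 2,
        mlp_sizes: tuple[int, ...] = (256, 64, 2),
        dropout: float = 0.2,
        lr: float = 1e-4,
        l2: float = 1e-4,
        class_weight: float = 1.2,
        gamma: float = 0.95,
        batch_size: int = 32,
        max_epochs: int = 100,
        patience: int = 10,
        validation_fraction: float = 0.1,
        threshold: float = 0.5,
        dtype: str = "float32",
        random_state: int = 0,
    ):
        self.cnn_channels = cnn_channels
        self.kernel = kernel
        self.pool = pool
        self.sage_channels = sage_channels
        self.sage_rounds = sage_rounds
        self.mlp_sizes = mlp_sizes
        self.dropout = dropout
        self.lr = lr
        self.l2 = l2
        self.class_weight = class_weight
        self.gamma = gamma
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.dtype = dtype
        self.random_state = random_state

    # ------------------------------------------------------------------
    # architecture

    def _build(self, X: GraphData, rng: np.random.Generator) -> None:
        dt = np.dtype(self.dtype)
        in_ch = X.linear.shape[1]
        drop_rng = np.random.default_rng(rng.integers(2**31))
        self._cnn = []
        ch = in_ch
        for _ in range(4):
            self._cnn.append(
                (
                    nn.Conv1dSame(ch, self.cnn_channels, self.kernel, rng=rng, dtype=dt),
                    nn.LeakyReLU(),
                    nn.MaxPool1d(self.pool),
                    nn.Dropout(self.dropout, rng=drop_rng),
                )
            )
            ch = self.cnn_channels
        self._gmp = nn.GlobalMaxPool1d()
        self._agg = nn.MeanAggregate(X.n_nodes, X.edges, dtype=dt)
        self._agg_src = X
        self._sage = []
        d_in = X.descriptors.shape[1]
        for _ in range(self.sage_rounds):
            self._sage.append(
                (
                    nn.Dense(d_in, self.sage_channels, rng=rng, dtype=dt),
                    nn.LeakyReLU(),
                    nn.Dropout(self.dropout, rng=drop_rng),
                )
            )
            d_in = self.sage_channels
        self._mlp = []
        m_in = self.cnn_channels + self.sage_channels
        for i, size in enumerate(self.mlp_sizes):
            dense = nn.Dense(m_in, size, rng=rng, dtype=dt)
            last = i == len(self.mlp_sizes) - 1
            self._mlp.append(
                (
                    dense,
                    None if last else nn.LeakyReLU(),
                    None if last else nn.Dropout(self.dropout, rng=drop_rng),
                )
            )
            m_in = size

    def _all_layers(self) -> list:
        layers = [c for unit in self._cnn for c in unit]
        layers += [d for unit in self._sage for d in unit]
        layers += [d for unit in self._mlp for d in unit if d is not None]
        return layers

    def _parameters(self):
        out = []
        for layer in self._all_layers():
            if hasattr(layer, "params"):
                out.extend(layer.params())
        return out

    def _l2_weights(self):
        out = []
        for layer in self._all_layers():
            if hasattr(layer, "l2_params"):
                out.extend(layer.l2_params())
        return out

    # ------------------------------------------------------------------
    # forward / backward

    def _forward(self, X: GraphData, idx: np.ndarray, train: bool) -> np.ndarray:
        dt = np.dtype(self.dtype)
        if X is not self._agg_src:
            # a different graph (e.g. prediction on the full network after
            # isolated training) needs its own aggregation operator
            self._agg = nn.MeanAggregate(X.n_nodes, X.edges, dtype=dt)
            self._agg_src = X
        lin = (X.linear[idx] - self._lin_mean) / self._lin_scale
        h = lin.astype(dt)
        for conv, act, pool, drop in self._cnn:
            h = drop.forward(pool.forward(act.forward(conv.forward(h))), train)
        cnn_out = self._gmp.forward(h)

        d = ((X.descriptors - self._desc_mean) / self._desc_scale).astype(dt)
        for dense, act, drop in self._sage:
            d = drop.forward(act.forward(dense.forward(self._agg.forward(d))), train)
        self._sage_full = d
        sage_out = d[idx]

        z = np.concatenate([cnn_out, sage_out], axis=1)
        for dense, act, drop in self._mlp:
            z = dense.forward(z)
            if act is not None:
                z = drop.forward(act.forward(z), train)
        self._idx = idx
        return z

    def _backward(self, grad: np.ndarray) -> None:
        g = grad
        for dense, act, drop in reversed(self._mlp):
            if act is not None:
                g = act.backward(drop.backward(g))
            g = dense.backward(g)
        n_cnn = self.cnn_channels
        g_cnn, g_sage_rows = g[:, :n_cnn], g[:, n_cnn:]

        g_sage = np.zeros_like(self._sage_full)
        g_sage[self._idx] = g_sage_rows
        for dense, act, drop in reversed(self._sage):
            g_sage = dense.backward(act.backward(drop.backward(g_sage)))
            g_sage = self._agg.backward(g_sage)

        g = self._gmp.backward(g_cnn)
        for conv, act, pool, drop in reversed(self._cnn):
            g = conv.backward(act.backward(pool.backward(drop.backward(g))))

    def _loss(self, X: GraphData, idx: np.ndarray, y: np.ndarray, train: bool):
        logits = self._forward(X, idx, train)
        loss, grad = nn.weighted_cross_entropy(logits, y[idx], self._class_weights)
        return logits, loss, grad

    # ------------------------------------------------------------------
    # sklearn interface

    def fit(self, X: GraphData, y) -> "SilenceREINClassifier":
        """Train on a graph; ``y[i] = -1`` marks node ``i`` unlabeled."""
        if X.linear is None:
            raise ValueError("GraphData.linear is required for training")
        y = np.asarray(y, dtype=np.int64)
        if y.shape[0] != X.n_nodes:
            raise ValueError("y must give one entry (-1, 0 or 1) per node")
        labeled = np.flatnonzero(y >= 0)
        classes = np.unique(y[labeled])
        if classes.size < 2:
            raise ValueError(
                "training requires both classes present among labelled nodes"
            )
        self.classes_ = np.array([0, 1])
        self._class_weights = np.array([1.0, self.class_weight], dtype=np.float64)

        rng = np.random.default_rng(self.random_state)
        # stratified validation split of the labelled nodes
        val_idx = np.empty(0, dtype=np.int64)
        train_idx = labeled
        if self.validation_fraction > 0 and self.patience < self.max_epochs:
            parts = []
            for cls in (0, 1):
                members = labeled[y[labeled] == cls]
                members = members[rng.permutation(len(members))]
                n_val = int(np.floor(self.validation_fraction * len(members)))
                parts.append(members[:n_val])
            val_idx = np.sort(np.concatenate(parts))
            train_idx = np.setdiff1d(labeled, val_idx)
            if np.unique(y[train_idx]).size < 2:
                val_idx = np.empty(0, dtype=np.int64)
                train_idx = labeled

        # per-channel standardization fitted on training nodes
        lin_t = X.linear[train_idx]
        self._lin_mean = lin_t.mean(axis=(0, 2), keepdims=True)[0]
        self._lin_scale = lin_t.std(axis=(0, 2), keepdims=True)[0]
        self._lin_scale[self._lin_scale < 1e-8] = 1.0
        self._desc_mean = X.descriptors[train_idx].mean(axis=0)
        self._desc_scale = X.descriptors[train_idx].std(axis=0)
        self._desc_scale[self._desc_scale < 1e-8] = 1.0

        self._build(X, rng)
        params = self._parameters()
        opt = nn.Adam(params, lr=self.lr)
        l2_weights = self._l2_weights()

        history = {"train_loss": [], "val_loss": [], "lr": []}
        lr = self.lr
        best_val = np.inf
        best_state = None
        stall = 0
        prev_loss = None
        l2_grads = [
            (W, g)
            for W in l2_weights
            for p, g in params
            if p is W
        ]
        bs = self.batch_size if self.batch_size > 0 else len(train_idx)
        for _epoch in range(self.max_epochs):
            opt.lr = lr
            history["lr"].append(lr)
            order = train_idx[rng.permutation(len(train_idx))]
            losses, sizes = [], []
            for start in range(0, len(order), bs):
                batch = order[start : start + bs]
                _, loss, grad = self._loss(X, batch, y, train=True)
                self._backward(grad)
                if self.l2 > 0:
                    for W, g in l2_grads:
                        g += self.l2 * W
                opt.step()
                losses.append(loss)
                sizes.append(len(batch))
            loss = float(np.average(losses, weights=sizes))
            history["train_loss"].append(loss)
            if prev_loss is not None and loss > prev_loss:
                lr *= self.gamma
            prev_loss = loss

            if val_idx.size:
                _, vloss, _ = self._loss(X, val_idx, y, train=False)
                history["val_loss"].append(vloss)
                if vloss < best_val - 1e-9:
                    best_val = vloss
                    best_state = [p.copy() for p, _ in params]
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if best_state is not None:
            for (p, _), saved in zip(params, best_state):
                p[...] = saved
        self.history_ = history
        self.n_features_in_ = int(np.prod(X.linear.shape[1:]))
        self._graph_shape = (X.n_nodes, X.linear.shape[1], X.linear.shape[2])
        return self

    def decision_function(self, X: GraphData, indices=None) -> np.ndarray:
        return self.predict_proba(X, indices)[:, 1]

    def predict_proba(self, X: GraphData, indices=None) -> np.ndarray:
        """Softmax class probabilities, rows ordered as ``indices``
        (default: every node)."""
        check_is_fitted(self, "history_")
        idx = (
            np.arange(X.n_nodes)
            if indices is None
            else np.asarray(indices, dtype=np.int64)
        )
        logits = self._forward(X, idx, train=False)
        return nn.softmax(logits.astype(np.float64))

    def predict(self, X: GraphData, indices=None, threshold=None) -> np.ndarray:
        """Label 1 (silencer) iff the silencer score reaches the threshold."""
        thr = self.threshold if threshold is None else threshold
        proba = self.predict_proba(X, indices)
        return (proba[:, 1] >= thr).astype(np.int64)

    def clone_unfitted(self) -> "SilenceREINClassifier":
        return copy.deepcopy(
            SilenceREINClassifier(**self.get_params())
        )
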