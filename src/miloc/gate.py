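"""Graph attention auto-encoder over the miRNA functional network.

The encoder updates each node's representation from its neighbors with
learned attention:

    e_ij    = sigmoid(v_s . act(W h_i) + v_r . act(W h_j))
    alpha_i = softmax of e_i over N(i) u {i}        (self-loops added)
    h'_i    = act(sum_j alpha_ij W h_j)

The decoder mirrors the encoder with transposed weights and its own attention
parameters, reconstructing the raw input.  The loss is the squared feature
reconstruction error plus ``structure_loss_weight`` times a structure term
(negative log-sigmoid of embedding inner products over the graph's edges),
which pushes adjacent nodes together in the latent space.
"""

from __future__ import annotations

import logging

import numpy as np

from ._autodiff import Adam, Tensor, glorot
from .config import GateParams
from .datatypes import EntityIndex, ValidationError, WeightedGraph

logger = logging.getLogger("miloc")

_ACTIVATIONS = {
    "sigmoid": lambda t: t.sigmoid(),
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "linear": lambda t: t,
}


def _attention_matrix(
    H: Tensor, W: Tensor, v_s: Tensor, v_r: Tensor, mask: np.ndarray, act
) -> tuple[Tensor, Tensor]:
    """Masked attention over ``mask`` (adjacency incl. self-loops).

    Returns (alpha, WH) where alpha rows sum to 1 over the neighborhood.
    """
    WH = H @ W
    f = act(WH) @ v_s   # n x 1, sender term
    g = act(WH) @ v_r   # n x 1, receiver term
    E = (f + g.T).sigmoid()
    alpha = E.masked_softmax(mask, axis=1)
    return alpha, WH


def attention_weights(
    H: np.ndarray,
    graph: WeightedGraph,
    W: np.ndarray,
    v_s: np.ndarray,
    v_r: np.ndarray,
    activation: str = "sigmoid",
) -> np.ndarray:
    """Attention coefficients alpha_ij for given layer parameters.

    Rows are probability vectors supported on N(i) plus the self-loop.
    """
    mask = _self_loop_mask(graph)
    act = _ACTIVATIONS[activation]
    alpha, _ = _attention_matrix(
        Tensor(H), Tensor(W), Tensor(np.reshape(v_s, (-1, 1))),
        Tensor(np.reshape(v_r, (-1, 1))), mask, act,
    )
    return alpha.data


def _self_loop_mask(graph: WeightedGraph) -> np.ndarray:
    mask = graph.adjacency.toarray() > 0
    np.fill_diagonal(mask, True)
    return mask


class GraphAttentionAutoencoder:
    """sklearn-style transformer refining node features along a graph.

    ``fit(X, graph)`` trains the auto-encoder; ``embedding_`` holds the
    encoder output (n x layer_dims[-1]) and ``loss_history_`` the per-epoch
    total loss.  ``transform(X)`` re-encodes features with the trained
    parameters and the stored graph.
    """

    def __init__(self, layer_dims: tuple[int, ...] = (128,),
                 learning_rate: float = 1e-3, epochs: int = 200,
                 structure_loss_weight: float = 1.0,
                 activation: str = "tanh", random_state: int = 0):
        self.layer_dims = tuple(layer_dims)
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.structure_loss_weight = structure_loss_weight
        self.activation = activation
        self.random_state = random_state

    @classmethod
    def from_params(cls, params: GateParams, random_state: int = 0):
        return cls(
            layer_dims=params.layer_dims,
            learning_rate=params.learning_rate,
            epochs=params.epochs,
            structure_loss_weight=params.structure_loss_weight,
            activation=params.activation,
            random_state=random_state,
        )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "layer_dims", "learning_rate", "epochs", "structure_loss_weight",
            "activation", "random_state")}

    def set_params(self, **params) -> "GraphAttentionAutoencoder":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- model -------------------------------------------------------------

    def _init_params(self, input_dim: int, rng: np.random.Generator) -> dict:
        dims = [input_dim, *self.layer_dims]
        enc, dec = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            enc.append({
                "W": glorot(rng, d_in, d_out),
                "v_s": glorot(rng, d_out, 1),
                "v_r": glorot(rng, d_out, 1),
            })
        for layer in reversed(enc):
            d_in = layer["W"].shape[0]
            dec.append({
                "W": layer["W"],  # shared, used transposed
                "v_s": glorot(rng, d_in, 1),
                "v_r": glorot(rng, d_in, 1),
            })
        return {"encoder": enc, "decoder": dec}

    def _forward(self, X: Tensor, mask: np.ndarray, params: dict):
        act = _ACTIVATIONS[self.activation]
        H = X
        for layer in params["encoder"]:
            alpha, WH = _attention_matrix(
                H, layer["W"], layer["v_s"], layer["v_r"], mask, act
            )
            H = act(alpha @ WH)
        Z = H
        decoder = params["decoder"]
        for k, layer in enumerate(decoder):
            Wt = layer["W"].T
            alpha, WH = _attention_matrix(
                H, Wt, layer["v_s"], layer["v_r"], mask, act
            )
            H = alpha @ WH
            if k < len(decoder) - 1:
                H = act(H)
            # final decoder layer stays linear: raw features are signed and
            # unbounded, so a squashing output could never reconstruct them
        return Z, H

    def _loss(self, X: Tensor, Z: Tensor, X_hat: Tensor,
              edge_mask: np.ndarray):
        diff = X_hat - X
        feat = (diff * diff).sum()
        if self.structure_loss_weight > 0 and edge_mask.any():
            # -sum over directed edges of log sigmoid(z_i . z_j), computed on
            # the dense Gram matrix (cheap at these n, avoids per-edge gathers)
            inner = Z @ Z.T
            struct = -((inner.sigmoid().clip(1e-12, 1.0).log()) * edge_mask).sum()
        else:
            struct = Tensor(0.0)
        total = feat + self.structure_loss_weight * struct
        return total, feat, struct

    # -- API ---------------------------------------------------------------

    def fit(self, X: np.ndarray, graph: WeightedGraph,
            y=None) -> "GraphAttentionAutoencoder":
        X = np.asarray(X, dtype=float)
        if X.shape[0] != len(graph):
            raise ValidationError(
                f"feature rows ({X.shape[0]}) do not match graph nodes "
                f"({len(graph)})"
            )
        rng = np.random.default_rng(self.random_state)
        mask = _self_loop_mask(graph)
        edge_mask = (graph.adjacency.toarray() > 0).astype(float)
        params = self._init_params(X.shape[1], rng)
        trainable = [t for layer in params["encoder"] + params["decoder"]
                     for t in layer.values()]
        # deduplicate shared encoder/decoder weights
        uniq = list({id(t): t for t in trainable}.values())
        opt = Adam(uniq, lr=self.learning_rate)
        Xt = Tensor(X)
        history = []
        for _ in range(self.epochs):
            opt.zero_grad()
            Z, X_hat = self._forward(Xt, mask, params)
            total, feat, struct = self._loss(Xt, Z, X_hat, edge_mask)
            total.backward()
            opt.step()
            history.append(float(total.data))
        if not np.isfinite(history).all():
            raise ValidationError("non-finite loss during auto-encoder training")
        self.params_ = params
        self.mask_ = mask
        self.edge_mask_ = edge_mask
        self.graph_ = graph
        self.loss_history_ = history
        Z, X_hat = self._forward(Xt, mask, params)
        self.embedding_ = Z.data
        self.reconstruction_ = X_hat.data
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z, _ = self._forward(Tensor(np.asarray(X, dtype=float)),
                             self.mask_, self.params_)
        return Z.data

    def fit_transform(self, X: np.ndarray, graph: WeightedGraph) -> np.ndarray:
        return self.fit(X, graph).embedding_

    def reconstruct(self, X: np.ndarray) -> tuple[np.ndarray, float, float]:
        """Reconstruction and the two loss components for given features."""
        Xt = Tensor(np.asarray(X, dtype=float))
        Z, X_hat = self._forward(Xt, self.mask_, self.params_)
        _, feat, struct = self._loss(Xt, Z, X_hat, self.edge_mask_)
        return X_hat.data, float(feat.data), float(struct.data)


def gate_fit(
    X: np.ndarray,
    graph: WeightedGraph,
    params: GateParams | None = None,
    seed: int = 0,
) -> tuple[GraphAttentionAutoencoder, np.ndarray]:
    """Train the auto-encoder on ``X`` over ``graph``; return (model, Z)."""
    model = GraphAttentionAutoencoder.from_params(params or GateParams(), seed)
    Z = model.fit_transform(X, graph)
    return model, Z


def gate_reconstruct(
    model: GraphAttentionAutoencoder, X: np.ndarray
) -> tuple[np.ndarray, float, float]:
    return model.reconstruct(X)
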