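"""Multi-label localization classifier: self-attention + fully-connected net.

The concatenated feature vector is split into its five feature-type blocks,
each linearly projected to a common token dimension.  Scaled dot-product
self-attention across the five tokens lets the net weigh feature sources
against each other; the attended tokens are concatenated and passed through
two ReLU hidden layers into a 7-unit sigmoid output, trained with binary
cross-entropy under Adam.  The attention stage can be disabled (ablation),
in which case the raw concatenation feeds the hidden layers directly.
"""

from __future__ import annotations

import logging

import numpy as np

from ._autodiff import Adam, Tensor, glorot, zeros
from .config import ClassifierParams
from .datatypes import MIRNA_LOCALIZATIONS, ValidationError

logger = logging.getLogger("miloc")

BCE_EPS = 1e-7


def bce_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Summed binary cross-entropy with predictions clipped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValidationError(
            f"label shape {y.shape} does not match prediction shape {y_hat.shape}"
        )
    p = np.clip(y_hat, BCE_EPS, 1 - BCE_EPS)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def _bce_tensor(y: np.ndarray, y_hat: Tensor) -> Tensor:
    p = y_hat.clip(BCE_EPS, 1 - BCE_EPS)
    yt = Tensor(y)
    return -(yt * p.log() + (1 - yt) * (1 - p).log()).sum()


def binarize_predictions(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label ell is predicted iff score >= threshold (ties predict)."""
    if not 0 < threshold < 1:
        raise ValidationError("decision threshold must be in (0, 1)")
    return (np.asarray(scores) >= threshold).astype(np.int8)


class LocalizationClassifier:
    """sklearn-style multi-label classifier over block-structured features.

    Parameters
    ----------
    block_dims:
        Widths of the feature-type blocks laid out left-to-right in the input
        matrix (e.g. ``(64, 128, 128, 128, 4)``).  ``None`` treats the whole
        input as a single block.
    use_attention:
        Whether to apply token self-attention across blocks before the
        fully-connected stage.
    attention_dim:
        Common projection width for the block tokens.
    hidden_sizes, learning_rate, epochs, batch_size:
        Fully-connected stage and Adam settings; ``batch_size=None`` is full
        batch.
    threshold:
        Decision threshold applied by :meth:`predict`.

    After ``fit``: ``loss_history_`` (per-epoch training BCE), ``n_params_``
    (trainable parameter count), ``n_features_in_``.
    """

    N_LABELS = len(MIRNA_LOCALIZATIONS)

    def __init__(self, block_dims: tuple[int, ...] | None = None,
                 use_attention: bool = True, attention_dim: int = 128,
                 hidden_sizes: tuple[int, ...] = (256, 64),
                 learning_rate: float = 1e-3, epochs: int = 300,
                 batch_size: int | None = None, threshold: float = 0.5,
                 weight_decay: float = 0.3, dropout: float = 0.0,
                 random_state: int = 0):
        self.block_dims = block_dims
        self.use_attention = use_attention
        self.attention_dim = attention_dim
        self.hidden_sizes = tuple(hidden_sizes)
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.threshold = threshold
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.random_state = random_state

    @classmethod
    def from_params(cls, params: ClassifierParams,
                    block_dims: tuple[int, ...] | None = None,
                    random_state: int = 0) -> "LocalizationClassifier":
        return cls(
            block_dims=block_dims,
            use_attention=params.use_attention,
            attention_dim=params.attention_dim,
            hidden_sizes=params.hidden_sizes,
            learning_rate=params.learning_rate,
            epochs=params.epochs,
            batch_size=params.batch_size,
            threshold=params.threshold,
            weight_decay=params.weight_decay,
            dropout=params.dropout,
            random_state=random_state,
        )

    _PARAM_NAMES = ("block_dims", "use_attention", "attention_dim",
                    "hidden_sizes", "learning_rate", "epochs", "batch_size",
                    "threshold", "weight_decay", "dropout", "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._PARAM_NAMES}

    def set_params(self, **params) -> "LocalizationClassifier":
        for k, v in params.items():
            if k not in self._PARAM_NAMES:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- model -------------------------------------------------------------

    def _init(self, d_in: int, rng: np.random.Generator) -> dict:
        params: dict = {}
        if self.use_attention:
            dims = self.block_dims or (d_in,)
            a = self.attention_dim
            params["proj"] = [glorot(rng, d, a) for d in dims]
            params["Wq"] = glorot(rng, a, a)
            params["Wk"] = glorot(rng, a, a)
            params["Wv"] = glorot(rng, a, a)
            width = len(dims) * a
        else:
            width = d_in
        params["fc"] = []
        for h in self.hidden_sizes:
            params["fc"].append((glorot(rng, width, h), zeros(h)))
            width = h
        params["out"] = (glorot(rng, width, self.N_LABELS), zeros(self.N_LABELS))
        return params

    def _attend(self, X: Tensor, params: dict) -> tuple[Tensor, Tensor]:
        dims = self.block_dims or (X.shape[1],)
        offsets = np.concatenate([[0], np.cumsum(dims)])
        tokens = []
        for k, P in enumerate(params["proj"]):
            lo, hi = int(offsets[k]), int(offsets[k + 1])
            tokens.append(_col_slice(X, lo, hi) @ P)
        T = Tensor.stack(tokens, axis=1)            # n x B x a
        a = self.attention_dim
        n, B = T.shape[0], len(tokens)
        T2 = T.reshape(n * B, a)  # collapse batch for one GEMM per projection
        Q = (T2 @ params["Wq"]).reshape(n, B, a)
        K = (T2 @ params["Wk"]).reshape(n, B, a)
        V = (T2 @ params["Wv"]).reshape(n, B, a)
        scores = (Q @ K.swapaxes(1, 2)) * (1.0 / np.sqrt(a))
        attn = scores.softmax(axis=2)               # n x B x B, rows sum to 1
        out = attn @ V                              # n x B x a
        flat = out.reshape(out.shape[0], len(tokens) * a)
        return flat, attn

    def _forward(self, X: Tensor, params: dict,
                 dropout_rng: np.random.Generator | None = None
                 ) -> tuple[Tensor, Tensor | None]:
        attn = None
        H = X
        if self.use_attention:
            H, attn = self._attend(X, params)
        for W, b in params["fc"]:
            H = (H @ W + b).relu()
            if dropout_rng is not None and self.dropout > 0:
                H = H.dropout(self.dropout, dropout_rng)
        W, b = params["out"]
        return (H @ W + b).sigmoid(), attn

    @staticmethod
    def _count_params(params: dict) -> int:
        total = 0
        stack = list(params.values())
        while stack:
            item = stack.pop()
            if isinstance(item, Tensor):
                total += item.data.size
            elif isinstance(item, (list, tuple)):
                stack.extend(item)
        return total

    def _trainables(self, params: dict) -> list[Tensor]:
        out: list[Tensor] = []
        stack = list(params.values())
        while stack:
            item = stack.pop()
            if isinstance(item, Tensor):
                out.append(item)
            elif isinstance(item, (list, tuple)):
                stack.extend(item)
        return out

    # -- API ---------------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "LocalizationClassifier":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2:
            raise ValidationError("X and Y must be 2-D")
        if len(X) != len(Y):
            raise ValidationError("X and Y row counts differ")
        if len(X) < 2:
            raise ValidationError("need at least 2 training samples")
        if Y.shape[1] != self.N_LABELS:
            raise ValidationError(f"Y must have {self.N_LABELS} label columns")
        if self.block_dims and sum(self.block_dims) != X.shape[1]:
            raise ValidationError(
                f"block dims {self.block_dims} sum to {sum(self.block_dims)}, "
                f"but X has {X.shape[1]} columns"
            )
        rng = np.random.default_rng(self.random_state)
        params = self._init(X.shape[1], rng)
        trainables = self._trainables(params)
        opt = Adam(trainables, lr=self.learning_rate,
                   weight_decay=self.weight_decay)
        drop_rng = np.random.default_rng(self.random_state + 1) \
            if self.dropout > 0 else None
        n = len(X)
        batch = self.batch_size or n
        history = []
        for _ in range(self.epochs):
            order = rng.permutation(n) if batch < n else np.arange(n)
            epoch_loss = 0.0
            for lo in range(0, n, batch):
                idx = order[lo:lo + batch]
                opt.zero_grad()
                y_hat, _ = self._forward(Tensor(X[idx]), params, drop_rng)
                loss = _bce_tensor(Y[idx], y_hat)
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
            if not np.isfinite(epoch_loss):
                raise ValidationError("non-finite training loss")
            history.append(epoch_loss)
        self.params_ = params
        self.loss_history_ = history
        self.n_features_in_ = X.shape[1]
        self.n_params_ = self._count_params(params)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        y_hat, _ = self._forward(Tensor(X), self.params_)
        return y_hat.data

    def predict(self, X: np.ndarray) -> np.ndarray:
        return binarize_predictions(self.predict_proba(X), self.threshold)

    def attention_map(self, X: np.ndarray) -> np.ndarray:
        """Per-sample block-by-block attention matrices (n x B x B)."""
        if not self.use_attention:
            raise ValidationError("model was built without the attention stage")
        _, attn = self._forward(Tensor(np.asarray(X, dtype=float)), self.params_)
        return attn.data


def _col_slice(X: Tensor, lo: int, hi: int) -> Tensor:
    """Column-range view with gradient scatter on backward."""
    a = X

    def backward(g):
        if a.requires_grad:
            acc = np.zeros_like(a.data)
            acc[:, lo:hi] = g
            a._accumulate(acc)

    return Tensor._make(a.data[:, lo:hi], (a,), backward)


def self_attention(
    X: np.ndarray,
    block_dims: tuple[int, ...],
    attention_dim: int = 64,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Standalone token self-attention over feature blocks.

    Returns (transformed features, attention matrices).  Used by tests and
    exploratory analysis; the classifier embeds the same computation.
    """
    if sum(block_dims) != X.shape[1]:
        raise ValidationError("block layout does not match feature width")
    clf = LocalizationClassifier(
        block_dims=tuple(block_dims), attention_dim=attention_dim,
        random_state=seed,
    )
    rng = np.random.default_rng(seed)
    params = clf._init(X.shape[1], rng)
    flat, attn = clf._attend(Tensor(np.asarray(X, dtype=float)), params)
    return flat.data, attn.data


def train(
    X: np.ndarray,
    Y: np.ndarray,
    params: ClassifierParams | None = None,
    block_dims: tuple[int, ...] | None = None,
    seed: int = 0,
) -> LocalizationClassifier:
    """Thin functional wrapper over :class:`LocalizationClassifier`."""
    clf = LocalizationClassifier.from_params(
        params or ClassifierParams(), block_dims=block_dims, random_state=seed
    )
    return clf.fit(X, Y)
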