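"""1D convolutional decoder for multichannel trial segments.

Architecture (fixed):
``[conv1d(32, k=5) → ReLU → norm] → [conv1d(64, k=5) → ReLU → norm] →
global average pool over time → flatten → fully connected (2) → softmax``.

The global average pooling head makes the network input-length-agnostic, so
ragged trials are processed at native length with no padding convention.
Training minimizes weighted two-class cross-entropy with the Adam optimizer;
everything — initialization, batch order, updates — is driven by one seed,
so runs are bit-reproducible.

The whole network is implemented in numpy: convolutions are im2col matrix
products (BLAS), normalization is batch norm over the channel dimension
(running statistics for inference; layer norm available), and the backward
pass is hand-written.  Within a minibatch, trial feature maps are
concatenated along time, which makes one conv a single matrix multiply and
lets batch-norm statistics pool over all time points of the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .epoching import EpochSet

__all__ = ["CnnConfig", "SpeechCNN", "build_cnn", "train_cnn", "grid_search_cnn"]

_DTYPE = np.float32
_EPS = 1e-5

#: default learning-rate grid, spanning the 0.003-0.006 tuning range
DEFAULT_LR_GRID = (0.003, 0.0045, 0.006)


@dataclass
class CnnConfig:
    """Hyperparameters of the CNN decoder.

    The learning-rate grid default spans 0.003–0.006, the range within which
    per-participant rates were tuned; ``max_epochs`` caps training at 100.
    """

    block_filters: tuple[int, int] = (32, 64)
    kernel_size: int = 5
    norm_kind: str = "batch"            # or "layer"
    learning_rate: float = 0.003
    max_epochs: int = 100
    batch_size: int = 16
    seed: int = 0
    early_stop_patience: int | None = None

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.block_filters):
            raise ValueError("filter counts must be positive")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel size must be odd and positive")
        if not 0 < self.learning_rate < 1:
            raise ValueError("learning rate must lie in (0, 1)")
        if self.norm_kind not in ("batch", "layer"):
            raise ValueError("norm_kind must be 'batch' or 'layer'")

    def to_dict(self) -> dict:
        return asdict(self)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, T) -> (C*k, T-k+1) column matrix of sliding windows."""
    C, T = x.shape
    sw = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (C, T-k+1, k)
    return np.ascontiguousarray(sw.transpose(0, 2, 1)).reshape(C * k, T - k + 1)


def _col2im(dcols: np.ndarray, C: int, k: int, T: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter window gradients back to (C, T)."""
    d = dcols.reshape(C, k, T - k + 1)
    out = np.zeros((C, T), dtype=dcols.dtype)
    for j in range(k):
        out[:, j:j + T - k + 1] += d[:, j, :]
    return out


def _segments(lengths: Sequence[int]) -> list[tuple[int, int]]:
    edges = np.concatenate([[0], np.cumsum(lengths)])
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


class _Norm:
    """Batch norm over the feature (row) axis, statistics pooled over all
    time points of the minibatch; or layer norm per time point."""

    def __init__(self, n_features: int, kind: str):
        self.kind = kind
        self.gamma = np.ones(n_features, dtype=_DTYPE)
        self.beta = np.zeros(n_features, dtype=_DTYPE)
        self.running_mean = np.zeros(n_features, dtype=_DTYPE)
        self.running_var = np.ones(n_features, dtype=_DTYPE)
        self.momentum = 0.1

    def forward(self, x: np.ndarray, train: bool):
        if self.kind == "batch":
            if train:
                mu = x.mean(axis=1)
                var = x.var(axis=1)
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mu).astype(_DTYPE)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var).astype(_DTYPE)
            else:
                mu, var = self.running_mean, self.running_var
            xhat = (x - mu[:, None]) / np.sqrt(var[:, None] + _EPS)
            cache = (xhat, var)
            return self.gamma[:, None] * xhat + self.beta[:, None], cache
        # layer norm: normalize each column over features
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        xhat = (x - mu) / np.sqrt(var + _EPS)
        return self.gamma[:, None] * xhat + self.beta[:, None], (xhat, var)

    def backward(self, dy: np.ndarray, cache):
        xhat, var = cache
        self.dgamma = (dy * xhat).sum(axis=1).astype(_DTYPE)
        self.dbeta = dy.sum(axis=1).astype(_DTYPE)
        if self.kind == "batch":
            m = xhat.shape[1]
            dxhat = dy * self.gamma[:, None]
            dx = (dxhat - dxhat.mean(axis=1, keepdims=True)
                  - xhat * (dxhat * xhat).mean(axis=1, keepdims=True))
            return dx / np.sqrt(var[:, None] + _EPS)
        m = xhat.shape[0]
        dxhat = dy * self.gamma[:, None]
        dx = (dxhat - dxhat.mean(axis=0, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=0, keepdims=True))
        return dx / np.sqrt(var + _EPS)

    def params(self):
        return [("gamma", self.gamma, "dgamma"), ("beta", self.beta, "dbeta")]

    @property
    def n_params(self) -> int:
        return 2 * len(self.gamma)


class SpeechCNN(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style two-class CNN over ragged (channels × time) trials.

    ``fit(X, y, sample_weight=None, validation=None)`` accepts a list of 2-D
    arrays (or a 3-D array) plus optional per-trial loss weights; when a
    ``(X_val, y_val)`` tuple is given, the weights with the best validation
    accuracy are retained, otherwise the final-epoch weights are kept.
    """

    def __init__(self, block_filters=(32, 64), kernel_size=5, norm_kind="batch",
                 learning_rate=0.003, max_epochs=100, batch_size=16, seed=0,
                 early_stop_patience=None):
        self.block_filters = block_filters
        self.kernel_size = kernel_size
        self.norm_kind = norm_kind
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.seed = seed
        self.early_stop_patience = early_stop_patience

    # -- construction ------------------------------------------------------

    def _init_weights(self, n_channels: int) -> None:
        cfg = CnnConfig(tuple(self.block_filters), self.kernel_size, self.norm_kind,
                        self.learning_rate, self.max_epochs, self.batch_size,
                        self.seed, self.early_stop_patience)
        rng = np.random.default_rng(np.random.SeedSequence(self.seed).spawn(1)[0])
        f1, f2 = cfg.block_filters
        k = cfg.kernel_size
        self.n_channels_ = n_channels
        self.W1_ = (rng.standard_normal((f1, n_channels * k))
                    * np.sqrt(2.0 / (n_channels * k))).astype(_DTYPE)
        self.b1_ = np.zeros(f1, dtype=_DTYPE)
        self.norm1_ = _Norm(f1, cfg.norm_kind)
        self.W2_ = (rng.standard_normal((f2, f1 * k))
                    * np.sqrt(2.0 / (f1 * k))).astype(_DTYPE)
        self.b2_ = np.zeros(f2, dtype=_DTYPE)
        self.norm2_ = _Norm(f2, cfg.norm_kind)
        self.Wfc_ = (rng.standard_normal((2, f2)) * np.sqrt(1.0 / f2)).astype(_DTYPE)
        self.bfc_ = np.zeros(2, dtype=_DTYPE)
        self._rng = rng
        self._cfg = cfg

    def n_parameters(self) -> int:
        return int(self.W1_.size + self.b1_.size + self.norm1_.n_params
                   + self.W2_.size + self.b2_.size + self.norm2_.n_params
                   + self.Wfc_.size + self.bfc_.size)

    # -- forward / backward ------------------------------------------------

    def _forward(self, trials: list[np.ndarray], train: bool):
        k = self.kernel_size
        min_T = 2 * (k - 1) + 1
        for t in trials:
            if t.shape[1] < min_T:
                raise ValueError(
                    f"trial length {t.shape[1]} below the minimal receptive span {min_T}"
                )
        cols1 = [_im2col(np.asarray(t, dtype=_DTYPE), k) for t in trials]
        L1 = [c.shape[1] for c in cols1]
        C1 = np.concatenate(cols1, axis=1)
        A1 = self.W1_ @ C1 + self.b1_[:, None]
        R1 = np.maximum(A1, 0)
        Z1, cache1 = self.norm1_.forward(R1, train)

        seg1 = _segments(L1)
        cols2 = [_im2col(np.ascontiguousarray(Z1[:, a:b]), k) for a, b in seg1]
        L2 = [c.shape[1] for c in cols2]
        C2 = np.concatenate(cols2, axis=1)
        A2 = self.W2_ @ C2 + self.b2_[:, None]
        R2 = np.maximum(A2, 0)
        Z2, cache2 = self.norm2_.forward(R2, train)

        seg2 = _segments(L2)
        G = np.stack([Z2[:, a:b].mean(axis=1) for a, b in seg2])  # (B, f2)
        logits = G @ self.Wfc_.T + self.bfc_
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        cache = (C1, A1, cache1, Z1, L1, C2, A2, cache2, Z2, L2, G)
        return probs, cache

    def _backward(self, probs, y_idx, w, cache):
        C1, A1, cache1, Z1, L1, C2, A2, cache2, Z2, L2, G = cache
        B = len(y_idx)
        f1, f2 = self.block_filters
        k = self.kernel_size

        # weights are globally normalized to mean 1, so dividing by the
        # batch size keeps the gradient scale consistent across batches
        dlogits = probs.copy()
        dlogits[np.arange(B), y_idx] -= 1.0
        dlogits *= (w / B)[:, None]
        self.dWfc_ = (dlogits.T @ G).astype(_DTYPE)
        self.dbfc_ = dlogits.sum(axis=0).astype(_DTYPE)
        dG = dlogits @ self.Wfc_

        dZ2 = np.repeat(dG / np.array(L2)[:, None], L2, axis=0).T.astype(_DTYPE)
        dR2 = self.norm2_.backward(dZ2, cache2)
        dA2 = dR2 * (A2 > 0)
        self.dW2_ = (dA2 @ C2.T).astype(_DTYPE)
        self.db2_ = dA2.sum(axis=1).astype(_DTYPE)
        dC2 = self.W2_.T @ dA2

        dZ1 = np.zeros_like(Z1)
        for (a1, b1), (a2, b2) in zip(_segments(L1), _segments(L2)):
            dZ1[:, a1:b1] = _col2im(dC2[:, a2:b2], f1, k, b1 - a1)
        dR1 = self.norm1_.backward(dZ1, cache1)
        dA1 = dR1 * (A1 > 0)
        self.dW1_ = (dA1 @ C1.T).astype(_DTYPE)
        self.db1_ = dA1.sum(axis=1).astype(_DTYPE)

    def _params(self):
        yield self, "W1_", "dW1_"
        yield self, "b1_", "db1_"
        yield self.norm1_, "gamma", "dgamma"
        yield self.norm1_, "beta", "dbeta"
        yield self, "W2_", "dW2_"
        yield self, "b2_", "db2_"
        yield self.norm2_, "gamma", "dgamma"
        yield self.norm2_, "beta", "dbeta"
        yield self, "Wfc_", "dWfc_"
        yield self, "bfc_", "dbfc_"

    def _snapshot(self):
        return [getattr(o, name).copy() for o, name, _ in self._params()] + [
            self.norm1_.running_mean.copy(), self.norm1_.running_var.copy(),
            self.norm2_.running_mean.copy(), self.norm2_.running_var.copy()]

    def _restore(self, snap):
        for (o, name, _), val in zip(self._params(), snap):
            setattr(o, name, val.copy())
        (self.norm1_.running_mean, self.norm1_.running_var,
         self.norm2_.running_mean, self.norm2_.running_var) = (v.copy() for v in snap[-4:])

    # -- training ----------------------------------------------------------

    @staticmethod
    def _as_trials(X) -> list[np.ndarray]:
        if isinstance(X, EpochSet):
            return X.trials
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return [X[i] for i in range(X.shape[0])]
        return list(X)

    def fit(self, X, y, sample_weight=None, validation=None):
        trials = self._as_trials(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("SpeechCNN is a two-class decoder; both classes must be present")
        y_idx = np.searchsorted(self.classes_, y)
        n = len(trials)
        w = (np.ones(n) if sample_weight is None
             else np.asarray(sample_weight, dtype=np.float64))
        w = w * n / w.sum()

        self._init_weights(trials[0].shape[0])
        lr = float(self.learning_rate)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        m_state = [np.zeros_like(getattr(o, name)) for o, name, _ in self._params()]
        v_state = [np.zeros_like(getattr(o, name)) for o, name, _ in self._params()]
        step = 0

        history = {"loss": [], "val_accuracy": []}
        best_val, best_snap, since_best = -np.inf, None, 0
        order = np.arange(n)
        for epoch in range(self.max_epochs):
            self._rng.shuffle(order)
            total_loss, total_w = 0.0, 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                batch = [trials[i] for i in idx]
                probs, cache = self._forward(batch, train=True)
                p_true = probs[np.arange(len(idx)), y_idx[idx]]
                loss = -(w[idx] * np.log(np.maximum(p_true, 1e-12))).sum() / w[idx].sum()
                if not np.isfinite(loss):
                    raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
                total_loss += loss * w[idx].sum()
                total_w += w[idx].sum()
                self._backward(probs, y_idx[idx], w[idx], cache)
                step += 1
                for j, (o, name, gname) in enumerate(self._params()):
                    g = getattr(o, gname)
                    m_state[j] = beta1 * m_state[j] + (1 - beta1) * g
                    v_state[j] = beta2 * v_state[j] + (1 - beta2) * g * g
                    mh = m_state[j] / (1 - beta1 ** step)
                    vh = v_state[j] / (1 - beta2 ** step)
                    setattr(o, name, (getattr(o, name)
                                      - lr * mh / (np.sqrt(vh) + eps)).astype(_DTYPE))
            history["loss"].append(total_loss / total_w)

            if validation is not None:
                Xv, yv = validation
                acc = float(np.mean(self.predict(Xv) == np.asarray(yv)))
                history["val_accuracy"].append(acc)
                if acc > best_val:
                    best_val, best_snap, since_best = acc, self._snapshot(), 0
                else:
                    since_best += 1
                    if (self.early_stop_patience is not None
                            and since_best >= self.early_stop_patience):
                        break
        if best_snap is not None:
            self._restore(best_snap)
        self.history_ = history
        return self

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X):
        trials = self._as_trials(X)
        out = np.empty((len(trials), 2))
        for start in range(0, len(trials), 256):
            chunk = trials[start:start + 256]
            probs, _ = self._forward(chunk, train=False)
            out[start:start + len(chunk)] = probs
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def build_cnn(config: CnnConfig, n_channels: int) -> SpeechCNN:
    """Construct (and initialize) an untrained network for ``n_channels``
    input channels; weights are deterministic given ``config.seed``."""
    model = SpeechCNN(**config.to_dict())
    model._init_weights(n_channels)
    model.classes_ = np.array(["no", "yes"])
    return model


def train_cnn(model: SpeechCNN, train: EpochSet, val: EpochSet | None,
              config: CnnConfig | None = None) -> SpeechCNN:
    """Train on one EpochSet; if ``val`` is given the best-validation-accuracy
    weights are retained."""
    if config is not None:
        model.set_params(**config.to_dict())
    validation = (val.trials, val.labels) if val is not None else None
    model.fit(train.trials, train.labels, validation=validation)
    return model


def grid_search_cnn(train: EpochSet, grid: dict[str, list] | None, cv_spec,
                    base_config: CnnConfig | None = None):
    """Score every grid point with the Bayesian-bootstrap CV protocol; the
    best mean CV accuracy wins, ties broken toward the smaller learning rate.

    ``grid=None`` searches the shipped learning-rate grid
    (:data:`DEFAULT_LR_GRID`).  Returns ``(best_config, table)`` where table
    is a list of dicts with the grid point and its mean/sd CV accuracy.
    """
    from itertools import product

    from .evaluate import bayesian_bootstrap_cv

    if grid is None:
        grid = {"learning_rate": list(DEFAULT_LR_GRID)}
    base = base_config or CnnConfig()
    keys = sorted(grid)
    if any(len(grid[k]) == 0 for k in keys) or not keys:
        raise ValueError("grid must be non-empty")
    combos = [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))]
    table = []
    for combo in combos:
        params = {**base.to_dict(), **combo}
        cfg = CnnConfig(**{**params, "block_filters": tuple(params["block_filters"])})
        accs = bayesian_bootstrap_cv(
            train, k=cv_spec.k_folds, n_bootstrap=cv_spec.n_bootstrap,
            decoder_factory=lambda: SpeechCNN(**cfg.to_dict()),
            seed=cv_spec.seed,
        )
        table.append({**combo, "cv_mean": float(np.nanmean(accs)),
                      "cv_sd": float(np.nanstd(accs))})
    order = sorted(
        range(len(combos)),
        key=lambda i: (-table[i]["cv_mean"], combos[i].get("learning_rate", 0.0)),
    )
    best = order[0]
    best_cfg = CnnConfig(**{**base.to_dict(), **combos[best]})
    return best_cfg, table
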