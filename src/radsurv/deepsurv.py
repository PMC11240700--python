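"""Feed-forward Cox partial-likelihood network ("Deepsurv"), in numpy.

The network maps a covariate vector to a scalar log-risk score and is trained
by minimizing the negative log Cox partial likelihood computed within each
mini-batch (risk sets restricted to the batch; Breslow handling of ties):

    loss(batch) = - sum_{i in batch, event_i} [ s_i - log sum_{j: t_j >= t_i} exp(s_j) ]

Architecture and optimization follow the printed configuration: up to a few
fully connected hidden layers with batch normalization (momentum 0.85) and
dropout, ReLU or SELU activations, adam or momentum-SGD, learning rate 0.01
with inverse-time decay 0.001, 512 epochs with early stopping (10% validation
split, patience 16), batch size 32, dropout 0.1.  The printed regularization
constant (15) is treated as an L2 coefficient normalized by the training-set
size, i.e. the penalty added to the per-observation loss is
``l2_reg / n_train * sum(W**2)``; with 0 hidden layers, no dropout and zero
regularization the model reduces to a linear Cox model and full-batch
training recovers the Cox maximum partial-likelihood estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DeepsurvConfig", "DeepSurvNetwork", "cox_ph_loss", "cox_ph_loss_grad"]

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def _cox_parts(scores: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Sorted arrays and per-subject risk-set denominators (Breslow ties)."""
    scores = np.asarray(scores, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel().astype(bool)
    order = np.argsort(time, kind="stable")
    s, t, e = scores[order], time[order], event[order]
    m = s.max()
    exp_s = np.exp(s - m)
    rev = np.cumsum(exp_s[::-1])[::-1]  # rev[k] = sum_{j >= k} exp(s_j)
    first = np.searchsorted(t, t, side="left")  # first index of each tie group
    denom = rev[first]
    return order, s, t, e, exp_s, rev, first, denom, m


def cox_ph_loss(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Negative log Cox partial likelihood (sum over events, Breslow ties).

    With a single event among ``n`` subjects of equal score the loss is
    ``log n``.  Equals the full-cohort partial likelihood when evaluated on
    the whole sample.
    """
    _, s, _, e, _, _, _, denom, m = _cox_parts(scores, time, event)
    if not e.any():
        raise ValueError("no events in batch")
    return float(-(s[e] - (np.log(denom[e]) + m)).sum())


def cox_ph_loss_grad(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray
) -> np.ndarray:
    """Gradient of :func:`cox_ph_loss` with respect to the scores."""
    order, s, t, e, exp_s, rev, first, denom, _ = _cox_parts(scores, time, event)
    n = s.size
    w = np.zeros(n)
    np.add.at(w, first[e], 1.0 / denom[e])
    a = np.cumsum(w)  # a[k] = sum over events i with first_i <= k of 1/denom_i
    grad_sorted = -e.astype(float) + exp_s * a
    grad = np.empty(n)
    grad[order] = grad_sorted
    return grad


@dataclass
class DeepsurvConfig:
    hidden_layers: int = 1
    hidden_nodes: int = 15
    activation: str = "relu"  # relu | selu
    optimizer: str = "adam"  # adam | sgd
    epochs: int = 512
    batch_size: int = 32
    batch_norm: bool = True
    momentum: float = 0.85  # SGD and batch-norm running-stat momentum
    learning_rate: float = 0.01
    lr_decay: float = 0.001  # inverse-time: lr_t = lr0 / (1 + decay * epoch)
    l2_reg: float = 15.0  # cohort-size-normalized L2 coefficient
    dropout: float = 0.1
    early_stopping: bool = True
    val_fraction: float = 0.1
    patience: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0 or self.lr_decay < 0:
            raise ValueError("rates must be positive")
        if self.activation not in ("relu", "selu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    return _SELU_LAMBDA * np.where(z > 0, z, _SELU_ALPHA * (np.exp(np.minimum(z, 0.0)) - 1.0))


def _act_grad(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(float)
    return _SELU_LAMBDA * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(z, 0.0)))


class DeepSurvNetwork:
    """MLP log-risk predictor trained with the batched Cox loss."""

    def __init__(self, config: DeepsurvConfig | None = None):
        self.config = config or DeepsurvConfig()
        self._fitted = False

    # -- parameter handling ------------------------------------------------
    def _init_params(self, n_in: int) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        dims = [n_in] + [cfg.hidden_nodes] * cfg.hidden_layers + [1]
        self.W, self.b = [], []
        for i in range(len(dims) - 1):
            fan_in = dims[i]
            if cfg.activation == "relu":
                sd = np.sqrt(2.0 / fan_in)
            else:  # lecun normal, the SELU-appropriate init
                sd = np.sqrt(1.0 / fan_in)
            self.W.append(rng.normal(0.0, sd, size=(dims[i], dims[i + 1])))
            self.b.append(np.zeros(dims[i + 1]))
        nh = cfg.hidden_layers
        self.bn_gamma = [np.ones(cfg.hidden_nodes) for _ in range(nh)]
        self.bn_beta = [np.zeros(cfg.hidden_nodes) for _ in range(nh)]
        self.bn_mean = [np.zeros(cfg.hidden_nodes) for _ in range(nh)]
        self.bn_var = [np.ones(cfg.hidden_nodes) for _ in range(nh)]
        self._rng = rng

    def _params(self) -> list[np.ndarray]:
        return self.W + self.b + self.bn_gamma + self.bn_beta

    def _snapshot(self):
        return [p.copy() for p in self._params()] + [
            m.copy() for m in self.bn_mean
        ] + [v.copy() for v in self.bn_var]

    def _restore(self, snap) -> None:
        ps = self._params()
        for p, s in zip(ps, snap[: len(ps)]):
            p[...] = s
        rest = snap[len(ps):]
        nh = len(self.bn_mean)
        for m, s in zip(self.bn_mean, rest[:nh]):
            m[...] = s
        for v, s in zip(self.bn_var, rest[nh:]):
            v[...] = s

    # -- forward / backward ------------------------------------------------
    def _forward(self, X: np.ndarray, training: bool):
        cfg = self.config
        cache = {"h": [X], "z": [], "xhat": [], "bnstats": [], "drop": []}
        h = X
        eps = 1e-5
        for layer in range(cfg.hidden_layers):
            z = h @ self.W[layer] + self.b[layer]
            cache["z"].append(z)
            if cfg.batch_norm:
                if training:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    self.bn_mean[layer] = (
                        cfg.momentum * self.bn_mean[layer] + (1 - cfg.momentum) * mu
                    )
                    self.bn_var[layer] = (
                        cfg.momentum * self.bn_var[layer] + (1 - cfg.momentum) * var
                    )
                else:
                    mu = self.bn_mean[layer]
                    var = self.bn_var[layer]
                xhat = (z - mu) / np.sqrt(var + eps)
                zbn = self.bn_gamma[layer] * xhat + self.bn_beta[layer]
                cache["xhat"].append(xhat)
                cache["bnstats"].append((mu, var, eps))
            else:
                zbn = z
                cache["xhat"].append(None)
                cache["bnstats"].append(None)
            a = _act(zbn, cfg.activation)
            cache.setdefault("zbn", []).append(zbn)
            if training and cfg.dropout > 0:
                keep = 1.0 - cfg.dropout
                mask = (self._rng.random(a.shape) < keep) / keep
                a = a * mask
                cache["drop"].append(mask)
            else:
                cache["drop"].append(None)
            cache["h"].append(a)
            h = a
        s = (h @ self.W[-1] + self.b[-1]).ravel()
        return s, cache

    def _backward(self, ds: np.ndarray, cache) -> tuple[list, list, list, list]:
        cfg = self.config
        nh = cfg.hidden_layers
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        dgamma = [None] * nh
        dbeta = [None] * nh
        h_last = cache["h"][-1]
        ds2 = ds[:, None]
        dW[-1] = h_last.T @ ds2
        db[-1] = ds2.sum(axis=0)
        dh = ds2 @ self.W[-1].T
        for layer in range(nh - 1, -1, -1):
            if cache["drop"][layer] is not None:
                dh = dh * cache["drop"][layer]
            zbn = cache["zbn"][layer]
            dzbn = dh * _act_grad(zbn, cfg.activation)
            if cfg.batch_norm:
                xhat = cache["xhat"][layer]
                mu, var, eps = cache["bnstats"][layer]
                m = dzbn.shape[0]
                dgamma[layer] = (dzbn * xhat).sum(axis=0)
                dbeta[layer] = dzbn.sum(axis=0)
                dxhat = dzbn * self.bn_gamma[layer]
                inv = 1.0 / np.sqrt(var + eps)
                dz = (
                    inv
                    / m
                    * (
                        m * dxhat
                        - dxhat.sum(axis=0)
                        - xhat * (dxhat * xhat).sum(axis=0)
                    )
                )
            else:
                dgamma[layer] = np.zeros_like(self.bn_gamma[layer])
                dbeta[layer] = np.zeros_like(self.bn_beta[layer])
                dz = dzbn
            h_prev = cache["h"][layer]
            dW[layer] = h_prev.T @ dz
            db[layer] = dz.sum(axis=0)
            dh = dz @ self.W[layer].T
        return dW, db, dgamma, dbeta

    # -- training ----------------------------------------------------------
    def fit(
        self, X: np.ndarray, time: np.ndarray, event: np.ndarray
    ) -> "DeepSurvNetwork":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event).astype(int)
        n, p = X.shape
        self._init_params(p)
        rng = self._rng

        if cfg.early_stopping and cfg.val_fraction > 0 and n >= 20:
            n_val = max(int(round(cfg.val_fraction * n)), 2)
            perm = rng.permutation(n)
            # ensure the validation split contains at least one event
            for _ in range(20):
                val_idx, tr_idx = perm[:n_val], perm[n_val:]
                if event[val_idx].sum() >= 1 and event[tr_idx].sum() >= 1:
                    break
                perm = rng.permutation(n)
        else:
            tr_idx = np.arange(n)
            val_idx = None
        Xtr, ttr, etr = X[tr_idx], time[tr_idx], event[tr_idx]
        n_tr = len(tr_idx)
        l2 = cfg.l2_reg / max(n_tr, 1)

        params = self._params()
        if cfg.optimizer == "adam":
            mbuf = [np.zeros_like(p_) for p_ in params]
            vbuf = [np.zeros_like(p_) for p_ in params]
            t_step = 0
        else:
            vel = [np.zeros_like(p_) for p_ in params]

        best_val = np.inf
        best_snap = None
        stall = 0
        bs = min(cfg.batch_size, n_tr)

        for epoch in range(cfg.epochs):
            lr = cfg.learning_rate / (1.0 + cfg.lr_decay * epoch)
            order = rng.permutation(n_tr)
            for start in range(0, n_tr, bs):
                idx = order[start : start + bs]
                if len(idx) < 2 or etr[idx].sum() == 0:
                    continue  # zero-event batch carries no partial-likelihood signal
                Xb, tb, eb = Xtr[idx], ttr[idx], etr[idx]
                s, cache = self._forward(Xb, training=True)
                ds = cox_ph_loss_grad(s, tb, eb) / len(idx)
                dW, db, dgamma, dbeta = self._backward(ds, cache)
                grads = dW + db + dgamma + dbeta
                # L2 penalty on weight matrices only
                for k in range(len(self.W)):
                    grads[k] = grads[k] + 2.0 * l2 * self.W[k]
                if cfg.optimizer == "adam":
                    t_step += 1
                    b1, b2, eps = 0.9, 0.999, 1e-8
                    for p_, g, m_, v_ in zip(params, grads, mbuf, vbuf):
                        m_[...] = b1 * m_ + (1 - b1) * g
                        v_[...] = b2 * v_ + (1 - b2) * g * g
                        mhat = m_ / (1 - b1**t_step)
                        vhat = v_ / (1 - b2**t_step)
                        p_ -= lr * mhat / (np.sqrt(vhat) + eps)
                else:
                    for p_, g, v_ in zip(params, grads, vel):
                        v_[...] = cfg.momentum * v_ - lr * g
                        p_ += v_
                if any(not np.isfinite(p_).all() for p_ in params):
                    raise RuntimeError(
                        f"NaN/inf parameters at epoch {epoch}; "
                        f"lr={lr:.4g}, batch events={int(eb.sum())}"
                    )
            if val_idx is not None:
                sv, _ = self._forward(X[val_idx], training=False)
                if event[val_idx].sum() > 0:
                    val_loss = cox_ph_loss(sv, time[val_idx], event[val_idx]) / len(val_idx)
                else:  # pragma: no cover - guarded at split time
                    val_loss = np.inf
                if val_loss < best_val - 1e-9:
                    best_val = val_loss
                    best_snap = self._snapshot()
                    stall = 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        break
        if val_idx is not None and best_snap is not None:
            self._restore(best_snap)
        self._fitted = True
        return self

    def predict_risk(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("network is not fitted")
        s, _ = self._forward(np.asarray(X, dtype=float), training=False)
        return s

    @property
    def linear_weights(self) -> np.ndarray:
        """Weights of the output layer (the coefficients when 0 hidden layers)."""
        return self.W[-1].ravel().copy()
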