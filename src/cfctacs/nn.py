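"""Compact convolutional EEG decoder with hand-written backpropagation.

The architecture follows the EEGNet-8,2 design adapted to two-period
(pre/post stimulation) inputs:

1. a temporal convolution of ``F1`` kernels applied along time on every
   channel — a learnable band-pass filter bank;
2. a depthwise spatial convolution: ``D`` spatial kernels per temporal
   filter, each spanning all ``C`` channels, under a max-norm constraint;
3. batch normalisation, ELU, average pooling, dropout;
4. a separable temporal convolution (depthwise temporal kernels followed by
   a pointwise mix to ``F2`` maps), again with BN/ELU/pooling/dropout;
5. a dense softmax head over ``N`` classes with a max-norm constraint.

Two-period handling (``combine_mode``):

* ``concat_time`` — pre and post segments are concatenated along time, so a
  single shared filter bank convolves both periods (T = 128 at the default
  64 samples per period);
* ``feature_diff`` — the shared trunk is applied to each 64-sample period
  separately and the classifier sees the post-minus-pre feature difference;
* ``pre`` / ``post`` — single-period decoding (T = 64).

Everything is float32 numpy.  Optimisation is Adam on the cross-entropy of
the softmax output (binary cross-entropy for N = 2), with He-initialised
weights and max-norm reprojection after every update, matching the reference
training recipe (alpha = 1e-3, beta1 = 0.9, beta2 = 0.999, batch 16).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32

__all__ = ["EEGNetDecoder", "Parameter"]


class Parameter:
    """A trainable array with gradient, Adam state and optional max-norm."""

    __slots__ = ("value", "grad", "m", "v", "maxnorm", "maxnorm_axis", "name")

    def __init__(self, value, name="", maxnorm=None, maxnorm_axis=None):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)
        self.maxnorm = maxnorm
        self.maxnorm_axis = maxnorm_axis
        self.name = name

    def zero_grad(self):
        self.grad[...] = 0.0

    def apply_maxnorm(self):
        if self.maxnorm is None:
            return
        norms = np.sqrt(
            (self.value**2).sum(axis=self.maxnorm_axis, keepdims=True)
        )
        scale = np.minimum(1.0, self.maxnorm / np.maximum(norms, 1e-12))
        self.value *= scale


def _he(rng, shape, fan_in):
    return rng.standard_normal(shape).astype(DTYPE) * np.sqrt(2.0 / fan_in)


def _pad_lr(L):
    return (L - 1) // 2, L // 2


def _twin(x, L, pad):
    """Sliding time windows along the last axis after zero padding."""
    pads = [(0, 0)] * (x.ndim - 1) + [pad]
    xp = np.pad(x, pads)
    return sliding_window_view(xp, L, axis=-1)


class TemporalFilterBank:
    """F temporal kernels, 'same' padding, shared across channels.

    Input (B, C, T) -> output (B, F, C, T).
    """

    def __init__(self, n_filters, length, rng, is_first=False):
        self.L = length
        self.is_first = is_first  # the input gradient is skipped if True
        self.w = Parameter(_he(rng, (n_filters, length), length), "temporal_w")

    def forward(self, x, training):
        B, C, T = x.shape
        F, L = self.w.value.shape
        pl, pr = _pad_lr(L)
        win = _twin(x, L, (pl, pr))  # (B, C, T, L)
        self._win = win if training else None
        self._shape = (B, C, T)
        y = win.reshape(-1, L) @ self.w.value.T  # (B*C*T, F)
        return np.ascontiguousarray(
            y.reshape(B, C, T, F).transpose(0, 3, 1, 2)
        )

    def backward(self, g):
        B, F, C, T = g.shape
        L = self.L
        pl, _ = _pad_lr(L)
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, F)  # (B*C*T, F)
        self.w.grad += (g2.T @ self._win.reshape(-1, L)).astype(DTYPE)
        if self.is_first:
            return None
        wf = self.w.value[:, ::-1]
        gwin = _twin(g, L, (L - 1, L - 1))  # (B, F, C, T+L-1, L)
        dxp = np.einsum("bfcul,fl->bcu", gwin, wf, optimize=True)
        return np.ascontiguousarray(dxp[..., pl : pl + T])

    @property
    def params(self):
        return [self.w]


class DepthwiseSpatialConv:
    """D spatial kernels per temporal filter, each spanning all channels.

    Input (B, F, C, T) -> output (B, F*D, T).  Weights are max-norm
    constrained over the channel axis (bound 1.0, the reference design).
    """

    def __init__(self, n_temporal, depth, n_channels, rng, maxnorm=1.0):
        self.F, self.D, self.C = n_temporal, depth, n_channels
        self.w = Parameter(
            _he(rng, (n_temporal, depth, n_channels), n_channels),
            "spatial_w",
            maxnorm=maxnorm,
            maxnorm_axis=2,
        )

    def forward(self, x, training):
        self._x = x if training else None
        y = np.einsum("bfct,fdc->bfdt", x, self.w.value, optimize=True)
        B = x.shape[0]
        return y.reshape(B, self.F * self.D, -1)

    def backward(self, g):
        B, _, T = g.shape
        g4 = g.reshape(B, self.F, self.D, T)
        self.w.grad += np.einsum(
            "bfdt,bfct->fdc", g4, self._x, optimize=True
        ).astype(DTYPE)
        return np.einsum("bfdt,fdc->bfct", g4, self.w.value, optimize=True)

    @property
    def params(self):
        return [self.w]


class DepthwiseTemporalConv:
    """Per-map temporal kernels ('same' padding): input/output (B, K, T)."""

    def __init__(self, n_maps, length, rng):
        self.L = length
        self.w = Parameter(_he(rng, (n_maps, length), length), "sep_depth_w")

    def forward(self, x, training):
        L = self.L
        pl, pr = _pad_lr(L)
        win = _twin(x, L, (pl, pr))  # (B, K, T, L)
        self._win = win if training else None
        return np.einsum("bktl,kl->bkt", win, self.w.value, optimize=True)

    def backward(self, g):
        B, K, T = g.shape
        L = self.L
        pl, _ = _pad_lr(L)
        self.w.grad += np.einsum(
            "bkt,bktl->kl", g, self._win, optimize=True
        ).astype(DTYPE)
        wf = self.w.value[:, ::-1]
        gwin = _twin(g, L, (L - 1, L - 1))
        dxp = np.einsum("bkul,kl->bku", gwin, wf, optimize=True)
        return np.ascontiguousarray(dxp[..., pl : pl + T])

    @property
    def params(self):
        return [self.w]


class PointwiseConv:
    """1x1 mixing across maps: (B, K, T) -> (B, F2, T)."""

    def __init__(self, n_in, n_out, rng):
        self.w = Parameter(_he(rng, (n_out, n_in), n_in), "sep_point_w")

    def forward(self, x, training):
        self._x = x if training else None
        return np.einsum("bkt,fk->bft", x, self.w.value, optimize=True)

    def backward(self, g):
        self.w.grad += np.einsum(
            "bft,bkt->fk", g, self._x, optimize=True
        ).astype(DTYPE)
        return np.einsum("bft,fk->bkt", g, self.w.value, optimize=True)

    @property
    def params(self):
        return [self.w]


class BatchNorm:
    """Batch normalisation over all axes except axis 1 (the feature maps)."""

    def __init__(self, k, momentum=0.1, eps=1e-5):
        self.gamma = Parameter(np.ones(k), "bn_gamma")
        self.beta = Parameter(np.zeros(k), "bn_beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(k, dtype=DTYPE)
        self.running_var = np.ones(k, dtype=DTYPE)

    def _bshape(self, ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, training):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x.ndim)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        if training:
            self._xhat, self._invstd, self._axes, self._shape = (
                xhat,
                invstd,
                axes,
                shape,
            )
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(
            shape
        )

    def backward(self, g):
        axes, shape = self._axes, self._shape
        xhat, invstd = self._xhat, self._invstd
        n = g.size // g.shape[1]
        self.gamma.grad += (g * xhat).sum(axis=axes).astype(DTYPE)
        self.beta.grad += g.sum(axis=axes).astype(DTYPE)
        dxhat = g * self.gamma.value.reshape(shape)
        mean_dxhat = dxhat.mean(axis=axes).reshape(shape)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes).reshape(shape)
        return invstd.reshape(shape) * (
            dxhat - mean_dxhat - xhat * mean_dxhat_xhat
        )

    @property
    def params(self):
        return [self.gamma, self.beta]


class ELU:
    def forward(self, x, training):
        y = np.where(x > 0, x, np.expm1(x))
        if training:
            self._x, self._y = x, y
        return y

    def backward(self, g):
        return g * np.where(self._x > 0, 1.0, self._y + 1.0)

    params: list = []


class AvgPool:
    """Non-overlapping average pooling along the last axis."""

    def __init__(self, size):
        self.size = size

    def forward(self, x, training):
        T = x.shape[-1]
        if T % self.size:
            raise ValueError(
                f"time axis {T} not divisible by pool size {self.size}"
            )
        self._T = T
        return x.reshape(x.shape[:-1] + (T // self.size, self.size)).mean(-1)

    def backward(self, g):
        rep = np.repeat(g, self.size, axis=-1)
        return rep / self.size

    params: list = []


class Dropout:
    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    params: list = []


class Dense:
    """Affine map with per-unit max-norm (bound 0.25, reference design)."""

    def __init__(self, n_in, n_out, rng, maxnorm=0.25):
        self.w = Parameter(
            _he(rng, (n_out, n_in), n_in), "dense_w",
            maxnorm=maxnorm, maxnorm_axis=1,
        )
        self.b = Parameter(np.zeros(n_out), "dense_b")

    def forward(self, x, training):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, g):
        self.w.grad += (g.T @ self._x).astype(DTYPE)
        self.b.grad += g.sum(axis=0).astype(DTYPE)
        return g @ self.w.value

    @property
    def params(self):
        return [self.w, self.b]


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _xent(proba, y):
    eps = 1e-12
    return float(-np.log(proba[np.arange(len(y)), y] + eps).mean())


class EEGNetDecoder:
    """The two-period EEG decoder.

    Parameters
    ----------
    config
        A :class:`cfctacs.models.ModelConfig` (any object with the same
        attributes works).
    seed
        Seeds weight initialisation and dropout.
    """

    def __init__(self, config, seed: int = 0):
        cfg = config
        self.config = cfg
        self.combine_mode = cfg.combine_mode
        self.trained = False
        T = cfg.trunk_T  # time points seen by the trunk
        min_t = cfg.pool1 * cfg.pool2
        if T < min_t or T % min_t:
            raise ValueError(
                f"T={T} incompatible with the pooling chain; T must be a "
                f"multiple of pool1*pool2={min_t} (minimum {min_t})"
            )
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(rng.integers(2**31))
        F1, D, F2, C = cfg.F1, cfg.D, cfg.F2, cfg.C
        self.conv1 = TemporalFilterBank(F1, cfg.kern_length, rng, is_first=True)
        self.bn1 = BatchNorm(F1)
        self.dws = DepthwiseSpatialConv(
            F1, D, C, rng, maxnorm=cfg.maxnorm_spatial
        )
        self.bn2 = BatchNorm(F1 * D)
        self.elu1 = ELU()
        self.pool1 = AvgPool(cfg.pool1)
        self.drop1 = Dropout(cfg.dropout, self._drop_rng)
        self.dwt = DepthwiseTemporalConv(F1 * D, cfg.sep_kern_length, rng)
        self.pw = PointwiseConv(F1 * D, F2, rng)
        self.bn3 = BatchNorm(F2)
        self.elu2 = ELU()
        self.pool2 = AvgPool(cfg.pool2)
        self.drop2 = Dropout(cfg.dropout, self._drop_rng)
        self.feature_dim = F2 * (T // (cfg.pool1 * cfg.pool2))
        self.dense = Dense(
            self.feature_dim, cfg.n_classes, rng, maxnorm=cfg.maxnorm_dense
        )
        self._trunk = [
            self.conv1, self.bn1, self.dws, self.bn2, self.elu1,
            self.pool1, self.drop1, self.dwt, self.pw, self.bn3,
            self.elu2, self.pool2, self.drop2,
        ]
        self._adam_t = 0

    # -- plumbing -----------------------------------------------------------

    @property
    def params(self) -> list[Parameter]:
        out = []
        for layer in self._trunk:
            out.extend(layer.params)
        out.extend(self.dense.params)
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    @property
    def temporal_kernels(self) -> np.ndarray:
        """Learned first-layer kernels, shape (F1, kern_length)."""
        return np.array(self.conv1.w.value, dtype=float)

    # -- forward / backward -------------------------------------------------

    def _trunk_forward(self, x, training):
        for layer in self._trunk:
            x = layer.forward(x, training)
        return x.reshape(x.shape[0], -1)

    def _trunk_backward(self, gfeat, shapes_hint):
        g = gfeat.reshape(shapes_hint)
        for layer in reversed(self._trunk):
            g = layer.backward(g)
        return g

    def forward(self, X, training=False):
        """Logits for an assembled input batch.

        ``X`` is (B, C, T) for single-period or concatenated inputs, and
        (B, 2, C, T) in ``feature_diff`` mode.
        """
        X = np.asarray(X, dtype=DTYPE)
        if self.combine_mode == "feature_diff":
            if X.ndim != 4 or X.shape[1] != 2:
                raise ValueError(
                    "feature_diff mode expects input (B, 2, C, T)"
                )
            B = X.shape[0]
            stacked = np.concatenate([X[:, 0], X[:, 1]], axis=0)
            feats = self._trunk_forward(stacked, training)
            f = feats[B:] - feats[:B]  # post minus pre
        else:
            if X.ndim != 3:
                raise ValueError("expected input (B, C, T)")
            if X.shape[1] != self.config.C or X.shape[2] != self.config.trunk_T:
                raise ValueError(
                    f"input shape {X.shape[1:]} does not match model "
                    f"(C={self.config.C}, T={self.config.trunk_T})"
                )
            f = self._trunk_forward(X, training)
        return self.dense.forward(f, training)

    def _backward_from_logits(self, glogits, batch):
        gfeat = self.dense.backward(glogits)
        F2 = self.config.F2
        tp = self.feature_dim // F2
        if self.combine_mode == "feature_diff":
            g_stacked = np.concatenate([-gfeat, gfeat], axis=0)
            self._trunk_backward(g_stacked, (2 * batch, F2, tp))
        else:
            self._trunk_backward(gfeat, (batch, F2, tp))

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities (inference mode; rows sum to one)."""
        return softmax(self.forward(X, training=False))

    def loss_and_grad(self, X, y):
        """Training-mode forward/backward; returns (loss, accuracy)."""
        y = np.asarray(y)
        logits = self.forward(X, training=True)
        proba = softmax(logits)
        loss = _xent(proba, y)
        B = len(y)
        glog = proba.copy()
        glog[np.arange(B), y] -= 1.0
        glog /= B
        self._backward_from_logits(glog.astype(DTYPE), B)
        acc = float((proba.argmax(1) == y).mean())
        return loss, acc

    # -- optimisation -------------------------------------------------------

    def adam_step(self, lr, beta1, beta2, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for p in self.params:
            p.m = beta1 * p.m + (1 - beta1) * p.grad
            p.v = beta2 * p.v + (1 - beta2) * p.grad**2
            mhat = p.m / (1 - beta1**t)
            vhat = p.v / (1 - beta2**t)
            p.value -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(DTYPE)
            p.apply_maxnorm()
            p.zero_grad()

    def _snapshot(self):
        state = [p.value.copy() for p in self.params]
        running = [
            (bn.running_mean.copy(), bn.running_var.copy())
            for bn in (self.bn1, self.bn2, self.bn3)
        ]
        return state, running

    def _restore(self, snap):
        state, running = snap
        for p, v in zip(self.params, state):
            p.value = v
        for bn, (m, v) in zip((self.bn1, self.bn2, self.bn3), running):
            bn.running_mean, bn.running_var = m, v

    def fit(self, X, y, X_val=None, y_val=None, train_config=None):
        """Mini-batch Adam training; returns the per-epoch history dict.

        When a validation set is given, the weights achieving the best
        validation accuracy (ties broken by lower validation loss) over the
        run are restored at the end — the "best in validation" model.
        ``history['best_epoch']`` records which epoch that was.

        Raises ``RuntimeError`` with diagnostics if the loss becomes NaN.
        """
        from .models import TrainConfig  # local import to avoid a cycle

        tc = train_config or TrainConfig()
        X = np.asarray(X, dtype=DTYPE)
        y = np.asarray(y)
        rng = np.random.default_rng(tc.seed)
        n = len(y)
        history = {
            "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
        }
        best = None  # (acc, -loss, epoch, snapshot)
        for epoch in range(tc.epochs):
            order = rng.permutation(n)
            losses, accs = [], []
            for start in range(0, n, tc.batch_size):
                idx = order[start : start + tc.batch_size]
                loss, acc = self.loss_and_grad(X[idx], y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch "
                        f"{start // tc.batch_size}: loss={loss}"
                    )
                self.adam_step(tc.lr, tc.beta1, tc.beta2)
                losses.append(loss)
                accs.append(acc)
            history["train_loss"].append(float(np.mean(losses)))
            history["train_acc"].append(float(np.mean(accs)))
            if X_val is not None:
                proba = self.predict_proba(X_val)
                vl = _xent(proba, np.asarray(y_val))
                va = float((proba.argmax(1) == np.asarray(y_val)).mean())
                history["val_loss"].append(vl)
                history["val_acc"].append(va)
                key = (va, -vl)
                if best is None or key > best[0]:
                    best = (key, epoch, self._snapshot())
        if best is not None and not getattr(tc, "restore_best", True):
            history["best_epoch"] = best[1]
            history["best_val_acc"] = best[0][0]
            history["best_val_loss"] = -best[0][1]
            best = None
        if best is not None:
            self._restore(best[2])
            history["best_epoch"] = best[1]
            history["best_val_acc"] = best[0][0]
            history["best_val_loss"] = -best[0][1]
        self.trained = True
        self.history = history
        return history

    # -- persistence --------------------------------------------------------

    def save(self, path):
        """Single-file checkpoint: layer-name -> array plus a JSON config."""
        import json
        from dataclasses import asdict

        arrays = {p.name + f"_{i}": p.value for i, p in enumerate(self.params)}
        arrays["_running"] = np.concatenate(
            [
                np.concatenate([bn.running_mean, bn.running_var])
                for bn in (self.bn1, self.bn2, self.bn3)
            ]
        )
        arrays["_config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path):
        import json

        from .models import ModelConfig

        data = np.load(path)
        cfg = ModelConfig(
            **json.loads(bytes(data["_config_json"]).decode())
        )
        dec = cls(cfg, seed=0)
        for i, p in enumerate(dec.params):
            p.value = data[p.name + f"_{i}"].astype(DTYPE)
        run = data["_running"]
        off = 0
        for bn in (dec.bn1, dec.bn2, dec.bn3):
            k = bn.running_mean.size
            bn.running_mean = run[off : off + k].astype(DTYPE)
            bn.running_var = run[off + k : off + 2 * k].astype(DTYPE)
            off += 2 * k
        dec.trained = True
        return dec
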