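"""Confounding-factor correction component: a large-kernel 1-D CNN.

The corrector ``f(X; delta)`` scans the SNP sequence with 16 kernels of
width ~p/10, forcing the network to respond to broad, population-level
allele-frequency patterns rather than individual SNPs.  Its per-sample
scalar output estimates the population-level (first-order) confounding
contribution to the phenotype; the residual phenotype is then handed to
the selector.

Architecture (for p = 10000): conv(16 kernels, width 1000, same padding,
truncated-normal init) -> ReLU -> non-overlapping max-pool(size 2000,
stride 2000) -> flatten (5 x 16 = 80 features) -> dense(32) ->
dropout(rate 0.9, training only) -> dense(1).

For p below the pool size the kernel and pool are scaled proportionally
(kernel p/10, pool p/5), keeping the 5-position pooled map; construction
with the full-scale sizes on a small p raises an error pointing at this
mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nnet import (Adam, TrainConfig, bce_with_logits, conv1d_same,
                   conv1d_weight_grad, iter_batches, sigmoid, truncated_normal)

__all__ = ["CorrectorModel", "fit_corrector", "residualize", "ResidualTarget"]

N_KERNELS = 16
KERNEL_SIZE = 1000
POOL_SIZE = 2000
FC1_OUT = 32


class CorrectorModel:
    """1-D CNN estimating per-sample population-level phenotype effects."""

    def __init__(self, p: int, task_kind: str = "continuous",
                 kernel_size: int = KERNEL_SIZE, pool_size: int = POOL_SIZE,
                 n_kernels: int = N_KERNELS, fc1_out: int = FC1_OUT,
                 dropout_rate: float = 0.9, init_std: float = 0.1,
                 rng: np.random.Generator | None = None):
        if p < pool_size:
            raise ValueError(
                f"p={p} is smaller than the pool size {pool_size}; scale the "
                "kernel and pool proportionally for small p, e.g. "
                "CorrectorModel.scaled_for(p) (kernel p/10, pool p/5)")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.p = p
        self.task_kind = task_kind
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.n_kernels = n_kernels
        self.dropout_rate = dropout_rate
        self.n_pooled = p // pool_size
        n_flat = self.n_pooled * n_kernels
        self.params = {
            "Wc": truncated_normal(rng, (n_kernels, kernel_size), init_std),
            "bc": np.zeros(n_kernels),
            "W1": truncated_normal(rng, (n_flat, fc1_out), init_std),
            "b1": np.zeros(fc1_out),
            "W2": truncated_normal(rng, (fc1_out, 1), init_std),
            "b2": np.zeros(1),
        }

    @classmethod
    def scaled_for(cls, p: int, **kw) -> "CorrectorModel":
        """Small-p mode: kernel p/10 and pool p/5, preserving the full-scale
        kernel:pool:p proportions."""
        return cls(p, kernel_size=max(2, p // 10), pool_size=max(2, p // 5), **kw)

    # -- forward -----------------------------------------------------------

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Return (output (n,), cache) — cache only populated when training."""
        X = np.asarray(X, dtype=float)
        b = X.shape[0]
        P = self.pool_size
        conv = conv1d_same(X, self.params["Wc"]) + self.params["bc"][None, :, None]
        relu = np.maximum(conv, 0.0)
        t = self.n_pooled
        windows = relu[:, :, :t * P].reshape(b, self.n_kernels, t, P)
        argmax = windows.argmax(axis=-1)
        pooled = np.take_along_axis(windows, argmax[..., None], axis=-1)[..., 0]
        flat = pooled.reshape(b, -1)
        h1 = flat @ self.params["W1"] + self.params["b1"]
        if training and self.dropout_rate > 0:
            if rng is None:
                raise ValueError("training forward needs an rng for dropout")
            keep = 1.0 - self.dropout_rate
            mask = (rng.random(h1.shape) < keep) / keep
            h1d = h1 * mask
        else:
            mask = None
            h1d = h1
        out = (h1d @ self.params["W2"] + self.params["b2"])[:, 0]
        cache = (X, conv, argmax, flat, h1d, mask) if training else None
        return out, cache

    def predict(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        """Deterministic inference (dropout off), chunked over samples."""
        X = np.asarray(X, dtype=float)
        return np.concatenate([self.forward(X[s:s + batch])[0]
                               for s in range(0, X.shape[0], batch)])

    # -- backward ----------------------------------------------------------

    def backward(self, dout: np.ndarray, cache) -> dict[str, np.ndarray]:
        X, conv, argmax, flat, h1d, mask = cache
        b = X.shape[0]
        P = self.pool_size
        grads = {}
        grads["W2"] = h1d.T @ dout[:, None]
        grads["b2"] = np.array([dout.sum()])
        dh1 = dout[:, None] @ self.params["W2"].T
        if mask is not None:
            dh1 = dh1 * mask
        grads["W1"] = flat.T @ dh1
        grads["b1"] = dh1.sum(axis=0)
        dflat = dh1 @ self.params["W1"].T
        dpooled = dflat.reshape(b, self.n_kernels, self.n_pooled)
        dconv = np.zeros_like(conv)
        dwin = dconv[:, :, :self.n_pooled * P].reshape(b, self.n_kernels,
                                                       self.n_pooled, P)
        np.put_along_axis(dwin, argmax[..., None], dpooled[..., None], axis=-1)
        dconv[:, :, :self.n_pooled * P] = dwin.reshape(b, self.n_kernels, -1)
        dconv *= (conv > 0)
        grads["bc"] = dconv.sum(axis=(0, 2))
        grads["Wc"] = conv1d_weight_grad(X, dconv, self.kernel_size)
        return grads


def fit_corrector(X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
                  rng: np.random.Generator,
                  model: CorrectorModel | None = None
                  ) -> tuple[CorrectorModel, list[float]]:
    """Fit the corrector by Adam for the fixed (small) epoch budget.

    Returns the model and the per-epoch mean training loss.  The short
    budget is deliberate: run further, the CNN starts absorbing genetic
    signal beyond the population-level pattern it is meant to capture.
    """
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if model is None:
        if p >= POOL_SIZE:
            model = CorrectorModel(p, task_kind=cfg.task_kind,
                                   dropout_rate=cfg.dropout_rate,
                                   init_std=cfg.init_std, rng=rng)
        else:
            model = CorrectorModel.scaled_for(p, task_kind=cfg.task_kind,
                                              dropout_rate=cfg.dropout_rate,
                                              init_std=cfg.init_std, rng=rng)
    opt = Adam(model.params, lr=cfg.learning_rate)
    trace: list[float] = []
    for _ in range(cfg.corrector_epochs):
        losses, weights = [], []
        for idx in iter_batches(X.shape[0], cfg.batch_size, rng):
            out, cache = model.forward(X[idx], training=True, rng=rng)
            yb = y[idx]
            if cfg.task_kind == "continuous":
                diff = out - yb
                loss = float(np.mean(diff ** 2))
                dout = 2.0 * diff / idx.size
            else:
                loss = bce_with_logits(out, yb)
                dout = (sigmoid(out) - yb) / idx.size
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"corrector loss became non-finite ({loss}) at epoch "
                    f"{len(trace) + 1}; inspect learning rate / input scale")
            opt.step(model.backward(dout, cache))
            losses.append(loss)
            weights.append(idx.size)
        trace.append(float(np.average(losses, weights=weights)))
    return model, trace


@dataclass
class ResidualTarget:
    """What the selector fits after confounder correction.

    Continuous phenotypes: ``target`` is the residual y - f(X) and
    ``offset`` is zero.  Binary phenotypes: ``target`` stays y and the
    corrector output is carried as a fixed additive ``offset`` on the
    logit scale inside the selector's link.
    """

    target: np.ndarray
    offset: np.ndarray
    task_kind: str


def residualize(y: np.ndarray, pop_effect: np.ndarray,
                task_kind: str = "continuous") -> ResidualTarget:
    y = np.asarray(y, dtype=float)
    pop_effect = np.asarray(pop_effect, dtype=float)
    if y.shape != pop_effect.shape:
        raise ValueError("y and pop_effect must have the same shape")
    if task_kind == "continuous":
        return ResidualTarget(y - pop_effect, np.zeros_like(y), task_kind)
    if task_kind == "binary":
        return ResidualTarget(y, pop_effect, task_kind)
    raise ValueError(f"unknown task_kind {task_kind!r}")
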