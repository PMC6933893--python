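"""Fixed-effect estimation component: SNP weighting vector + LSTM.

The selector computes ``h(X_i; theta) = l(X_i * omega; iota)``: each SNP
column is scaled by its entry of the weighting vector ``omega`` before the
sequence is consumed by an LSTM ``l`` with hidden size round(0.15 p) and a
scalar output head on the final hidden state.  Because ``omega`` multiplies
the raw genotypes one-to-one, ``|omega_j|`` after training reflects how much
SNP j matters to the fit, and is used directly as the association score.

The p weighted values enter the LSTM as ceil(p / w) timesteps of width w
(default one SNP per step); w trades sequence length against per-step width
and matters only for speed, since the network sees the same inputs either
way.  theta = [omega; iota] is trained jointly by backpropagation through
time under the fixed-budget early stop.
"""

from __future__ import annotations

import numpy as np

from .nnet import (Adam, TrainConfig, bce_with_logits, iter_batches, sigmoid,
                   truncated_normal)
from .corrector import ResidualTarget

__all__ = ["SelectorModel", "fit_selector", "snp_scores"]


class SelectorModel:
    """Weighting vector + single-layer LSTM + scalar output head.

    Parameters
    ----------
    p : number of SNPs (length of omega)
    hidden : LSTM hidden units; defaults to round(0.15 p)
    chunk_width : SNPs consumed per timestep
    omega_init : 'ones' or 'truncated_normal' (see docs/methods.md)
    """

    def __init__(self, p: int, hidden: int | None = None, chunk_width: int = 1,
                 omega_init: str = "truncated_normal", init_std: float = 0.1,
                 rng: np.random.Generator | None = None,
                 compute_dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.p = p
        # batch compute runs in float32 by default (heavy BPTT matmuls);
        # parameters and Adam state stay float64
        self.compute_dtype = compute_dtype
        self.w = int(chunk_width)
        if self.w < 1:
            raise ValueError("chunk_width must be >= 1")
        self.T = -(-p // self.w)  # ceil
        self.hidden = int(round(0.15 * p)) if hidden is None else int(hidden)
        if self.hidden < 1:
            raise ValueError("hidden size must be >= 1")
        H, w = self.hidden, self.w
        if omega_init == "ones":
            omega = np.ones(p)
        elif omega_init == "truncated_normal":
            omega = truncated_normal(rng, p, init_std)
        else:
            raise ValueError(f"unknown omega_init {omega_init!r}")
        self.params = {
            "omega": omega,
            "Wx": truncated_normal(rng, (w, 4 * H), init_std),
            "Wh": truncated_normal(rng, (H, 4 * H), init_std),
            "b": np.zeros(4 * H),
            "Wo": truncated_normal(rng, (H, 1), init_std),
            "bo": np.zeros(1),
        }

    # gate layout in the 4H axis: [input, forget, cell-candidate, output]

    def _sequence(self, X: np.ndarray) -> np.ndarray:
        """Weight SNPs by omega and fold into (b, T, w), zero-padded."""
        b = X.shape[0]
        V = X * self.params["omega"]
        if self.T * self.w != self.p:
            V = np.pad(V, ((0, 0), (0, self.T * self.w - self.p)))
        return V.reshape(b, self.T, self.w)

    def forward(self, X: np.ndarray, training: bool = False):
        """Return (output (b,), cache)."""
        dt = self.compute_dtype
        X = np.asarray(X, dtype=float)
        b = X.shape[0]
        H = self.hidden
        Wx = self.params["Wx"].astype(dt)
        Wh = self.params["Wh"].astype(dt)
        bias = self.params["b"].astype(dt)
        seq = self._sequence(X).astype(dt)
        h = np.zeros((b, H), dtype=dt)
        c = np.zeros((b, H), dtype=dt)
        gates_all = np.empty((self.T, b, 4 * H), dtype=dt) if training else None
        c_all = np.empty((self.T, b, H), dtype=dt) if training else None
        h_prev_all = np.empty((self.T, b, H), dtype=dt) if training else None
        for t in range(self.T):
            if training:
                h_prev_all[t] = h
            z = seq[:, t, :] @ Wx + h @ Wh + bias
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            if training:
                gates_all[t] = np.concatenate([i, f, g, o], axis=1)
                c_all[t] = c
        out = (h @ self.params["Wo"].astype(dt)
               + self.params["bo"].astype(dt))[:, 0].astype(float)
        cache = (X, seq, gates_all, c_all, h_prev_all, h) if training else None
        return out, cache

    def predict(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.concatenate([self.forward(X[s:s + batch])[0]
                               for s in range(0, X.shape[0], batch)])

    def backward(self, dout: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Backprop through time; returns grads for every entry of params."""
        dt = self.compute_dtype
        X, seq, gates_all, c_all, h_prev_all, h_T = cache
        b = X.shape[0]
        H, w = self.hidden, self.w
        Wx = self.params["Wx"].astype(dt)
        Wh = self.params["Wh"].astype(dt)
        Wo = self.params["Wo"].astype(dt)
        dout = np.asarray(dout, dtype=dt)
        grads = {k: np.zeros(v.shape, dtype=dt) for k, v in self.params.items()}
        grads["Wo"] = h_T.T @ dout[:, None]
        grads["bo"] = np.array([dout.sum()], dtype=dt)
        dh = dout[:, None] @ Wo.T
        dc = np.zeros((b, H), dtype=dt)
        dseq = np.empty((b, self.T, w), dtype=dt)
        for t in range(self.T - 1, -1, -1):
            i = gates_all[t][:, :H]
            f = gates_all[t][:, H:2 * H]
            g = gates_all[t][:, 2 * H:3 * H]
            o = gates_all[t][:, 3 * H:]
            c = c_all[t]
            c_prev = c_all[t - 1] if t > 0 else np.zeros((b, H), dtype=dt)
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            grads["Wx"] += seq[:, t, :].T @ dz
            grads["Wh"] += h_prev_all[t].T @ dz
            grads["b"] += dz.sum(axis=0)
            dseq[:, t, :] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        dV = dseq.reshape(b, self.T * w)[:, :self.p]
        grads["omega"] = (X.astype(dt) * dV).sum(axis=0)
        return {k: v.astype(float) for k, v in grads.items()}


def fit_selector(X: np.ndarray, target: ResidualTarget, cfg: TrainConfig,
                 rng: np.random.Generator,
                 model: SelectorModel | None = None
                 ) -> tuple[SelectorModel, list[float]]:
    """Fit theta = [omega; iota] by Adam for the fixed epoch budget.

    Continuous task: minimizes squared error against the residual
    phenotype.  Binary task: minimizes cross-entropy of
    sigmoid(offset + h(X; theta)), the offset being the corrector's
    logit-scale contribution (zero for the LSTM-only baseline).
    """
    cfg.validate()
    X = np.asarray(X, dtype=float)
    if model is None:
        model = SelectorModel(X.shape[1],
                              hidden=int(round(cfg.hidden_frac * X.shape[1])),
                              chunk_width=cfg.chunk_width,
                              init_std=cfg.init_std, rng=rng)
    opt = Adam(model.params, lr=cfg.learning_rate)
    trace: list[float] = []
    yt, offset = target.target, target.offset
    for _ in range(cfg.selector_epochs):
        losses, weights = [], []
        for idx in iter_batches(X.shape[0], cfg.batch_size, rng):
            out, cache = model.forward(X[idx], training=True)
            if cfg.task_kind == "continuous":
                diff = out - yt[idx]
                loss = float(np.mean(diff ** 2))
                dout = 2.0 * diff / idx.size
            else:
                logits = out + offset[idx]
                loss = bce_with_logits(logits, yt[idx])
                dout = (sigmoid(logits) - yt[idx]) / idx.size
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"selector loss became non-finite ({loss}) at epoch "
                    f"{len(trace) + 1}; inspect learning rate / input scale")
            opt.step(model.backward(dout, cache))
            losses.append(loss)
            weights.append(idx.size)
        trace.append(float(np.average(losses, weights=weights)))
    return model, trace


def snp_scores(model: SelectorModel):
    """Per-SNP association scores |omega_j| (higher = more associated)."""
    from .scores import ScoreVector
    return ScoreVector(scores=np.abs(model.params["omega"]),
                       method="selector_omega",
                       orientation="higher_is_associated")
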