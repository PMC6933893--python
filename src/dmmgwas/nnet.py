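"""Minimal NumPy neural-network core: initializers, Adam, FFT 1-D convolution.

Everything the corrector CNN and selector LSTM need, batch-vectorized and
driven by explicit ``numpy.random.Generator`` objects so that every fit is
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft

__all__ = ["truncated_normal", "Adam", "conv1d_same", "conv1d_weight_grad",
           "sigmoid", "bce_with_logits", "TrainConfig"]


def truncated_normal(rng: np.random.Generator, shape, std: float = 0.1) -> np.ndarray:
    """Normal(0, std) truncated at +-2 std, drawn by rejection."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2.0 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2.0 * std
    return out


def sigmoid(z: np.ndarray) -> np.ndarray:
    # scipy.special.expit, inlined to keep hot loops allocation-light
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, numerically stable in the logits."""
    return float(np.mean(np.maximum(logits, 0) - logits * y
                         + np.log1p(np.exp(-np.abs(logits)))))


class Adam:
    """ADAM over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            self.params[k] -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps)


# ---------------------------------------------------------------------------
# FFT-based 1-D cross-correlation ("same" padding), needed because the
# corrector's kernels are enormous (width ~p/10) and direct convolution
# would be quadratic in the kernel size.

def conv1d_same(X: np.ndarray, W: np.ndarray, chunk: int = 32) -> np.ndarray:
    """Cross-correlate each row of X (b, p) with each kernel of W (c, K).

    Returns (b, c, p) with zero 'same' padding: out[b,c,i] =
    sum_j X[b, i+j-pad] W[c,j], pad = (K-1)//2.
    """
    b, p = X.shape
    c, K = W.shape
    pad = (K - 1) // 2
    L = next_fast_len(p + K - 1)
    Wf = rfft(W[:, ::-1], n=L, axis=-1)  # reversal turns convolution into correlation
    out = np.empty((b, c, p))
    offset = K - 1 - pad
    for s in range(0, b, chunk):
        Xf = rfft(X[s:s + chunk], n=L, axis=-1)
        full = irfft(Xf[:, None, :] * Wf[None, :, :], n=L, axis=-1)
        out[s:s + chunk] = full[..., offset:offset + p]
    return out


def conv1d_weight_grad(X: np.ndarray, dout: np.ndarray, K: int,
                       chunk: int = 32) -> np.ndarray:
    """Gradient of conv1d_same w.r.t. the kernels.

    dW[c,j] = sum_b sum_i dout[b,c,i] X[b, i+j-pad]; accumulated in the
    frequency domain so only one inverse FFT per kernel is needed.
    """
    b, p = X.shape
    c = dout.shape[1]
    pad = (K - 1) // 2
    L = next_fast_len(2 * p - 1)
    acc = None
    for s in range(0, b, chunk):
        Af = rfft(dout[s:s + chunk, :, ::-1], n=L, axis=-1)  # (bc, c, Lf)
        Bf = rfft(X[s:s + chunk], n=L, axis=-1)  # (bc, Lf)
        part = (Af * Bf[:, None, :]).sum(axis=0)
        acc = part if acc is None else acc + part
    full = irfft(acc, n=L, axis=-1)  # (c, L); lag l at index l + p - 1
    start = p - 1 - pad
    return full[:, start:start + K]


from dataclasses import dataclass, field


@dataclass
class TrainConfig:
    """Optimization settings shared by corrector and selector fits.

    The epoch budgets double as early stopping: training always halts at
    the fixed budget, well before convergence, which regularizes both
    networks (particularly the corrector, which would otherwise absorb
    genetic signal beyond the population-level pattern).
    """

    task_kind: str = "continuous"  # chooses squared error + identity link,
    # or cross-entropy + logit link, jointly
    learning_rate: float = 0.001
    batch_size: int = 128
    corrector_epochs: int = 20
    selector_epochs: int = 1500
    chunk_width: int = 1  # SNPs per LSTM timestep
    hidden_frac: float = 0.15  # LSTM hidden units = round(hidden_frac * p)
    dropout_rate: float = 0.9  # drop probability in the corrector head
    init_std: float = 0.1  # truncated-normal initializer scale

    def validate(self) -> None:
        if self.task_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


def iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    """Shuffled mini-batch index iterator; single full batch when n < batch."""
    if n <= batch_size:
        yield np.arange(n)
        return
    order = rng.permutation(n)
    for s in range(0, n, batch_size):
        yield order[s:s + batch_size]
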