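"""The deep mixed model: corrector -> residualize -> selector -> scores.

Two-stage estimation.  First the corrector CNN is fit to the raw phenotype
(Eq. stage 1), capturing the population-level confounding signal.  Its
per-sample output is removed from the phenotype — subtracted for continuous
traits, carried as a fixed logit offset for binary traits — and the
selector (weighting vector + LSTM) is fit to what remains (stage 2).  The
magnitude of the learned weighting vector is the per-SNP association score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corrector import CorrectorModel, fit_corrector, residualize
from .nnet import TrainConfig
from .scores import ScoreVector
from .selector import SelectorModel, fit_selector, snp_scores

__all__ = ["DMMResult", "fit_dmm", "fit_lstm_only", "TrainConfig"]


@dataclass
class DMMResult:
    corrector: CorrectorModel | None
    selector: SelectorModel
    scores: ScoreVector
    corrector_trace: list[float]
    selector_trace: list[float]
    pop_effect: np.ndarray  # corrector output per sample (zeros if ablated)


def fit_dmm(X: np.ndarray, y: np.ndarray, cfg: TrainConfig | None = None,
            seed: int = 0) -> DMMResult:
    """Fit the full two-component model; deterministic given the seed.

    Corrector and selector draw from independent component-indexed RNG
    streams, so the selector's initialization and batch order are
    identical between the full model and the corrector-ablated baseline
    at the same seed (paired comparisons isolate the corrector's effect).
    """
    cfg = cfg if cfg is not None else TrainConfig()
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    corrector, ctrace = fit_corrector(X, y, cfg,
                                      np.random.default_rng([seed, 0]))
    pop_effect = corrector.predict(X)
    target = residualize(y, pop_effect, cfg.task_kind)
    selector, strace = fit_selector(X, target, cfg,
                                    np.random.default_rng([seed, 1]))
    sc = snp_scores(selector)
    sc.method = "DMM"
    return DMMResult(corrector=corrector, selector=selector, scores=sc,
                     corrector_trace=ctrace, selector_trace=strace,
                     pop_effect=pop_effect)


def fit_lstm_only(X: np.ndarray, y: np.ndarray, cfg: TrainConfig | None = None,
                  seed: int = 0) -> DMMResult:
    """Selector-only ablation: no confounder correction (zero offset).

    Equivalent to fit_dmm with the corrector output forced to zero; the
    baseline the full model is compared against.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    pop_effect = np.zeros(X.shape[0])
    target = residualize(y, pop_effect, cfg.task_kind)
    selector, strace = fit_selector(X, target, cfg,
                                    np.random.default_rng([seed, 1]))
    sc = snp_scores(selector)
    sc.method = "LSTM"
    return DMMResult(corrector=None, selector=selector, scores=sc,
                     corrector_trace=[], selector_trace=strace,
                     pop_effect=pop_effect)
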