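"""Shared per-SNP score container with orientation metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScoreVector"]


@dataclass
class ScoreVector:
    """One real-valued association score per SNP.

    ``orientation`` records whether larger scores mean stronger association
    (e.g. |omega|, -log p already transformed) or weaker (raw p-values), so
    the evaluation layer can sweep thresholds in the right direction.
    """

    scores: np.ndarray
    method: str
    orientation: str = "higher_is_associated"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.orientation not in ("higher_is_associated",
                                    "lower_is_associated"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError(f"non-finite scores in method {self.method!r}")

    @property
    def p(self) -> int:
        return self.scores.shape[0]

    def strengths(self) -> np.ndarray:
        """Scores on a higher-is-more-associated scale.

        p-value-like scores are mapped through -log10 (clipped at 1e-300),
        the monotone transform matching a p-value threshold sweep.
        """
        if self.orientation == "higher_is_associated":
            return self.scores
        return -np.log10(np.clip(self.scores, 1e-300, None))
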