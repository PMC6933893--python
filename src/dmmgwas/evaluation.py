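"""Candidate-restricted ROC/AUC protocol and the benchmark grid.

Every method produces one score per SNP.  The protocol ranks SNPs by
association strength, keeps only the top 10% (1000 of 10000 SNPs by
default) as distinct candidates, and pools every remaining SNP at one tied
worst score.  ROC curves are computed over the full ranking with tied
blocks contributing diagonal segments, so a method with no usable ranking
— e.g. an L1 path whose active set misses the causal SNPs — scores exactly
0.5.  AUC is the trapezoidal area, which under this tie convention equals
the Mann-Whitney U statistic with ties counted 1/2.

The grid runner executes settings x methods x replicate seeds (replicate
seed = base seed + replicate index) and reports per-setting mean AUCs in
the benchmark's row layout (phenotype kind, n, sigma_u^2, k).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .scores import ScoreVector
from .simgen import SimConfig, SimDataset, simulate_dataset

__all__ = ["ROCCurve", "restricted_roc", "evaluate_method", "GridResult",
           "run_grid", "diagnose_corrector", "make_method_registry"]


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    candidate_cap: int
    method: str = ""


def restricted_roc(scores: ScoreVector, causal_indices: np.ndarray,
                   candidate_cap: int = 1000, method: str | None = None) -> ROCCurve:
    """ROC over the capped ranking; positives are the causal SNPs.

    SNPs ranked beyond ``candidate_cap`` are pooled into a single tied
    block strictly below every candidate; tied blocks appear as diagonal
    ROC segments, and the AUC is the trapezoidal area under the curve.
    """
    causal_indices = np.asarray(causal_indices, dtype=int)
    if causal_indices.size == 0:
        raise ValueError("causal index set is empty")
    strengths = scores.strengths().astype(float)
    p = strengths.shape[0]
    if not (0 < candidate_cap <= p):
        raise ValueError(f"candidate_cap must lie in (0, {p}]")
    if candidate_cap < p:
        # pool by strength threshold so tied blocks are never split: every
        # SNP strictly weaker than the rank-cap strength joins one tied
        # worst block (an all-tied, uninformative method thus stays 0.5)
        threshold = np.sort(strengths)[::-1][candidate_cap - 1]
        pooled = strengths.min() - 1.0
        strengths = strengths.copy()
        strengths[strengths < threshold] = pooled
    is_pos = np.zeros(p, dtype=bool)
    is_pos[causal_indices] = True
    n_pos = int(is_pos.sum())
    n_neg = p - n_pos
    if n_neg == 0:
        raise ValueError("no negative SNPs")
    # group by unique strength, descending; each block is one threshold step
    uniq, inv = np.unique(-strengths, return_inverse=True)
    n_blocks = uniq.shape[0]
    tp_block = np.bincount(inv, weights=is_pos.astype(float), minlength=n_blocks)
    fp_block = np.bincount(inv, weights=(~is_pos).astype(float), minlength=n_blocks)
    tpr = np.concatenate([[0.0], np.cumsum(tp_block) / n_pos])
    fpr = np.concatenate([[0.0], np.cumsum(fp_block) / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc, candidate_cap=candidate_cap,
                    method=method if method is not None else scores.method)


def evaluate_method(dataset: SimDataset,
                    method: Callable[[SimDataset], ScoreVector],
                    candidate_cap: int | None = None) -> ROCCurve:
    """Score the dataset with ``method`` and apply the restricted protocol.

    ``candidate_cap`` defaults to 10% of p (1000 when p = 10000).
    """
    sv = method(dataset) if callable(method) else method
    cap = candidate_cap if candidate_cap is not None else max(1, dataset.config.p // 10)
    return restricted_roc(sv, dataset.truth.causal_indices, candidate_cap=cap)


# ---------------------------------------------------------------------------
# method registry and the settings grid

def make_method_registry(train_cfg=None, lambda_grid=None, seed_offset: int = 0
                         ) -> dict[str, Callable[[SimDataset], ScoreVector]]:
    """Standard scorers keyed by the benchmark's method labels.

    ``train_cfg`` (a :class:`~dmmgwas.nnet.TrainConfig`) controls the deep
    models; its ``task_kind`` is overridden per dataset.
    """
    from .baselines import (adaptive_lasso_scores, lasso_scores, lmm_scan,
                            univariate_wald)
    from .dmm import fit_dmm, fit_lstm_only
    from .nnet import TrainConfig

    base = train_cfg if train_cfg is not None else TrainConfig()

    def _cfg(ds):
        return replace(base, task_kind=ds.config.phenotype_kind)

    return {
        "UT": lambda ds: univariate_wald(ds.X, ds.y, ds.config.phenotype_kind),
        "LMM": lambda ds: lmm_scan(ds.X, ds.y, ds.config.phenotype_kind),
        "LASSO": lambda ds: lasso_scores(ds.X, ds.y, lambda_grid),
        "AL": lambda ds: adaptive_lasso_scores(ds.X, ds.y, lambda_grid),
        "LSTM": lambda ds: fit_lstm_only(ds.X, ds.y, _cfg(ds),
                                         seed=ds.config.seed + seed_offset).scores,
        "DMM": lambda ds: fit_dmm(ds.X, ds.y, _cfg(ds),
                                  seed=ds.config.seed + seed_offset).scores,
    }


@dataclass
class GridResult:
    """Mean-AUC table (one row per setting, one column per method) plus the
    replicate-level records behind it."""

    table: pd.DataFrame
    replicates: pd.DataFrame
    failures: list[dict] = field(default_factory=list)

    def to_csv(self, table_path, replicates_path=None) -> None:
        self.table.to_csv(table_path, index=False)
        if replicates_path is not None:
            self.replicates.to_csv(replicates_path, index=False)


def run_grid(settings: Sequence[dict], methods: dict[str, Callable],
             seeds: Sequence[int], base_config: SimConfig | None = None,
             candidate_cap: int | None = None) -> GridResult:
    """Run every setting x replicate seed x method.

    Each ``settings`` entry overrides fields of ``base_config`` (typically
    phenotype_kind, n, sigma_u2, k).  Per-cell failures are recorded and
    surface as NaN cells rather than aborting the grid.
    """
    base = base_config if base_config is not None else SimConfig()
    records, failures = [], []
    for setting in settings:
        for seed in seeds:
            cfg = replace(base, seed=int(seed), **setting)
            ds = simulate_dataset(cfg)
            for name, fn in methods.items():
                try:
                    roc = evaluate_method(ds, fn, candidate_cap=candidate_cap)
                    records.append({
                        "phenotype": cfg.phenotype_kind, "n": cfg.n,
                        "sigma_u2": cfg.sigma_u2, "k": cfg.k,
                        "seed": seed, "method": name, "auc": roc.auc,
                    })
                except Exception as exc:  # noqa: BLE001 - cell isolation
                    failures.append({"setting": dict(setting), "seed": seed,
                                     "method": name, "error": repr(exc)})
    reps = pd.DataFrame.from_records(records)
    if reps.empty:
        return GridResult(table=pd.DataFrame(), replicates=reps,
                          failures=failures)
    table = (reps.pivot_table(index=["phenotype", "n", "sigma_u2", "k"],
                              columns="method", values="auc", aggfunc="mean",
                              sort=False)
             .reset_index())
    table.columns.name = None
    return GridResult(table=table, replicates=reps, failures=failures)


# ---------------------------------------------------------------------------
# corrector diagnostic

def _safe_corr(a: np.ndarray, b: np.ndarray) -> float | None:
    """Pearson correlation, or None when either series is constant."""
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def diagnose_corrector(dataset: SimDataset, corrector, selector) -> dict:
    """Per-sample diagnostic of how the two components split the phenotype.

    Returns the four series (phenotype, selector-only prediction,
    corrector-only prediction, true confounder contribution G @ gamma) and
    the correlations corr(corrector, G gamma) and corr(full prediction, y).
    Only meaningful on simulated data; refuses when truth is absent.
    """
    if dataset.truth is None or dataset.truth.gamma is None:
        raise ValueError("diagnostic requires a simulated dataset with truth")
    X = dataset.X.astype(float)
    y = np.asarray(dataset.y, dtype=float)
    confounder = dataset.structure.G @ dataset.truth.gamma
    corr_out = corrector.predict(X)
    sel_out = selector.predict(X)
    dmm_pred = corr_out + sel_out
    series = pd.DataFrame({
        "y": y,
        "selector_pred": sel_out,
        "corrector_pred": corr_out,
        "confounder": confounder,
        "dmm_pred": dmm_pred,
    })
    return {
        "series": series,
        "corr_corrector_confounder": _safe_corr(corr_out, confounder),
        "corr_dmm_phenotype": _safe_corr(dmm_pred, y),
        "corr_selector_phenotype": _safe_corr(sel_out, y),
    }
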