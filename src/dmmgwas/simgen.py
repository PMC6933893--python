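"""Synthetic stratified-population GWAS cohorts with grouped marginal epistasis.

The generator emulates the study design used to benchmark the deep mixed
model: ``n`` samples drawn from 25 geographic regions (5 populations, each
split unevenly into 5 subpopulations), genotyped at ``p`` SNPs coded as
minor-allele counts 0/1/2.  ``k`` causal SNPs are partitioned into
``m = k/t`` interaction groups; each group contributes one epistatic
variable — the element-wise minimum of its member genotype columns — with a
group effect size ``beta_i ~ N(0, 25)``.  Region membership confounds the
phenotype through region effects ``gamma ~ N(0, sigma_u^2)``:

    r = sum_i min_group_i(X) * beta_i + G @ gamma

Continuous phenotypes are ``y = r + eps`` with unit Gaussian noise; binary
phenotypes are Bernoulli draws with success probability ``logistic(r)``.

Population structure follows a two-level Balding-Nichols hierarchy: an
ancestral allele frequency per SNP, population frequencies diverged from it
with ``fst_pop``, and subpopulation (region) frequencies diverged from their
population with ``fst_subpop``.  Only the region design matrix ``G`` enters
the phenotype model, so any generator producing realistic stratification of
allele frequencies serves; this one has closed-form frequency moments that
the test suite checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

__all__ = [
    "SimConfig",
    "PopulationStructure",
    "SimTruth",
    "SimDataset",
    "generate_population_structure",
    "generate_genotypes",
    "select_causal_groups",
    "epistatic_variable",
    "simulate_response",
    "simulate_phenotype",
    "simulate_dataset",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cohort.

    Defaults correspond to the easiest cell of the benchmark grid:
    500 samples, 10000 SNPs, 10 causal SNPs in groups of 5, confounder
    variance 5, continuous phenotype.
    """

    n: int = 500
    p: int = 10_000
    k: int = 10
    t: int = 5
    sigma_u2: float = 5.0
    phenotype_kind: str = "continuous"
    seed: int = 0
    n_populations: int = 5
    n_subpops_per_pop: int = 5
    fst_pop: float = 0.1
    fst_subpop: float = 0.05
    maf_range: tuple[float, float] = (0.2, 0.5)
    # Dirichlet concentration for the uneven region sizes
    region_concentration: float = 5.0

    @property
    def m(self) -> int:
        return self.k // self.t

    @property
    def q(self) -> int:
        return self.n_populations * self.n_subpops_per_pop

    def validate(self) -> None:
        if self.t < 1 or self.k % self.t != 0:
            raise ConfigError(f"k={self.k} must be divisible by t={self.t}")
        if self.k >= self.p:
            raise ConfigError(f"k={self.k} must be < p={self.p}")
        if self.n < 2:
            raise ConfigError("need at least 2 samples")
        if self.sigma_u2 < 0:
            raise ConfigError("sigma_u2 must be non-negative")
        if self.phenotype_kind not in ("continuous", "binary"):
            raise ConfigError(f"unknown phenotype_kind {self.phenotype_kind!r}")
        if not (0 <= self.fst_pop < 1 and 0 <= self.fst_subpop < 1):
            raise ConfigError("fst parameters must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi < 1")
        if self.n < self.q:
            raise ConfigError(
                f"n={self.n} is smaller than the number of regions q={self.q}; "
                "cannot populate unequal regions"
            )


@dataclass
class PopulationStructure:
    """Region assignment and per-region allele frequencies."""

    region_of_sample: np.ndarray  # (n,) int region index in [0, q)
    G: np.ndarray  # (n, q) one-hot region design
    allele_freqs: np.ndarray  # (q, p)
    ancestral_freqs: np.ndarray  # (p,)


@dataclass
class SimTruth:
    """Ground-truth manifest for one simulated cohort."""

    causal_indices: np.ndarray  # (k,) sorted
    groups: list[np.ndarray]  # m arrays of t indices, partition of causal set
    beta: np.ndarray  # (m,)
    gamma: np.ndarray  # (q,)
    r: np.ndarray  # (n,) genetic + confounder response
    epsilon: np.ndarray | None = None  # (n,) continuous case only

    def to_json_dict(self) -> dict:
        d = {
            "causal_indices": self.causal_indices.tolist(),
            "groups": [g.tolist() for g in self.groups],
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
        }
        return d


@dataclass
class SimDataset:
    """One simulated cohort: genotypes, phenotype, structure and truth."""

    X: np.ndarray  # (n, p) int8 in {0,1,2}
    y: np.ndarray  # (n,)
    structure: PopulationStructure
    truth: SimTruth
    config: SimConfig


def _balding_nichols(rng: np.random.Generator, base: np.ndarray, fst: float,
                     n_demes: int) -> np.ndarray:
    """Draw deme allele frequencies around ``base`` with divergence ``fst``.

    Beta(p(1-F)/F, (1-p)(1-F)/F) has mean p and variance F p (1-p); F = 0
    degenerates to copying ``base``.
    """
    if fst == 0:
        return np.tile(base, (n_demes, 1))
    c = (1.0 - fst) / fst
    a = np.clip(base * c, 1e-12, None)
    b = np.clip((1.0 - base) * c, 1e-12, None)
    freqs = rng.beta(a, b, size=(n_demes, base.shape[0]))
    return np.clip(freqs, 0.0, 1.0)


def generate_population_structure(cfg: SimConfig,
                                  rng: np.random.Generator) -> PopulationStructure:
    """Build region labels, the one-hot design G, and region allele frequencies.

    Region sizes are unequal: membership probabilities are drawn from a
    Dirichlet with a moderate concentration, then samples are assigned
    multinomially.
    """
    cfg.validate()
    q = cfg.q
    ancestral = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.p)
    pop_freqs = _balding_nichols(rng, ancestral, cfg.fst_pop, cfg.n_populations)
    region_freqs = np.empty((q, cfg.p))
    for pop in range(cfg.n_populations):
        sub = _balding_nichols(rng, pop_freqs[pop], cfg.fst_subpop,
                               cfg.n_subpops_per_pop)
        region_freqs[pop * cfg.n_subpops_per_pop:(pop + 1) * cfg.n_subpops_per_pop] = sub

    weights = rng.dirichlet(np.full(q, cfg.region_concentration))
    region_of_sample = rng.choice(q, size=cfg.n, p=weights)
    G = np.zeros((cfg.n, q))
    G[np.arange(cfg.n), region_of_sample] = 1.0
    return PopulationStructure(
        region_of_sample=region_of_sample,
        G=G,
        allele_freqs=region_freqs,
        ancestral_freqs=ancestral,
    )


def generate_genotypes(structure: PopulationStructure, cfg: SimConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Sample genotypes X[s, j] ~ Binomial(2, freq[region(s), j])."""
    freqs = structure.allele_freqs[structure.region_of_sample]  # (n, p)
    if freqs.shape != (cfg.n, cfg.p):
        raise ValueError(
            f"structure/config shape mismatch: {freqs.shape} vs ({cfg.n}, {cfg.p})"
        )
    return rng.binomial(2, freqs).astype(np.int8)


def select_causal_groups(cfg: SimConfig,
                         rng: np.random.Generator) -> tuple[np.ndarray, list[np.ndarray]]:
    """Pick k causal SNPs uniformly without replacement; group consecutively.

    Groups are formed from consecutive blocks of the sampled (unsorted)
    index list; ``causal_indices`` is returned sorted.
    """
    if cfg.t < 1 or cfg.k % cfg.t != 0:
        raise ConfigError(f"k={cfg.k} must be divisible by t={cfg.t}")
    sampled = rng.choice(cfg.p, size=cfg.k, replace=False)
    groups = [sampled[i * cfg.t:(i + 1) * cfg.t].copy() for i in range(cfg.m)]
    return np.sort(sampled), groups


def epistatic_variable(X_group: np.ndarray) -> np.ndarray:
    """Element-wise minimum over the group's genotype columns.

    This is the interaction variable: it is nonzero only for samples
    carrying at least one minor allele at *every* SNP in the group, which
    is what makes the grouped-interaction benchmark hard for additive
    methods.
    """
    X_group = np.asarray(X_group)
    if X_group.ndim != 2 or X_group.shape[1] == 0:
        raise ValueError("epistatic_variable needs a non-empty n x t matrix")
    return X_group.min(axis=1)


def simulate_response(X: np.ndarray, structure: PopulationStructure,
                      causal_indices: np.ndarray, groups: list[np.ndarray],
                      cfg: SimConfig, rng: np.random.Generator) -> SimTruth:
    """Draw effect sizes and form r = sum_i z_i beta_i + G gamma."""
    m = len(groups)
    beta = rng.normal(0.0, 5.0, size=m)  # variance 25
    gamma = rng.normal(0.0, np.sqrt(cfg.sigma_u2), size=cfg.q)
    r = np.zeros(X.shape[0])
    for b, g in zip(beta, groups):
        r += epistatic_variable(X[:, g]).astype(float) * b
    r += structure.G @ gamma
    return SimTruth(causal_indices=np.asarray(causal_indices), groups=list(groups),
                    beta=beta, gamma=gamma, r=r)


def simulate_phenotype(truth: SimTruth, kind: str,
                       rng: np.random.Generator) -> np.ndarray:
    """Continuous: y = r + N(0,1).  Binary: y ~ Bernoulli(logistic(r))."""
    r = truth.r
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite response r")
    if kind == "continuous":
        eps = rng.normal(0.0, 1.0, size=r.shape[0])
        truth.epsilon = eps
        return r + eps
    if kind == "binary":
        prob = expit(r)  # numerically safe at extreme r
        return (rng.random(r.shape[0]) < prob).astype(float)
    raise ValueError(f"unknown phenotype kind {kind!r}")


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Generate a full cohort deterministically from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    structure = generate_population_structure(cfg, rng)
    X = generate_genotypes(structure, cfg, rng)
    causal, groups = select_causal_groups(cfg, rng)
    truth = simulate_response(X, structure, causal, groups, cfg, rng)
    y = simulate_phenotype(truth, cfg.phenotype_kind, rng)
    return SimDataset(X=X, y=y, structure=structure, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# on-disk manifest

def write_truth_manifest(dataset: SimDataset, path: str | Path) -> None:
    """JSON truth manifest: 0-based causal indices, groups, effects, config."""
    cfg = dataset.config
    payload = dataset.truth.to_json_dict()
    payload.update({
        "sigma_u2": cfg.sigma_u2,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "region_of_sample": dataset.structure.region_of_sample.tolist(),
    })
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_manifest(path: str | Path) -> dict:
    d = json.loads(Path(path).read_text())
    d["causal_indices"] = np.asarray(d["causal_indices"], dtype=int)
    d["groups"] = [np.asarray(g, dtype=int) for g in d["groups"]]
    d["beta"] = np.asarray(d["beta"])
    d["gamma"] = np.asarray(d["gamma"])
    return d
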