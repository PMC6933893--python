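"""Simulator unit and property tests.

Oracles: explicit-loop recomputations of the response, closed-form
Balding-Nichols frequency moments, and binomial/logistic sampling moments.
"""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chi2_contingency

from dmmgwas.simgen import (ConfigError, SimConfig, epistatic_variable,
                            generate_genotypes, generate_population_structure,
                            select_causal_groups, simulate_dataset,
                            simulate_phenotype, simulate_response)


def _structure(cfg, seed=0):
    return generate_population_structure(cfg, np.random.default_rng(seed))


class TestPopulationStructure:
    def test_one_hot_design_and_region_count(self):
        cfg = SimConfig(n=500, p=200)
        s = _structure(cfg)
        assert s.G.shape == (500, 25)
        assert np.all(s.G.sum(axis=1) == 1.0)
        assert s.allele_freqs.shape == (25, 200)
        assert np.all((s.allele_freqs >= 0) & (s.allele_freqs <= 1))

    def test_region_sizes_unequal(self):
        cfg = SimConfig(n=500, p=50)
        s = _structure(cfg, seed=3)
        counts = np.bincount(s.region_of_sample, minlength=25)
        assert len(set(counts.tolist())) > 1

    def test_zero_divergence_collapses_to_ancestral(self):
        cfg = SimConfig(n=100, p=80, fst_pop=0.0, fst_subpop=0.0)
        s = _structure(cfg)
        assert np.allclose(s.allele_freqs, s.ancestral_freqs[None, :])

    def test_balding_nichols_variance_moment(self):
        # E[sample variance across the q region frequencies] =
        # pbar(1-pbar) * (f_total - f_pop * within_pop_pair_share), with
        # f_total = f1 + f2(1-f1); within-population region pairs share
        # covariance f1 * pbar(1-pbar).
        cfg = SimConfig(n=200, p=4000, seed=1)
        s = _structure(cfg, seed=1)
        f1, f2 = cfg.fst_pop, cfg.fst_subpop
        f_tot = f1 + f2 * (1 - f1)
        q = cfg.q
        n_pairs = q * (q - 1)
        within = cfg.n_populations * cfg.n_subpops_per_pop * (cfg.n_subpops_per_pop - 1)
        expected_factor = f_tot - f1 * within / n_pairs
        pq = s.ancestral_freqs * (1 - s.ancestral_freqs)
        ratio = np.mean(s.allele_freqs.var(axis=0, ddof=1) / pq)
        assert ratio == pytest.approx(expected_factor, rel=0.05)

    def test_rejects_fewer_samples_than_regions(self):
        with pytest.raises(ConfigError, match="regions"):
            SimConfig(n=10, p=100).validate()

    def test_zero_divergence_chi2_homogeneity(self):
        # with fst = 0 allele counts are homogeneous across regions: the
        # chi-square test is non-significant at 0.05 for >= 90% of SNPs
        cfg = SimConfig(n=500, p=300, fst_pop=0.0, fst_subpop=0.0, seed=5)
        s = _structure(cfg, seed=5)
        X = generate_genotypes(s, cfg, np.random.default_rng(6))
        sig = 0
        for j in range(cfg.p):
            minor = np.bincount(s.region_of_sample, weights=X[:, j],
                                minlength=25)
            total = 2.0 * np.bincount(s.region_of_sample, minlength=25)
            keep = total > 0
            table = np.vstack([minor[keep], total[keep] - minor[keep]])
            if table.min() >= 0 and table.sum(axis=0).min() > 0:
                p = chi2_contingency(table + 0.5)[1]
                sig += p < 0.05
        assert sig / cfg.p <= 0.10


class TestGenotypes:
    def test_degenerate_frequencies(self):
        cfg = SimConfig(n=50, p=4, k=2, t=2)
        s = _structure(cfg)
        s.allele_freqs[:, 0] = 0.0
        s.allele_freqs[:, 1] = 1.0
        X = generate_genotypes(s, cfg, np.random.default_rng(0))
        assert np.all(X[:, 0] == 0)
        assert np.all(X[:, 1] == 2)
        assert set(np.unique(X)) <= {0, 1, 2}

    def test_binomial_mean(self):
        cfg = SimConfig(n=10_000, p=1, n_populations=1, n_subpops_per_pop=1,
                        k=0, t=1)
        s = _structure(cfg)
        s.allele_freqs[:] = 0.5
        X = generate_genotypes(s, cfg, np.random.default_rng(1))
        se = np.sqrt(2 * 0.5 * 0.5 / cfg.n)
        assert abs(X.mean() - 1.0) < 3 * se


class TestCausalGroups:
    @pytest.mark.parametrize("k,t,m", [(10, 5, 2), (50, 5, 10), (5, 5, 1)])
    def test_partition(self, k, t, m):
        cfg = SimConfig(n=100, p=400, k=k, t=t)
        causal, groups = select_causal_groups(cfg, np.random.default_rng(2))
        assert len(groups) == m
        union = np.sort(np.concatenate(groups))
        assert union.shape == (k,)
        assert len(np.unique(union)) == k
        assert np.array_equal(union, causal)
        assert np.array_equal(causal, np.sort(causal))

    def test_indivisible_group_size_rejected(self):
        with pytest.raises(ConfigError):
            select_causal_groups(SimConfig(n=100, p=400, k=10, t=3),
                                 np.random.default_rng(0))


class TestEpistaticVariable:
    def test_row_with_zero_gives_zero(self):
        assert epistatic_variable(np.array([[0, 2, 1, 2, 1]]))[0] == 0

    def test_singleton_group_identity(self):
        col = np.array([[0], [1], [2]])
        assert np.array_equal(epistatic_variable(col), [0, 1, 2])

    def test_matches_double_loop_oracle(self, rng):
        X = rng.integers(0, 3, size=(20, 5))
        got = epistatic_variable(X)
        for i in range(20):
            m = 2
            for j in range(5):
                if X[i, j] < m:
                    m = X[i, j]
            assert got[i] == m

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            epistatic_variable(np.empty((5, 0)))


class TestResponse:
    def test_matches_naive_recomputation(self):
        cfg = SimConfig(n=50, p=100, k=10, t=5, seed=3)
        ds = simulate_dataset(cfg)
        r = np.zeros(cfg.n)
        for i, g in enumerate(ds.truth.groups):
            for s in range(cfg.n):
                zmin = min(ds.X[s, j] for j in g)
                r[s] += zmin * ds.truth.beta[i]
        for s in range(cfg.n):
            r[s] += ds.truth.gamma[ds.structure.region_of_sample[s]]
        assert np.allclose(r, ds.truth.r, atol=1e-12)

    def test_zero_effects_give_zero_response(self):
        cfg = SimConfig(n=40, p=60, k=10, t=5)
        rng = np.random.default_rng(0)
        s = _structure(cfg)
        X = generate_genotypes(s, cfg, rng)
        causal, groups = select_causal_groups(cfg, rng)
        truth = simulate_response(X, s, causal, groups, cfg, rng)
        truth.beta[:] = 0
        truth.gamma[:] = 0
        r = sum(epistatic_variable(X[:, g]).astype(float) * b
                for b, g in zip(truth.beta, truth.groups)) + s.G @ truth.gamma
        assert np.all(r == 0)

    def test_no_confounding_when_sigma_u2_zero(self):
        cfg = SimConfig(n=60, p=80, k=10, t=5, sigma_u2=0.0, seed=2)
        ds = simulate_dataset(cfg)
        assert np.all(ds.truth.gamma == 0)
        z = sum(epistatic_variable(ds.X[:, g]).astype(float) * b
                for b, g in zip(ds.truth.beta, ds.truth.groups))
        assert np.allclose(ds.truth.r, z)

    def test_r_depends_only_on_causal_columns(self):
        cfg = SimConfig(n=60, p=120, k=10, t=5, seed=4)
        ds = simulate_dataset(cfg)
        genetic = ds.truth.r - ds.structure.G @ ds.truth.gamma
        rng = np.random.default_rng(9)
        Xp = ds.X.copy()
        noncausal = np.setdiff1d(np.arange(cfg.p), ds.truth.causal_indices)
        Xp[:, noncausal] = Xp[:, rng.permutation(noncausal)]
        genetic_p = sum(epistatic_variable(Xp[:, g]).astype(float) * b
                        for b, g in zip(ds.truth.beta, ds.truth.groups))
        assert np.allclose(genetic, genetic_p)


class TestPhenotype:
    def test_binary_is_fair_coin_at_zero_response(self):
        from dmmgwas.simgen import SimTruth
        n = 100_000
        truth = SimTruth(np.array([0]), [np.array([0])], np.zeros(1),
                         np.zeros(1), np.zeros(n))
        y = simulate_phenotype(truth, "binary", np.random.default_rng(0))
        assert set(np.unique(y)) <= {0.0, 1.0}
        assert abs(y.mean() - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_binary_extreme_logit_underflow_safe(self):
        from dmmgwas.simgen import SimTruth
        truth = SimTruth(np.array([0]), [np.array([0])], np.zeros(1),
                         np.zeros(1), np.full(200, -50.0))
        y = simulate_phenotype(truth, "binary", np.random.default_rng(0))
        assert np.all(np.isfinite(y))
        assert np.all(y == 0)

    def test_binary_calibration_matches_logistic(self):
        from dmmgwas.simgen import SimTruth
        n = 100_000
        r = np.repeat([-2.0, -0.5, 0.7, 1.5], n // 4)
        truth = SimTruth(np.array([0]), [np.array([0])], np.zeros(1),
                         np.zeros(1), r)
        y = simulate_phenotype(truth, "binary", np.random.default_rng(3))
        for val in (-2.0, -0.5, 0.7, 1.5):
            m = y[r == val].mean()
            pr = expit(val)
            se = np.sqrt(pr * (1 - pr) / (n // 4))
            assert abs(m - pr) < 4 * se

    def test_continuous_noise_unit_variance(self):
        from dmmgwas.simgen import SimTruth
        n = 100_000
        truth = SimTruth(np.array([0]), [np.array([0])], np.zeros(1),
                         np.zeros(1), np.zeros(n))
        y = simulate_phenotype(truth, "continuous", np.random.default_rng(1))
        assert y.var() == pytest.approx(1.0, rel=0.02)

    def test_unknown_kind_rejected(self):
        from dmmgwas.simgen import SimTruth
        truth = SimTruth(np.array([0]), [np.array([0])], np.zeros(1),
                         np.zeros(1), np.zeros(5))
        with pytest.raises(ValueError):
            simulate_phenotype(truth, "ordinal", np.random.default_rng(0))


class TestDataset:
    def test_determinism(self):
        cfg = SimConfig(n=80, p=150, k=10, t=5, seed=11)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.truth.beta, b.truth.beta)
        assert np.array_equal(a.truth.causal_indices, b.truth.causal_indices)

    def test_paper_scale_shapes(self):
        ds = simulate_dataset(SimConfig(n=500, p=10_000, k=10, t=5, seed=0))
        assert ds.X.shape == (500, 10_000)
        assert ds.y.shape == (500,)
        assert len(ds.truth.groups) == 2
        assert ds.config.m == 2

    def test_continuous_residual_is_epsilon(self, small_dataset):
        ds = small_dataset
        assert np.allclose(ds.y - ds.truth.r, ds.truth.epsilon)

    def test_confounder_variance_scales_with_sigma_u2(self):
        def mean_var(sig):
            vs = []
            for seed in range(20):
                cfg = SimConfig(n=60, p=60, k=10, t=5, sigma_u2=sig, seed=seed)
                ds = simulate_dataset(cfg)
                vs.append((ds.structure.G @ ds.truth.gamma).var())
            return np.mean(vs)

        assert mean_var(10.0) > mean_var(5.0)
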