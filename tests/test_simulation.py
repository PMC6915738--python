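"""Distributional and structural checks of the generative models."""

import numpy as np
import pytest
from scipy import integrate, stats

from mreqtl.simulation import (
    GenotypeErrorModel,
    SimulationConfig,
    apply_genotyping_error,
    draw_allele_freqs,
    simulate_architecture,
    simulate_expression,
    simulate_genotypes,
    simulate_genotypes_ld,
    simulate_scenario,
)


def small_config(**kw):
    defaults = dict(n_snp=500, n_trs=500, n_sample=50, seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestAlleleFrequencies:
    def test_no_truncation_accepts_first_draws(self, rng):
        cfg = small_config(freq_min=1e-12, freq_max=1 - 1e-12, n_snp=2000)
        p = draw_allele_freqs(cfg, rng)
        assert len(p) == 2000

    def test_bounds_are_strict_and_mean_symmetric(self, rng):
        cfg = small_config(n_snp=100_000)
        p = draw_allele_freqs(cfg, rng)
        assert p.min() > 0.05 and p.max() < 0.95
        # Beta(0.7, 0.7) truncated symmetrically keeps mean 1/2
        assert abs(p.mean() - 0.5) < 4 * p.std() / np.sqrt(len(p))

    def test_truncation_mass_matches_quadrature_oracle(self, rng):
        # oracle: tail mass of the Beta(0.7, 0.7) density by quadrature
        pdf = lambda x: stats.beta.pdf(x, 0.7, 0.7)
        lo, _ = integrate.quad(pdf, 0, 0.05)
        hi, _ = integrate.quad(pdf, 0.95, 1)
        expected = lo + hi
        raw = rng.beta(0.7, 0.7, 100_000)
        outside = ((raw <= 0.05) | (raw >= 0.95)).mean()
        assert abs(outside - expected) < 4 * np.sqrt(expected * (1 - expected) / 100_000)


class TestGenotypes:
    def test_zero_frequency_gives_all_zero(self, rng):
        g = simulate_genotypes(np.zeros(10), 20, rng)
        assert not g.dosages.any()

    def test_support_and_hwe_mean(self, rng):
        g = simulate_genotypes(np.full(5, 0.3), 100_000, rng)
        assert set(np.unique(g.dosages)) <= {0, 1, 2}
        means = g.dosages.mean(axis=0)
        ci = 4 * np.sqrt(2 * 0.3 * 0.7 / 100_000)
        assert np.all(np.abs(means - 0.6) < ci)

    def test_ld_block_size_one_matches_marginals(self, rng):
        freqs = np.array([0.2, 0.5, 0.7])
        g = simulate_genotypes_ld(freqs, 200_000, 1, 0.8, rng)
        # HWE genotype frequencies preserved by the copula thresholds
        for j, p in enumerate(freqs):
            obs = np.bincount(g.dosages[:, j], minlength=3) / 200_000
            exp = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
            assert np.allclose(obs, exp, atol=0.01)

    def test_ld_correlation_matches_copula_oracle(self, rng):
        # brute-force oracle: the same thresholding applied to explicit
        # bivariate normal draws
        n = 10**6
        z1 = rng.standard_normal(n)
        z2 = 0.8 * z1 + np.sqrt(1 - 0.8**2) * rng.standard_normal(n)
        q0, q1 = stats.norm.ppf(0.25), stats.norm.ppf(0.75)  # p = 0.5
        d1 = (z1 > q0).astype(int) + (z1 > q1).astype(int)
        d2 = (z2 > q0).astype(int) + (z2 > q1).astype(int)
        oracle = np.corrcoef(d1, d2)[0, 1]

        g = simulate_genotypes_ld(np.full(2, 0.5), 100_000, 2, 0.8, rng)
        emp = np.corrcoef(g.dosages[:, 0], g.dosages[:, 1])[0, 1]
        assert abs(emp - oracle) < 0.02

    def test_ld_rho_zero_independent(self, rng):
        g = simulate_genotypes_ld(np.full(4, 0.4), 50_000, 4, 0.0, rng)
        c = np.corrcoef(g.dosages.T)
        off = c[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.02)

    def test_ld_rho_one_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_genotypes_ld(np.full(4, 0.4), 10, 2, 1.0, rng)


class TestGenotypingError:
    def test_identity_model_is_noop(self, rng):
        g = simulate_genotypes(np.full(20, 0.4), 50, rng)
        out = apply_genotyping_error(g, GenotypeErrorModel.identity(), rng)
        assert np.array_equal(out.dosages, g.dosages)

    def test_deterministic_row(self, rng):
        g = simulate_genotypes(np.full(20, 0.2), 50, rng)
        m = np.eye(3)
        m[0] = [0, 1, 0]  # every true 0 becomes observed 1
        out = apply_genotyping_error(g, GenotypeErrorModel(m), rng)
        assert np.all(out.dosages[g.dosages == 0] == 1)
        assert np.array_equal(out.dosages[g.dosages != 0], g.dosages[g.dosages != 0])

    def test_confusion_frequencies_match_model(self, rng):
        g = simulate_genotypes(np.full(2000, 0.5), 500, rng)  # 10^6 entries
        model = GenotypeErrorModel.default_microarray()
        out = apply_genotyping_error(g, model, rng)
        for true in range(3):
            sel = g.dosages == true
            n = sel.sum()
            obs = np.bincount(out.dosages[sel], minlength=3) / n
            ci = 5 * np.sqrt(model.matrix[true] * (1 - model.matrix[true]) / n + 1e-12)
            assert np.all(np.abs(obs - model.matrix[true]) <= ci + 1e-4)

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError):
            GenotypeErrorModel(np.full((3, 3), 0.5))


class TestArchitecture:
    def test_expected_trans_count_matches_beta_binomial_oracle(self):
        # analytic oracle: E[#trans] = n_snp * n_trs * a / (a + b)
        a, b = 0.0004, 10.0
        expected = 1000 * 1000 * a / (a + b)  # ~40.0
        counts = []
        for seed in range(200):
            cfg = SimulationConfig(
                n_snp=1000, n_trs=1000, n_sample=10, cis_prob=0.0, seed=seed
            )
            arch = simulate_architecture(cfg, np.random.default_rng(seed))
            counts.append(arch.n_eqtl)
        # the count distribution is heavy-tailed; allow a wide MC band
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 5 * se + 2

    def test_empty_architecture(self, rng):
        cfg = small_config(cis_prob=0.0, trans_shape_a=1e-300)
        arch = simulate_architecture(cfg, rng)
        assert arch.n_eqtl == 0

    def test_effect_tail_matches_normal_oracle(self):
        tail = []
        for seed in range(40):
            cfg = SimulationConfig(n_snp=2000, n_trs=2000, n_sample=10, seed=seed)
            arch = simulate_architecture(cfg, np.random.default_rng(seed))
            if arch.n_eqtl:
                tail.append((np.abs(arch.beta) >= 2).mean())
        expected = 2 * stats.norm.sf(2 / 1.15)
        assert abs(np.mean(tail) - expected) < 0.01

    def test_indicators_disjoint_and_beta_everywhere(self, rng):
        cfg = small_config(cis_prob=0.5)
        arch = simulate_architecture(cfg, rng)
        keys = arch.pair_keys()
        assert len(np.unique(keys)) == len(keys)  # cis/trans sets disjoint
        assert np.all(arch.beta != 0)
        assert arch.n_eqtl == len(arch.beta)

    def test_effect_distribution_ks(self):
        # nonzero effects should look N(0, sigma_beta^2); allow one failure
        # at alpha = 0.01 across 20 seeds
        fails = 0
        for seed in range(20):
            cfg = SimulationConfig(n_snp=3000, n_trs=3000, n_sample=10, seed=seed)
            arch = simulate_architecture(cfg, np.random.default_rng(seed))
            p = stats.kstest(arch.beta, "norm", args=(0, 1.15)).pvalue
            fails += p < 0.01
        assert fails <= 1


class TestExpression:
    def test_noiseless_zero_effects(self, rng):
        cfg = small_config(cis_prob=0.0, trans_shape_a=1e-300)
        arch = simulate_architecture(cfg, rng)
        g = simulate_genotypes(np.full(cfg.n_snp, 0.4), cfg.n_sample, rng)
        y = simulate_expression(g, arch, 1e-300, rng)
        assert np.allclose(y.values, 0.0)

    def test_noiseless_single_eqtl_identity(self, rng):
        cfg = small_config(n_snp=10, n_trs=10)
        arch = simulate_architecture(cfg, rng)
        arch.snp_idx = np.array([3])
        arch.feat_idx = np.array([7])
        arch.beta = np.array([1.5])
        arch.dom = np.array([0.0])
        arch.is_cis = np.array([False])
        arch.n_snp, arch.n_trs = 10, 10
        g = simulate_genotypes(np.full(10, 0.5), 40, rng)
        y = simulate_expression(g, arch, 1e-300, rng)
        assert np.allclose(y.values[:, 7], 1.5 * g.dosages[:, 3])
        assert np.allclose(y.values[:, :7], 0.0)

    def test_variance_decomposition_oracle(self, rng):
        # Var(Y_j) = sum_i beta_ij^2 * 2 p_i (1 - p_i) + sigma_eps^2
        p = np.array([0.3, 0.5, 0.7])
        betas = np.array([1.2, -0.8, 0.5])
        n = 200_000
        g = simulate_genotypes(p, n, rng)
        from mreqtl.simulation import EffectArchitecture

        arch = EffectArchitecture(
            3, 1, np.arange(3), np.zeros(3, dtype=int), betas,
            np.zeros(3), np.zeros(3, dtype=bool),
        )
        y = simulate_expression(g, arch, 1.0, rng)
        expected = float((betas**2 * 2 * p * (1 - p)).sum() + 1.0)
        assert abs(y.values[:, 0].var() / expected - 1) < 0.02

    def test_dominance_recoding(self, rng):
        from mreqtl.simulation import EffectArchitecture

        g = simulate_genotypes(np.full(1, 0.5), 200, rng)
        arch = EffectArchitecture(
            1, 1, np.zeros(1, dtype=int), np.zeros(1, dtype=int),
            np.array([2.0]), np.array([0.7]), np.zeros(1, dtype=bool),
        )
        y = simulate_expression(g, arch, 1e-300, rng)
        het = (g.dosages[:, 0] == 1).astype(float)
        assert np.allclose(y.values[:, 0], 2.0 * g.dosages[:, 0] + 0.7 * het)


class TestScenario:
    def test_fixed_seed_bit_reproducible(self):
        a = simulate_scenario(small_config(seed=7))
        b = simulate_scenario(small_config(seed=7))
        assert np.array_equal(a.genotypes_true.dosages, b.genotypes_true.dosages)
        assert np.array_equal(a.expression.values, b.expression.values)
        assert np.array_equal(a.architecture.beta, b.architecture.beta)

    def test_le_and_ge_share_architecture_and_expression(self):
        le = simulate_scenario(small_config(seed=3, scenario="LE"))
        ge = simulate_scenario(small_config(seed=3, scenario="GE"))
        assert np.array_equal(le.expression.values, ge.expression.values)
        assert np.array_equal(le.architecture.beta, ge.architecture.beta)
        assert not np.array_equal(
            ge.genotypes_analysed.dosages, ge.genotypes_true.dosages
        )
        assert np.array_equal(ge.genotypes_true.dosages, le.genotypes_true.dosages)

    def test_lv_uses_smaller_effect_sd(self):
        assert small_config(scenario="LV").resolved_sigma_beta == 0.85
        assert small_config(scenario="LE").resolved_sigma_beta == 1.15

    def test_swapped_truth_orientation_mirrors_roster(self):
        al = simulate_scenario(small_config(seed=5))
        sw = simulate_scenario(small_config(seed=5, truth_orientation="swapped"))
        assert np.array_equal(al.expression.values, sw.expression.values)
        assert np.array_equal(sw.architecture.snp_idx, al.architecture.feat_idx)
        assert np.array_equal(sw.architecture.feat_idx, al.architecture.snp_idx)
        # the cis diagonal is invariant under the swap
        cis = al.architecture.is_cis
        assert np.array_equal(
            al.architecture.pair_keys()[cis], np.sort(sw.architecture.pair_keys()[cis])
        ) or np.array_equal(
            al.architecture.pair_keys()[cis], sw.architecture.pair_keys()[cis]
        )

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(scenario="XX")
        with pytest.raises(ValueError):
            SimulationConfig(freq_min=0.9, freq_max=0.1)
        with pytest.raises(ValueError):
            SimulationConfig(scenario="LD", ld_rho=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_snp=10, n_trs=20, truth_orientation="swapped")
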