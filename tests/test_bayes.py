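import numpy as np
import pytest

import ssgp
from ssgp.bayes import (
    PriorSpec,
    build_ssbr_design,
    fit_bayes_regression,
    fit_ssbr,
    solve_ssbr_direct,
    summarize_posterior,
)
from ssgp.genotypes import GenotypeMatrix, allele_freqs
from ssgp.mixed_models import McmcSettings, PhenotypeTable, VarianceComponents
from ssgp.pedigree import build_nrm, partition_nrm

from conftest import make_pedigree


def ridge_solution(y, M_c, sigma_a2, sigma_e2):
    """Closed-form joint posterior mean of (mu, alpha) under the normal prior."""
    n = len(y)
    V = sigma_a2 * (M_c @ M_c.T) + sigma_e2 * np.eye(n)
    ones = np.ones(n)
    Vi = np.linalg.inv(V)
    mu = float(ones @ Vi @ y / (ones @ Vi @ ones))
    alpha = sigma_a2 * (M_c.T @ Vi @ (y - mu))
    return mu, alpha


class TestPriorSpec:
    def test_pi_one_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(family="C", pi=1.0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(family="A")


class TestBayesRegression:
    def test_conjugate_oracle_pi0(self):
        cfg = ssgp.SimConfig(
            n_founders=50, n_generations=2, matings_per_generation=75,
            offspring_per_mating=2, n_snps=300, h2=0.5, seed=41,
            genotyped_generations=frozenset({1, 2}),
        )
        b = ssgp.simulate_all(cfg)
        geno = b.genotypes
        phen = b.phenotypes.subset(geno.animal_ids.tolist())
        vc = VarianceComponents.from_h2(0.5, var_y=float(phen.y.var()))
        chain = McmcSettings(n_iter=12000, burn_in=2000, thin=4, seed=5)
        post = fit_bayes_regression(phen, geno, PriorSpec(family="C", pi=0.0), vc, chain)
        q = allele_freqs(geno)
        M_c = geno.codes - geno.codes.mean(axis=0)
        sa2 = vc.sigma_g2 / float(np.sum(2 * q * (1 - q)))
        mu, alpha = ridge_solution(phen.y, M_c, sa2, vc.sigma_e2)
        assert np.corrcoef(alpha, post.marker_effect_means)[0, 1] > 0.999
        assert np.corrcoef(M_c @ alpha, post.ebv)[0, 1] > 0.999
        assert post.mu == pytest.approx(mu, abs=0.1)

    def test_null_data_high_pi_low_inclusion(self):
        rng = np.random.default_rng(3)
        n, p = 300, 1000
        codes = rng.binomial(2, 0.5, size=(n, p)).astype(float)
        geno = GenotypeMatrix(
            codes, np.arange(1, n + 1), np.array([f"m{j}" for j in range(p)])
        )
        phen = PhenotypeTable(np.arange(1, n + 1), rng.standard_normal(n))
        vc = VarianceComponents.from_h2(0.3, var_y=1.0, fixed=False)
        chain = McmcSettings(n_iter=1500, burn_in=500, thin=2, seed=7)
        post = fit_bayes_regression(phen, geno, PriorSpec(family="C", pi=0.99), vc, chain)
        assert post.inclusion_probs.mean() <= 0.02

    def test_bayesb_recovers_planted_qtl(self):
        cfg = ssgp.SimConfig(
            n_founders=80, n_generations=2, matings_per_generation=150,
            offspring_per_mating=2, n_snps=500, n_chromosomes=5,
            chromosome_length_bp=20_000_000, h2=0.5, architecture="major_qtl",
            n_qtl=3, qtl_variance_fraction=0.3,
            genotyped_generations=frozenset({0, 1, 2}), seed=301,
        )
        b = ssgp.simulate_all(cfg)
        geno = b.genotypes
        phen = b.phenotypes.subset(geno.animal_ids.tolist())
        vc = VarianceComponents.from_h2(0.5, var_y=float(phen.y.var()), fixed=False)
        chain = McmcSettings(n_iter=3000, burn_in=1000, thin=2, seed=9)
        post = fit_bayes_regression(phen, geno, PriorSpec(family="B", pi=0.98), vc, chain)
        qtl = b.truth.qtl_positions
        thresh = np.quantile(post.inclusion_probs, 0.99)
        assert np.all(post.inclusion_probs[qtl] >= thresh)

    def test_seeded_determinism(self, small_bundle):
        geno = small_bundle.genotypes
        phen = small_bundle.phenotypes.subset(geno.animal_ids.tolist())
        vc = VarianceComponents.from_h2(0.5, var_y=float(phen.y.var()), fixed=False)
        chain = McmcSettings(n_iter=400, burn_in=100, thin=2, seed=11)
        p1 = fit_bayes_regression(phen, geno, PriorSpec(family="B", pi=0.9), vc, chain)
        p2 = fit_bayes_regression(phen, geno, PriorSpec(family="B", pi=0.9), vc, chain)
        np.testing.assert_array_equal(p1.marker_effect_means, p2.marker_effect_means)
        np.testing.assert_array_equal(p1.sigma_e2_chain, p2.sigma_e2_chain)

    def test_pi_recovery_bayescpi(self):
        rng = np.random.default_rng(13)
        n, p = 500, 2000
        codes = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        M_c = codes - codes.mean(axis=0)
        alpha = np.zeros(p)
        nz = rng.choice(p, size=int(0.02 * p), replace=False)
        alpha[nz] = rng.standard_normal(len(nz)) * 0.3
        g = M_c @ alpha
        y = g + rng.standard_normal(n) * g.std()
        geno = GenotypeMatrix(
            codes, np.arange(1, n + 1), np.array([f"m{j}" for j in range(p)])
        )
        phen = PhenotypeTable(np.arange(1, n + 1), y)
        vc = VarianceComponents.from_h2(0.5, var_y=float(y.var()), fixed=False)
        chain = McmcSettings(n_iter=2000, burn_in=800, thin=2, seed=15)
        post = fit_bayes_regression(
            phen, geno, PriorSpec(family="C", pi=0.5, estimate_pi=True), vc, chain
        )
        assert 0.9 <= post.pi_chain.mean() < 1.0

    def test_marker_permutation_equivariance(self, small_bundle):
        geno = small_bundle.genotypes
        phen = small_bundle.phenotypes.subset(geno.animal_ids.tolist())
        vc = VarianceComponents.from_h2(0.5, var_y=float(phen.y.var()))
        chain = McmcSettings(n_iter=6000, burn_in=2000, thin=2, seed=21)
        post1 = fit_bayes_regression(phen, geno, PriorSpec(family="C", pi=0.0), vc, chain)
        rng = np.random.default_rng(0)
        perm = rng.permutation(geno.n_markers)
        geno_p = GenotypeMatrix(
            geno.codes[:, perm], geno.animal_ids.copy(), geno.marker_ids[perm]
        )
        post2 = fit_bayes_regression(phen, geno_p, PriorSpec(family="C", pi=0.0), vc, chain)
        # the locus visit order ties RNG draws to column position, so the
        # match is statistical (posterior means agree within MCMC error)
        r = np.corrcoef(post1.marker_effect_means[perm], post2.marker_effect_means)[0, 1]
        assert r > 0.99

    def test_non_finite_phenotypes_rejected(self, small_bundle):
        geno = small_bundle.genotypes
        with pytest.raises(ValueError):
            PhenotypeTable(geno.animal_ids, np.full(geno.n_animals, np.nan))


class TestSsbrDesign:
    def test_printed_x_structure(self, small_design, small_partition):
        n_n = small_partition.n_nongenotyped
        np.testing.assert_array_equal(small_design.X[n_n:, 1], -1.0)
        np.testing.assert_array_equal(small_design.X[:, 0], 1.0)
        from ssgp.genotypes import chol_solve_jitter

        expect = -(
            small_partition.A_ng
            @ chol_solve_jitter(small_partition.A_gg, np.ones(small_partition.n_genotyped))
        )
        np.testing.assert_allclose(small_design.X[:n_n, 1], expect, atol=1e-10)

    def test_all_genotyped_degenerate(self, small_A, small_bundle):
        geno_all = small_bundle.genotypes_all
        part = partition_nrm(small_A, geno_all.animal_ids)
        design = build_ssbr_design(part, geno_all)
        assert design.epsilon_cov.shape == (0, 0)
        np.testing.assert_array_equal(design.X[:, 1], -1.0)
        np.testing.assert_array_equal(design.M, geno_all.codes)

    def test_unrelated_nongenotyped_row(self):
        ped = make_pedigree([(1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 1, 2)])
        A = build_nrm(ped)
        part = partition_nrm(A, [1, 2, 4])
        geno = GenotypeMatrix(
            np.array([[2.0, 0.0], [0.0, 2.0], [1.0, 1.0]]),
            np.array([1, 2, 4]),
            np.array(["m0", "m1"]),
        )
        design = build_ssbr_design(part, geno)
        # animal 3 is unrelated to every genotyped animal
        i = design.animal_ids.tolist().index(3)
        np.testing.assert_array_equal(design.M[i], 0.0)
        assert design.epsilon_cov[i, i] == pytest.approx(A.values[2, 2])

    def test_trio_epsilon_diag_is_mendelian_sampling_variance(self):
        ped = make_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
        A = build_nrm(ped)
        part = partition_nrm(A, [1, 2])
        geno = GenotypeMatrix(
            np.array([[2.0], [0.0]]), np.array([1, 2]), np.array(["m0"])
        )
        design = build_ssbr_design(part, geno)
        assert design.epsilon_cov[0, 0] == pytest.approx(0.5)

    def test_epsilon_cov_psd(self, small_design):
        assert np.linalg.eigvalsh(small_design.epsilon_cov).min() > -1e-8


class TestFitSsbr:
    def test_direct_solve_matches_h_gblup(self, small_bundle, small_partition, small_design):
        # with pi=0, family C and fixed variances the SSBR system is the
        # mixed model on H built from the unscaled marker GRM
        geno = small_bundle.genotypes
        q = allele_freqs(geno)
        k = float(np.sum(2 * q * (1 - q)))
        M_c = geno.codes - geno.codes.mean(axis=0)
        Gm = ssgp.RelationshipMatrix(M_c @ M_c.T / k, geno.animal_ids, "GRM")
        H = ssgp.build_h_matrix(small_partition, Gm)
        phen = small_bundle.phenotypes
        vc = VarianceComponents.from_h2(0.5, var_y=float(phen.y.var()))
        direct = solve_ssbr_direct(phen, small_design, vc)
        from ssgp.mixed_models import solve_mme

        obs = H.indices_of(phen.animal_ids)
        rows = np.array([small_design.row_index()[a] for a in phen.animal_ids])
        beta, u = solve_mme(phen.y, obs, H, vc, X=small_design.X[rows])
        np.testing.assert_allclose(
            u[H.indices_of(small_design.animal_ids)], direct.ebv, atol=1e-8
        )

    def test_mcmc_matches_direct_solution(self, small_bundle, small_design):
        phen = small_bundle.phenotypes
        vc = VarianceComponents.from_h2(0.5, var_y=float(phen.y.var()))
        direct = solve_ssbr_direct(phen, small_design, vc)
        post = fit_ssbr(
            phen,
            small_design,
            PriorSpec(family="C", pi=0.0),
            vc,
            McmcSettings(n_iter=12000, burn_in=2000, thin=4, seed=23),
        )
        assert np.corrcoef(post.ebv, direct.ebv)[0, 1] > 0.999

    def test_reduces_to_bayes_regression_when_all_genotyped(self, small_A, small_bundle):
        geno_all = small_bundle.genotypes_all
        part = partition_nrm(small_A, geno_all.animal_ids)
        design = build_ssbr_design(part, geno_all)
        phen = small_bundle.phenotypes
        vc = VarianceComponents.from_h2(0.5, var_y=float(phen.y.var()))
        chain = McmcSettings(n_iter=6000, burn_in=2000, thin=2, seed=31)
        post_ssbr = fit_ssbr(phen, design, PriorSpec(family="C", pi=0.0), vc, chain)
        post_gen = fit_bayes_regression(
            phen, geno_all, PriorSpec(family="C", pi=0.0), vc, chain
        )
        ebv_ssbr = post_ssbr.ebv_of(geno_all.animal_ids.tolist())
        assert np.corrcoef(ebv_ssbr, post_gen.ebv)[0, 1] > 0.995
        assert post_ssbr.mu_g is None  # collinear column dropped

    def test_missing_design_animal_rejected(self, small_design):
        phen = PhenotypeTable(np.array(["ghost"], dtype=object), np.array([1.0]))
        with pytest.raises(KeyError):
            solve_ssbr_direct(phen, small_design, VarianceComponents(1.0, 1.0))


class TestSummarizePosterior:
    def test_constant_chain(self):
        out = summarize_posterior({"x": np.full(10, 3.0)}, burn_in=2, thin=1)
        assert out["x"]["mean"] == pytest.approx(3.0)
        assert out["x"]["sd"] == pytest.approx(0.0)

    def test_plain_average(self):
        out = summarize_posterior({"x": np.arange(4.0)}, burn_in=0, thin=1)
        assert out["x"]["mean"] == pytest.approx(1.5)

    def test_inclusion_prob_of_excluded_marker(self):
        alpha = np.zeros((5, 3))
        alpha[:, 1] = 1.0
        out = summarize_posterior({"alpha": alpha}, burn_in=1, thin=1)
        np.testing.assert_array_equal(out["alpha"]["inclusion_prob"], [0.0, 1.0, 0.0])

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior({"x": np.arange(3.0)}, burn_in=5, thin=1)
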