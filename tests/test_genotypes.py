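import numpy as np
import pytest
from scipy.stats import chi2, chisquare

import ssgp
from ssgp.genotypes import (
    GenotypeMatrix,
    allele_freqs,
    build_grm,
    detect_conflicts,
    impute_nongenotyped,
    impute_sporadic_missing,
    qc_filter,
    reweight_grm,
    scale_grm,
)
from ssgp.pedigree import build_nrm, partition_nrm

from conftest import make_pedigree


def gm(codes, prefix="a"):
    codes = np.asarray(codes, dtype=float)
    return GenotypeMatrix(
        codes,
        np.array([f"{prefix}{i}" for i in range(codes.shape[0])]),
        np.array([f"m{j}" for j in range(codes.shape[1])]),
    )


class TestQc:
    def test_exact_hwe_retained(self):
        col = np.array([0] * 25 + [1] * 50 + [2] * 25)
        g = gm(col[:, None])
        kept, rep = qc_filter(g)
        row = rep.table.iloc[0]
        assert row.retained
        assert row.hwe_pvalue == pytest.approx(1.0)
        assert row.maf == pytest.approx(0.5)
        assert kept.n_markers == 1

    def test_het_deficit_removed_chi2_oracle(self):
        # 50 AA, 0 Aa, 50 aa: chi-square = n = 100 under HW expected counts
        col = np.array([0] * 50 + [2] * 50)
        g = gm(col[:, None])
        kept, rep = qc_filter(g)
        row = rep.table.iloc[0]
        assert not row.retained and row.fail_rule == "hwe"
        obs = [50, 0, 50]
        exp = [25, 50, 25]
        stat, _ = chisquare(obs, exp)
        assert stat == pytest.approx(100.0)
        assert row.hwe_pvalue == pytest.approx(chi2.sf(stat, df=1))
        assert row.hwe_pvalue < 1e-6

    def test_monomorphic_removed_under_maf(self):
        g = gm(np.zeros((30, 1)))
        kept, rep = qc_filter(g)
        assert kept.n_markers == 0
        assert rep.table.iloc[0].fail_rule == "maf"

    def test_all_missing_removed_under_missing_rule(self):
        g = gm(np.full((10, 1), np.nan))
        kept, rep = qc_filter(g)
        assert rep.table.iloc[0].fail_rule == "missing"
        assert rep.n_removed_missing == 1

    def test_first_failing_rule_attribution_counts(self):
        codes = np.column_stack(
            [
                np.array([0] * 25 + [1] * 50 + [2] * 25),  # clean
                np.concatenate([np.full(30, np.nan), np.tile([0, 1, 2], 24)[:70]]),  # missing
                np.zeros(100),  # maf
                np.array([0] * 50 + [2] * 50),  # hwe
            ]
        )
        _, rep = qc_filter(gm(codes))
        assert rep.n_input_markers == 4
        assert (
            rep.n_retained
            + rep.n_removed_missing
            + rep.n_removed_maf
            + rep.n_removed_hwe
            == 4
        )
        assert rep.n_removed_missing == 1
        assert rep.n_removed_maf == 1
        assert rep.n_removed_hwe == 1

    def test_idempotent(self, small_bundle):
        g = small_bundle.genotypes
        once, rep1 = qc_filter(g)
        twice, rep2 = qc_filter(once)
        np.testing.assert_array_equal(once.codes, twice.codes)
        assert rep2.n_retained == rep2.n_input_markers


class TestImputeMissing:
    def test_identity_when_complete(self, small_bundle):
        g = small_bundle.genotypes
        out = impute_sporadic_missing(g)
        np.testing.assert_array_equal(out.codes, g.codes)

    def test_mean_of_column(self):
        codes = np.array([[0.0], [2.0], [np.nan]])
        out = impute_sporadic_missing(gm(codes))
        assert out.codes[2, 0] == pytest.approx(1.0)

    def test_column_means_preserved(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, size=(50, 20)).astype(float)
        mask = rng.random(codes.shape) < 0.05
        missing = codes.copy()
        missing[mask] = np.nan
        out = impute_sporadic_missing(gm(missing))
        np.testing.assert_allclose(
            out.codes.mean(axis=0), np.nanmean(missing, axis=0), atol=1e-12
        )


class TestAlleleFreqs:
    def test_examples(self):
        assert allele_freqs(gm(np.array([[0.0], [1.0], [2.0]])))[0] == pytest.approx(0.5)
        assert allele_freqs(gm(np.full((4, 1), 2.0)))[0] == pytest.approx(1.0)

    def test_genedrop_frequency_binomial_oracle(self):
        # one generation bred from many founders: descendant allele counts are
        # close to binomial(2n, q); drift inflation is bounded by founder drift
        cfg = ssgp.SimConfig(
            n_founders=400, n_generations=1, matings_per_generation=1000,
            offspring_per_mating=2, n_snps=40, founder_maf_range=(0.3, 0.3),
            sires_per_generation=200, seed=21,
        )
        ped = ssgp.simulate_pedigree(cfg)
        geno, _ = ssgp.simulate_genotypes(ped, cfg)
        desc = geno.codes[ped.generation == 1]
        q_hat = desc.mean(axis=0) / 2.0
        n_desc = desc.shape[0]
        se_binom = np.sqrt(0.3 * 0.7 / (2 * n_desc))
        # founder sampling dominates the sampling error of the descendant mean
        se_founder = np.sqrt(0.3 * 0.7 / (2 * cfg.n_founders))
        se = np.sqrt(se_binom**2 + se_founder**2)
        assert np.all(np.abs(q_hat - 0.3) < 4 * se)
        assert abs(q_hat.mean() - 0.3) < 3 * se / np.sqrt(cfg.n_snps) + 3 * se_founder

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            allele_freqs(gm(np.full((3, 1), np.nan)))


class TestGrm:
    def test_hand_oracle_3x3(self):
        G = build_grm(gm(np.array([[0.0], [1.0], [2.0]])))
        expected = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        np.testing.assert_allclose(G.values, expected, atol=1e-12)

    def test_identical_animals_zero_matrix(self):
        G = build_grm(gm(np.ones((4, 5))))
        np.testing.assert_allclose(G.values, 0.0, atol=1e-12)

    def test_row_sums_zero_centering(self, small_bundle):
        G = build_grm(small_bundle.genotypes)
        np.testing.assert_allclose(G.values @ np.ones(G.n), 0.0, atol=1e-8)
        # mean offdiag = -mean diag/(n-1)
        n = G.n
        off = G.values[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(
            off.mean(), -np.diag(G.values).mean() / (n - 1), atol=1e-10
        )

    def test_monomorphic_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            build_grm(gm(np.vstack([np.zeros(3), np.zeros(3)])))


class TestScaleGrm:
    def test_identity_when_matching(self, small_bundle, small_partition):
        G = build_grm(small_bundle.genotypes)
        Gs = scale_grm(G, small_partition.A_gg)
        again = scale_grm(Gs, small_partition.A_gg)
        np.testing.assert_allclose(again.values, Gs.values, atol=1e-10)
        # means match A_gg exactly
        n = Gs.n
        off = ~np.eye(n, dtype=bool)
        assert np.diag(Gs.values).mean() == pytest.approx(
            np.diag(small_partition.A_gg).mean()
        )
        assert Gs.values[off].mean() == pytest.approx(small_partition.A_gg[off].mean())

    def test_means_match_target_exactly(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, size=(20, 60)).astype(float)
        G = build_grm(gm(codes))
        off = ~np.eye(20, dtype=bool)
        target = np.eye(20) * 1.05
        target[off] = 0.08
        Gs = scale_grm(G, target)
        assert np.diag(Gs.values).mean() == pytest.approx(1.05, abs=1e-12)
        assert Gs.values[off].mean() == pytest.approx(0.08, abs=1e-12)

    def test_zero_matrix_rejected(self):
        G = build_grm(gm(np.ones((4, 5))))  # all-identical animals -> zero G
        with pytest.raises(ZeroDivisionError):
            scale_grm(G, np.eye(4))

    def test_scaling_removes_centering_singularity(self):
        cfg = ssgp.SimConfig(
            n_founders=40, n_generations=2, matings_per_generation=80,
            offspring_per_mating=1, n_snps=500, seed=33,
        )
        b = ssgp.simulate_all(cfg)
        A = build_nrm(b.pedigree)
        part = partition_nrm(A, b.genotypes.animal_ids)
        G = build_grm(b.genotypes)
        assert np.linalg.eigvalsh(G.values).min() < 1e-10  # singular by centering
        Gs = scale_grm(G, part.A_gg)
        assert np.linalg.eigvalsh(Gs.values).min() > 0


class TestConflicts:
    def test_clean_simulation_no_duplicate_flags(self):
        cfg = ssgp.SimConfig(
            n_founders=50, n_generations=3, matings_per_generation=25,
            offspring_per_mating=2, n_snps=2000, n_chromosomes=5, seed=55,
            genotyped_generations=frozenset({0, 1, 2, 3}),
        )
        b = ssgp.simulate_all(cfg)
        A = build_nrm(b.pedigree)
        part = partition_nrm(A, b.genotypes.animal_ids)
        pairs, _ = detect_conflicts(build_grm(b.genotypes), part.A_gg)
        assert sum(1 for p in pairs if p.conflict_class == "DUPLICATE") == 0

    def test_planted_duplicate_flagged(self, small_bundle):
        g2, ped2, errs = ssgp.plant_conflicts(
            small_bundle.genotypes, small_bundle.pedigree, 1, 0, seed=3
        )
        A = build_nrm(ped2)
        part = partition_nrm(A, g2.animal_ids)
        pairs, summary = detect_conflicts(build_grm(g2), part.A_gg)
        dup_ids = {
            frozenset((p.id1, p.id2))
            for p in pairs
            if p.conflict_class == "DUPLICATE"
        }
        planted = errs[0]
        assert frozenset((planted.animal_id, planted.detail["source"])) in dup_ids


class TestImputeNongenotyped:
    def test_parent_average_trio(self):
        ped = make_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
        A = build_nrm(ped)
        part = ssgp.partition_nrm(A, [1, 2])
        M_g = GenotypeMatrix(np.array([[2.0], [0.0]]), np.array([1, 2]), np.array(["m0"]))
        imp = impute_nongenotyped(part, M_g)
        assert imp.values[0, 0] == pytest.approx(1.0)

    def test_unrelated_row_exactly_zero(self):
        ped = make_pedigree([(1, 0, 0), (2, 0, 0), (3, 0, 0)])
        A = build_nrm(ped)
        part = ssgp.partition_nrm(A, [1, 2])
        M_g = GenotypeMatrix(
            np.array([[2.0, 1.0], [0.0, 1.0]]), np.array([1, 2]), np.array(["m0", "m1"])
        )
        imp = impute_nongenotyped(part, M_g)
        np.testing.assert_array_equal(imp.values[0], 0.0)

    def test_selector_identity_for_genotyped_animal(self, small_bundle, small_A):
        # A_iG A_GG^-1 M_G with i inside the genotyped set returns i's codes
        g_ids = small_bundle.genotypes.animal_ids
        g_idx = small_A.indices_of(g_ids)
        A_gg = small_A.values[np.ix_(g_idx, g_idx)]
        M = small_bundle.genotypes.codes
        X = np.linalg.solve(A_gg, M)
        np.testing.assert_allclose(A_gg[3] @ X, M[3], atol=1e-8)

    def test_rows_invariant_to_genotyped_order(self, small_bundle, small_A):
        ids = small_bundle.genotypes.animal_ids.tolist()
        part1 = ssgp.partition_nrm(small_A, ids)
        imp1 = impute_nongenotyped(part1, small_bundle.genotypes)
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(ids))
        ids_p = [ids[k] for k in perm]
        part2 = ssgp.partition_nrm(small_A, ids_p)
        imp2 = impute_nongenotyped(part2, small_bundle.genotypes.subset_animals(ids_p))
        np.testing.assert_allclose(imp1.values, imp2.values, atol=1e-8)


class TestReweightGrm:
    def test_zero_ebv_uniform_weights(self, small_bundle, small_partition):
        G = scale_grm(build_grm(small_bundle.genotypes), small_partition.A_gg)
        Gw = reweight_grm(
            G,
            np.zeros(G.n),
            small_bundle.genotypes,
            n_iter=1,
            A_gg=small_partition.A_gg,
        )
        np.testing.assert_allclose(Gw.values, G.values, atol=1e-8)

    def test_qtl_markers_gain_weight(self, qtl_bundle):
        b = qtl_bundle
        A = build_nrm(b.pedigree)
        part = partition_nrm(A, b.genotypes.animal_ids)
        G = scale_grm(build_grm(b.genotypes), part.A_gg)
        vc = ssgp.VarianceComponents.from_h2(0.5, var_y=float(b.phenotypes.y.var()))
        fit = ssgp.fit_ssgblup(b.phenotypes, part, G, vc, variant="I")
        u_g = fit.ebv_of(part.genotyped_ids)
        # reproduce one weighting iteration to inspect the weights directly
        from ssgp.genotypes import chol_solve_jitter

        q = allele_freqs(b.genotypes)
        het = 2 * q * (1 - q)
        T = b.genotypes.codes - b.genotypes.codes.mean(axis=0)
        alpha = T.T @ chol_solve_jitter(G.values, u_g)
        w = alpha**2 * het
        w *= len(w) / w.sum()
        qtl = b.truth.qtl_positions
        non = np.setdiff1d(np.arange(len(w)), qtl)
        assert w[qtl].mean() > w[non].mean()
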