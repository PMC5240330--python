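import numpy as np
import pytest

import ssgp


@pytest.fixture(scope="session")
def small_bundle():
    """Polygenic bundle: 80 founders+offspring, last two generations genotyped."""
    cfg = ssgp.SimConfig(
        n_founders=20,
        n_generations=3,
        matings_per_generation=10,
        offspring_per_mating=2,
        n_snps=300,
        n_chromosomes=3,
        chromosome_length_bp=30_000_000,
        h2=0.5,
        seed=101,
        genotyped_generations=frozenset({2, 3}),
    )
    return ssgp.simulate_all(cfg)


@pytest.fixture(scope="session")
def qtl_bundle():
    """Major-QTL bundle: 3 QTL windows carrying 15% of genetic variance."""
    cfg = ssgp.SimConfig(
        n_founders=60,
        n_generations=3,
        matings_per_generation=60,
        offspring_per_mating=2,
        n_snps=600,
        n_chromosomes=5,
        chromosome_length_bp=20_000_000,
        h2=0.5,
        architecture="major_qtl",
        n_qtl=3,
        qtl_variance_fraction=0.15,
        seed=202,
        genotyped_generations=frozenset({2, 3}),
    )
    return ssgp.simulate_all(cfg)


@pytest.fixture(scope="session")
def small_A(small_bundle):
    return ssgp.build_nrm(small_bundle.pedigree)


@pytest.fixture(scope="session")
def small_partition(small_bundle, small_A):
    return ssgp.partition_nrm(small_A, small_bundle.genotypes.animal_ids)


@pytest.fixture(scope="session")
def small_design(small_bundle, small_partition):
    return ssgp.build_ssbr_design(small_partition, small_bundle.genotypes)


def make_pedigree(records):
    """records: (id, sire, dam) with 0 = unknown."""
    return ssgp.Pedigree.from_records(records, unknown=0)


@pytest.fixture(scope="session")
def fullsib_mating_pedigree():
    # founders 1,2; full sibs 3,4; animal 5 from the 3x4 full-sib mating
    return make_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4)])


def genedrop_ibd_relationship(pedigree, n_rep=20_000, seed=0):
    """Monte-Carlo oracle: additive relationships from gene-dropped IBD sharing.

    Independent of the tabular method: founders get unique allele labels,
    alleles drop with fair Mendelian sampling, and a_ij is estimated as twice
    the probability that random alleles from i and j are identical by descent.
    """
    rng = np.random.default_rng(seed)
    n = pedigree.n
    lab = np.zeros((n, 2, n_rep), dtype=np.int32)
    next_lab = 0
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        for slot, par in ((0, s), (1, d)):
            if par == -1:
                lab[i, slot] = next_lab
                next_lab += 1
            else:
                pick = rng.integers(0, 2, size=n_rep)
                lab[i, slot] = lab[par][pick, np.arange(n_rep)]
    def a_hat(i, j):
        tot = 0.0
        for si in range(2):
            for sj in range(2):
                tot += np.mean(lab[i, si] == lab[j, sj])
        return tot / 2.0
    return a_hat
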