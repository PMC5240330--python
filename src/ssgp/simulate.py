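"""Synthetic data generator: pedigrees, gene-dropped genotypes, traits.

Produces multi-generation pedigrees with discrete non-overlapping
generations, biallelic SNP genotypes dropped from Hardy-Weinberg founders by
Mendelian transmission (loci independent), phenotypes under either a dense
polygenic architecture or one with a few large QTL windows, genotyping masks
(only selected generations genotyped) and deliberately planted data errors
(duplicate genotypes under new IDs, parentage swaps) for testing conflict
detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MarkerMap
from .mixed_models import PhenotypeTable
from .pedigree import UNKNOWN, Pedigree

__all__ = [
    "SimConfig",
    "TrueValues",
    "SimBundle",
    "PlantedError",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "mask_genotypes",
    "plant_conflicts",
    "simulate_all",
    "write_bundle",
]


@dataclass(frozen=True)
class SimConfig:
    n_founders: int = 40
    n_generations: int = 4
    matings_per_generation: int = 20
    offspring_per_mating: int = 2
    n_snps: int = 1000
    n_chromosomes: int = 5
    chromosome_length_bp: int = 100_000_000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.5
    architecture: str = "polygenic"  # or "major_qtl"
    n_qtl: int = 0
    qtl_variance_fraction: float = 0.0
    genotyped_generations: frozenset = field(default_factory=frozenset)
    sires_per_generation: int | None = None  # half-sib family structure
    n_contemporary_groups: int = 0
    cg_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 < 1.0):
            raise ValueError("h2 must be in (0, 1)")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie within (0, 0.5]")
        if self.architecture not in ("polygenic", "major_qtl"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "major_qtl":
            if self.n_qtl < 1:
                raise ValueError("major_qtl architecture requires n_qtl >= 1")
            if not (0.0 < self.qtl_variance_fraction < 1.0):
                raise ValueError("qtl_variance_fraction must be in (0, 1)")
        if self.n_founders < 2 or self.n_generations < 1:
            raise ValueError("need n_founders >= 2 and n_generations >= 1")

    @property
    def pedigree_size(self) -> int:
        return self.n_founders + (
            self.n_generations * self.matings_per_generation * self.offspring_per_mating
        )


@dataclass
class TrueValues:
    true_breeding_values: np.ndarray  # per pedigree animal
    qtl_positions: np.ndarray  # marker column indices (empty when polygenic)
    qtl_effects: np.ndarray
    marker_effects: np.ndarray  # full per-marker effect vector
    sigma_g2_true: float
    sigma_e2_true: float


@dataclass
class PlantedError:
    kind: str  # "duplicate" | "parentage"
    animal_id: object
    detail: dict


@dataclass
class SimBundle:
    config: SimConfig
    pedigree: Pedigree
    genotypes_all: GenotypeMatrix
    genotypes: GenotypeMatrix  # masked to genotyped generations
    marker_map: MarkerMap
    phenotypes: PhenotypeTable
    truth: TrueValues

    @property
    def genotyped_ids(self) -> np.ndarray:
        return self.genotypes.animal_ids


def _sexes(n: int) -> np.ndarray:
    # alternate within a cohort: deterministic mating feasibility
    return np.arange(n) % 2  # 0 = male, 1 = female


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Discrete-generation random-mating pedigree; IDs are 1..N, founders first."""
    rng = np.random.default_rng(config.seed)
    ids, sire, dam, gen = [], [], [], []
    for i in range(config.n_founders):
        ids.append(i + 1)
        sire.append(UNKNOWN)
        dam.append(UNKNOWN)
        gen.append(0)
    prev_start, prev_n = 0, config.n_founders
    next_id = config.n_founders + 1
    for g in range(1, config.n_generations + 1):
        cohort = np.arange(prev_start, prev_start + prev_n)
        sex = _sexes(prev_n)
        males, females = cohort[sex == 0], cohort[sex == 1]
        if len(males) == 0 or len(females) == 0:
            raise ValueError(
                f"generation {g - 1} lacks a male or a female candidate; "
                "impossible mating design"
            )
        n_sires = config.sires_per_generation or max(1, config.matings_per_generation // 3)
        sire_pool = rng.choice(males, size=min(n_sires, len(males)), replace=False)
        start = len(ids)
        for m in range(config.matings_per_generation):
            s = int(rng.choice(sire_pool))
            d = int(rng.choice(females))
            for _ in range(config.offspring_per_mating):
                ids.append(next_id)
                next_id += 1
                sire.append(s)
                dam.append(d)
                gen.append(g)
        prev_start, prev_n = start, len(ids) - start
    return Pedigree(
        ids=np.array(ids),
        sire=np.array(sire),
        dam=np.array(dam),
        generation=np.array(gen),
    )


def _marker_map(config: SimConfig, rng: np.random.Generator) -> MarkerMap:
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    chroms, positions = [], []
    for c in range(config.n_chromosomes):
        k = int(per_chrom[c])
        pos = np.sort(
            rng.choice(np.arange(1, config.chromosome_length_bp + 1), size=k, replace=False)
        )
        chroms.append(np.full(k, c + 1))
        positions.append(pos)
    marker_ids = np.array([f"snp{j + 1}" for j in range(config.n_snps)])
    return MarkerMap(marker_ids, np.concatenate(chroms), np.concatenate(positions))


def simulate_genotypes(
    pedigree: Pedigree, config: SimConfig
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Gene-drop genotypes: HW founders, Mendelian transmission, unlinked loci."""
    rng = np.random.default_rng(config.seed + 1)
    marker_map = _marker_map(config, rng)
    lo, hi = config.founder_maf_range
    q = rng.uniform(lo, hi, size=config.n_snps)
    n, p = pedigree.n, config.n_snps
    codes = np.zeros((n, p), dtype=np.float64)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == UNKNOWN or d == UNKNOWN:
            codes[i] = rng.binomial(2, q)
        else:
            u = rng.random((2, p))
            pat = (codes[s] == 2) | ((codes[s] == 1) & (u[0] < 0.5))
            mat = (codes[d] == 2) | ((codes[d] == 1) & (u[1] < 0.5))
            codes[i] = pat.astype(np.float64) + mat.astype(np.float64)
    geno = GenotypeMatrix(codes, pedigree.ids.copy(), marker_map.marker_ids.copy())
    return geno, marker_map


def _window_index(marker_map: MarkerMap, window_bp: int = 1_000_000) -> np.ndarray:
    return marker_map.chromosome * 10_000_000 + marker_map.position_bp // window_bp


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    config: SimConfig,
    marker_map: MarkerMap | None = None,
) -> tuple[PhenotypeTable, TrueValues]:
    """Phenotypes as TBV + residual, scaled so the phenotypic variance is ~1.

    ``major_qtl`` places ``n_qtl`` effects in distinct 1-Mb windows carrying
    ``qtl_variance_fraction`` of the genetic variance; the remainder is a
    dense polygenic background.  TBVs use centered dosages.
    """
    if genotypes.n_animals != pedigree.n:
        raise ValueError("phenotype simulation needs the full pre-masking genotype matrix")
    rng = np.random.default_rng(config.seed + 2)
    p = genotypes.n_markers
    Z = genotypes.codes - genotypes.codes.mean(axis=0, keepdims=True)
    sigma_g2 = config.h2
    sigma_e2 = 1.0 - config.h2

    effects = np.zeros(p)
    if config.architecture == "polygenic":
        effects = rng.normal(size=p)
        tbv = Z @ effects
        sd = tbv.std()
        if sd == 0:
            raise ValueError("degenerate genotypes: zero genetic variance")
        effects *= np.sqrt(sigma_g2) / sd
        tbv = Z @ effects
        qtl_pos = np.array([], dtype=np.int64)
        qtl_eff = np.array([])
    else:
        if marker_map is None:
            raise ValueError("major_qtl architecture requires a marker map")
        win = _window_index(marker_map)
        windows = np.unique(win)
        if config.n_qtl > len(windows):
            raise ValueError("requested more QTL than distinct 1-Mb windows")
        # prefer common variants so a QTL actually segregates
        maf = np.minimum(genotypes.codes.mean(axis=0) / 2, 1 - genotypes.codes.mean(axis=0) / 2)
        chosen_windows = rng.choice(windows, size=config.n_qtl, replace=False)
        qtl_pos = []
        for w in chosen_windows:
            members = np.flatnonzero(win == w)
            good = members[maf[members] >= 0.1]
            pool = good if len(good) else members
            qtl_pos.append(int(rng.choice(pool)))
        qtl_pos = np.array(sorted(qtl_pos), dtype=np.int64)
        bg = np.setdiff1d(np.arange(p), qtl_pos)

        f = config.qtl_variance_fraction
        # each QTL carries an equal share of the QTL variance (random sign),
        # so every planted window is individually visible to the GWAS
        share = f * sigma_g2 / config.n_qtl
        for j in qtl_pos:
            sd_j = Z[:, j].std()
            if sd_j == 0:
                raise ValueError("selected QTL marker is monomorphic")
            effects[j] = rng.choice([-1.0, 1.0]) * np.sqrt(share) / sd_j
        raw_b = rng.normal(size=len(bg))
        g_b = Z[:, bg] @ raw_b
        cb = np.sqrt((1 - f) * sigma_g2) / g_b.std()
        effects[bg] = raw_b * cb
        qtl_eff = effects[qtl_pos].copy()
        tbv = Z @ effects

    resid = rng.normal(0.0, np.sqrt(sigma_e2), size=pedigree.n)
    y_adj = tbv + resid

    cg = None
    raw = None
    if config.n_contemporary_groups > 0:
        cg = rng.integers(0, config.n_contemporary_groups, size=pedigree.n)
        cg_eff = rng.normal(0.0, config.cg_effect_sd, size=config.n_contemporary_groups)
        raw = y_adj + cg_eff[cg]

    phenos = PhenotypeTable(
        animal_ids=pedigree.ids.copy(),
        y=y_adj,
        raw=raw,
        contemporary_group=cg,
    )
    truth = TrueValues(
        true_breeding_values=tbv,
        qtl_positions=qtl_pos,
        qtl_effects=qtl_eff if config.architecture == "major_qtl" else np.array([]),
        marker_effects=effects,
        sigma_g2_true=float(tbv.var()),
        sigma_e2_true=float(resid.var()),
    )
    return phenos, truth


def mask_genotypes(
    genotypes: GenotypeMatrix, pedigree: Pedigree, config: SimConfig
) -> GenotypeMatrix:
    """Restrict the genotype matrix to animals in ``genotyped_generations``."""
    gens = set(config.genotyped_generations)
    if not gens:
        raise ValueError("genotyped_generations must be non-empty")
    if pedigree.generation is None:
        raise ValueError("pedigree has no generation labels")
    keep = np.isin(pedigree.generation, list(gens))
    if not keep.any():
        raise ValueError("masking removed every genotyped animal")
    return GenotypeMatrix(
        genotypes.codes[keep], genotypes.animal_ids[keep], genotypes.marker_ids.copy()
    )


def plant_conflicts(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    n_duplicates: int,
    n_parentage_errors: int,
    seed: int,
) -> tuple[GenotypeMatrix, Pedigree, list[PlantedError]]:
    """Plant genotype duplicates under new unrelated IDs and parentage swaps.

    Duplicate: one genotyped animal's row is copied under a fresh ID recorded
    with unknown parents.  Parentage swap: a genotyped non-founder's sire is
    replaced in the pedigree by an unrelated male of the same generation.
    """
    rng = np.random.default_rng(seed)
    if n_duplicates == 0 and n_parentage_errors == 0:
        return genotypes, pedigree, []
    geno_set = set(genotypes.animal_ids.tolist())
    geno_idx_in_ped = pedigree.indices_of(genotypes.animal_ids)

    ids = pedigree.ids.tolist()
    sire = pedigree.sire.copy()
    dam = pedigree.dam.copy()
    gen = None if pedigree.generation is None else pedigree.generation.copy()
    errors: list[PlantedError] = []

    # parentage swaps first (pedigree indices stay valid)
    candidates = [
        int(i)
        for i in geno_idx_in_ped
        if sire[i] != UNKNOWN
        and np.sum(sire == sire[i]) >= 2  # true half/full sibs exist
    ]
    rng.shuffle(candidates)
    if len(candidates) < n_parentage_errors:
        raise ValueError("not enough eligible animals for parentage swaps")
    def ancestors(i: int) -> set:
        out, stack = set(), [i]
        while stack:
            k = stack.pop()
            for par in (sire[k], dam[k]):
                if par != UNKNOWN and par not in out:
                    out.add(int(par))
                    stack.append(int(par))
        return out

    used = set()
    n_done = 0
    for i in candidates:
        if n_done == n_parentage_errors:
            break
        true_s = int(sire[i])
        anc = ancestors(i)
        same_gen = [
            j
            for j in range(i)
            if j != true_s
            and j not in used
            and j not in anc  # keep the fake sire genuinely unrelated
            and sire[j] == UNKNOWN  # founders: unrelated by construction
            and np.sum(sire == j) >= 1  # fake sire has own offspring
        ]
        if not same_gen:
            continue
        fake_s = int(rng.choice(same_gen))
        sire[i] = fake_s
        used.add(fake_s)
        errors.append(
            PlantedError(
                kind="parentage",
                animal_id=ids[i],
                detail={"true_sire": ids[true_s], "fake_sire": ids[fake_s]},
            )
        )
        n_done += 1
    if n_done < n_parentage_errors:
        raise ValueError("could not place all requested parentage swaps")

    # duplicates: append new pedigree records + copied genotype rows
    dup_sources = rng.choice(
        np.array(sorted(geno_set, key=str), dtype=object), size=n_duplicates, replace=False
    )
    codes = genotypes.codes
    animal_ids = genotypes.animal_ids.tolist()
    numeric = all(isinstance(x, (int, np.integer)) for x in ids)
    next_id = (max(ids) + 1) if numeric else None
    for src in dup_sources:
        new_id = next_id if numeric else f"dup_{src}"
        if numeric:
            next_id += 1
        ids.append(new_id)
        sire = np.append(sire, UNKNOWN)
        dam = np.append(dam, UNKNOWN)
        if gen is not None:
            gen = np.append(gen, gen.max())
        row = codes[animal_ids.index(src)]
        codes = np.vstack([codes, row])
        animal_ids.append(new_id)
        errors.append(PlantedError(kind="duplicate", animal_id=new_id, detail={"source": src}))

    new_ped = Pedigree(
        ids=np.array(ids), sire=sire, dam=dam, generation=gen
    )
    new_geno = GenotypeMatrix(codes, np.array(animal_ids), genotypes.marker_ids.copy())
    return new_geno, new_ped, errors


def simulate_all(config: SimConfig) -> SimBundle:
    """Run the full generator: pedigree, genotypes, phenotypes, mask."""
    ped = simulate_pedigree(config)
    geno_all, marker_map = simulate_genotypes(ped, config)
    phenos, truth = simulate_phenotypes(geno_all, ped, config, marker_map)
    cfg = config
    if not config.genotyped_generations:
        cfg = replace(config, genotyped_generations=frozenset({config.n_generations}))
    masked = mask_genotypes(geno_all, ped, cfg)
    return SimBundle(cfg, ped, geno_all, masked, marker_map, phenos, truth)


def write_bundle(bundle: SimBundle, outdir) -> dict:
    """Write the bundle in the plain-text formats the readers consume."""
    from . import io as ssgp_io
    from .pedigree import write_pedigree_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "genotypes": outdir / "genotypes.raw",
        "map": outdir / "map.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.csv",
    }
    write_pedigree_csv(bundle.pedigree, paths["pedigree"])
    ssgp_io.write_genotypes_raw(bundle.genotypes, paths["genotypes"])
    ssgp_io.write_marker_map_csv(bundle.marker_map, paths["map"])
    ssgp_io.write_phenotypes_csv(bundle.phenotypes, paths["phenotypes"])
    pd.DataFrame(
        {"id": bundle.pedigree.ids, "tbv": bundle.truth.true_breeding_values}
    ).to_csv(paths["truth"], index=False)
    return paths
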