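"""Genotype QC, genomic relationship matrices and covariate imputation.

Covers marker quality control (missing rate, MAF, Hardy-Weinberg),
mean-imputation of sporadically missing calls, the centered genomic
relationship matrix G = TT' / sum(2 q (1-q)), its rescaling to the means of
A_gg, iterative SNP-effect reweighting of G, pedigree-vs-genomic conflict
detection, and imputation of SNP covariates for non-genotyped animals
(M_hat_n = A_ng A_gg^-1 M_g).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.stats import chi2

from .pedigree import NrmPartition, RelationshipMatrix

__all__ = [
    "GenotypeMatrix",
    "MarkerMap",
    "QcReport",
    "ImputedCovariates",
    "ConflictPair",
    "qc_filter",
    "impute_sporadic_missing",
    "allele_freqs",
    "build_grm",
    "scale_grm",
    "detect_conflicts",
    "impute_nongenotyped",
    "reweight_grm",
    "chol_solve_jitter",
]

log = logging.getLogger(__name__)

MISSING = -9  # sentinel used in integer storage; float storage uses NaN


@dataclass
class GenotypeMatrix:
    """Animals x markers dosage codes in {0,1,2}; NaN marks a missing call."""

    codes: np.ndarray
    animal_ids: np.ndarray
    marker_ids: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.float64)
        self.animal_ids = np.asarray(self.animal_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        n, p = self.codes.shape
        if len(self.animal_ids) != n or len(self.marker_ids) != p:
            raise ValueError("ID lists do not match genotype matrix dimensions")
        finite = self.codes[np.isfinite(self.codes)]
        # raw calls are 0/1/2; mean-imputed entries are reals inside [0, 2]
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            raise ValueError("genotype codes must lie in [0, 2] or be missing")

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def subset_animals(self, ids: Sequence) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.animal_ids.tolist())}
        idx = np.array([index[a] for a in ids], dtype=np.int64)
        return GenotypeMatrix(self.codes[idx], np.asarray(ids), self.marker_ids.copy())

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.codes[:, keep], self.animal_ids.copy(), self.marker_ids[keep]
        )


@dataclass
class MarkerMap:
    """Chromosome and bp position per marker; positions increase within chromosome."""

    marker_ids: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids)
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if not (len(self.marker_ids) == len(self.chromosome) == len(self.position_bp)):
            raise ValueError("marker map columns must have equal length")
        for c in np.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    def __len__(self) -> int:
        return len(self.marker_ids)

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.marker_ids[keep], self.chromosome[keep], self.position_bp[keep])


@dataclass
class QcReport:
    """Per-marker QC metrics plus removal counts (first-failing-rule attribution)."""

    table: pd.DataFrame  # marker, maf, missing_rate, hwe_pvalue, retained, fail_rule
    n_input_markers: int
    n_removed_missing: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained: int


@dataclass
class ImputedCovariates:
    """Real-valued SNP covariates for non-genotyped animals (M_hat_n)."""

    values: np.ndarray
    animal_ids: np.ndarray


@dataclass
class ConflictPair:
    id1: object
    id2: object
    a: float
    g: float
    conflict_class: str  # "DUPLICATE" | "PARENTAGE"


def allele_freqs(genotypes: GenotypeMatrix) -> np.ndarray:
    """Allele frequency q_i of the dosage-counted allele per marker."""
    codes = genotypes.codes
    n_obs = np.sum(np.isfinite(codes), axis=0)
    if np.any(n_obs == 0):
        raise ValueError("marker with all genotypes missing; run qc_filter first")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        sums = np.nansum(codes, axis=0)
    return sums / (2.0 * n_obs)


def _hwe_pvalues(codes: np.ndarray) -> np.ndarray:
    """1-df Pearson chi-square test of Hardy-Weinberg proportions per marker."""
    obs = np.isfinite(codes)
    n = obs.sum(axis=0).astype(float)
    n0 = ((codes == 0) & obs).sum(axis=0).astype(float)
    n1 = ((codes == 1) & obs).sum(axis=0).astype(float)
    n2 = ((codes == 2) & obs).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (n1 + 2 * n2) / (2 * n)
        e0, e1, e2 = n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2
        stat = np.zeros(codes.shape[1])
        for o, e in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
            stat += term
    pvals = chi2.sf(stat, df=1)
    pvals[n == 0] = np.nan
    # monomorphic markers fit HW proportions trivially
    pvals[(q == 0) | (q == 1)] = 1.0
    return pvals


def qc_filter(
    genotypes: GenotypeMatrix,
    hwe_p_min: float = 1e-6,
    maf_min: float = 0.01,
    missing_max: float = 0.1,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove markers failing missing-rate, MAF or HWE rules (evaluated in that order)."""
    if genotypes.n_animals < 1 or genotypes.n_markers < 1:
        raise ValueError("qc_filter requires at least one animal and one marker")
    codes = genotypes.codes
    n = genotypes.n_animals
    miss = np.sum(~np.isfinite(codes), axis=0) / n
    n_obs = n - np.sum(~np.isfinite(codes), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(n_obs > 0, np.nansum(codes, axis=0) / (2.0 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(q, 1 - q)
    hwe_p = _hwe_pvalues(codes)

    fail_rule = np.full(genotypes.n_markers, "", dtype=object)
    fail_missing = miss > missing_max
    fail_rule[fail_missing] = "missing"
    fail_maf = (maf < maf_min) & (fail_rule == "")
    fail_rule[fail_maf] = "maf"
    fail_hwe = (hwe_p < hwe_p_min) & (fail_rule == "")
    fail_rule[fail_hwe] = "hwe"
    retained = fail_rule == ""

    report = QcReport(
        table=pd.DataFrame(
            {
                "marker": genotypes.marker_ids,
                "maf": maf,
                "missing_rate": miss,
                "hwe_pvalue": hwe_p,
                "retained": retained,
                "fail_rule": fail_rule,
            }
        ),
        n_input_markers=genotypes.n_markers,
        n_removed_missing=int(fail_missing.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_retained=int(retained.sum()),
    )
    return genotypes.subset_markers(retained), report


def impute_sporadic_missing(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by its marker mean 2*q_hat (real-valued)."""
    codes = genotypes.codes.copy()
    missing = ~np.isfinite(codes)
    if missing.any():
        q = allele_freqs(genotypes)
        fill = np.broadcast_to(2.0 * q, codes.shape)
        codes[missing] = fill[missing]
    return GenotypeMatrix(codes, genotypes.animal_ids.copy(), genotypes.marker_ids.copy())


def _centered(codes: np.ndarray) -> np.ndarray:
    return codes - codes.mean(axis=0, keepdims=True)


def build_grm(genotypes: GenotypeMatrix, weights: np.ndarray | None = None) -> RelationshipMatrix:
    """Standard genomic relationship matrix G = T D T' / sum(2 q (1-q)).

    ``T`` is the column-centered dosage matrix; ``D`` optional marker weights
    (identity by default). Allele frequencies come from the supplied animals.
    """
    if genotypes.n_animals < 2:
        raise ValueError("build_grm requires at least two animals")
    if np.any(~np.isfinite(genotypes.codes)):
        raise ValueError("missing genotypes present; run impute_sporadic_missing first")
    q = allele_freqs(genotypes)
    denom = float(np.sum(2.0 * q * (1.0 - q)))
    if denom == 0.0:
        raise ZeroDivisionError("all markers monomorphic: zero denominator for G")
    T = _centered(genotypes.codes)
    if weights is None:
        G = T @ T.T / denom
    else:
        G = (T * weights) @ T.T / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(values=G, ids=genotypes.animal_ids.copy(), kind="GRM")


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def scale_grm(G: RelationshipMatrix, A_gg: np.ndarray) -> RelationshipMatrix:
    """Adjust G so its mean diagonal and mean off-diagonal equal those of A_gg.

    Uses the mean-matching transform ``G* = b G + a 11'`` (scale plus common
    shift), whose two coefficients are fixed exactly by the two mean
    constraints.  Because centering leaves the all-ones vector in G's null
    space, the rank-one shift restores it and removes that singularity.
    A per-class multiplicative rescale would flip off-diagonal signs whenever
    the off-diagonal means of G and A_gg differ in sign (which centering
    makes typical) and cannot repair the null space.
    """
    A_gg = np.asarray(A_gg, dtype=np.float64)
    if A_gg.shape != G.values.shape:
        raise ValueError("G and A_gg must have the same order")
    n = G.n
    V = G.values
    mean_dg, mean_da = np.diag(V).mean(), np.diag(A_gg).mean()
    if mean_dg == 0.0:
        raise ZeroDivisionError("mean diagonal of G is zero; cannot scale")
    if n == 1:
        out = V * (mean_da / mean_dg)
    else:
        off = _offdiag_mask(n)
        mean_og, mean_oa = V[off].mean(), A_gg[off].mean()
        if mean_dg == mean_og:
            raise ZeroDivisionError(
                "G has equal diagonal and off-diagonal means; mean-matching degenerate"
            )
        b = (mean_da - mean_oa) / (mean_dg - mean_og)
        a = mean_oa - b * mean_og
        out = b * V + a
    out = 0.5 * (out + out.T)
    return RelationshipMatrix(values=out, ids=G.ids.copy(), kind="GRM")


def detect_conflicts(
    G: RelationshipMatrix,
    A_gg: np.ndarray,
    dup_g_min: float = 0.9,
    dup_a_max: float = 0.1,
    rel_delta: float = 0.2,
) -> tuple[list[ConflictPair], dict]:
    """Flag NRM-vs-GRM conflicts among genotyped animals.

    DUPLICATE: g >= dup_g_min while a <= dup_a_max (same DNA, unrelated on
    paper).  PARENTAGE: |g - a| >= rel_delta with a or g near 0.25 (within
    rel_delta/2), the half-sib signature of a mis-recorded parent.

    Returns the flagged pairs and a summary dict with the off-diagonal
    NRM-GRM correlation before/after dropping all flagged animals.
    """
    A_gg = np.asarray(A_gg, dtype=np.float64)
    V = G.values
    if A_gg.shape != V.shape:
        raise ValueError("G and A_gg must be in matched order")
    n = G.n
    iu = np.triu_indices(n, k=1)
    g, a = V[iu], A_gg[iu]

    # duplicates score exactly 1 on the diagonal-normalized scale even when
    # the animal's own G diagonal drifts from 1 on a small marker panel
    d = np.diag(V)
    with np.errstate(invalid="ignore", divide="ignore"):
        g_norm = g / np.sqrt(np.maximum(d[iu[0]] * d[iu[1]], 1e-12))
    dup = (g_norm >= dup_g_min) & (a <= dup_a_max)
    near_quarter = (np.abs(a - 0.25) <= rel_delta / 2) | (np.abs(g - 0.25) <= rel_delta / 2)
    par = (~dup) & (np.abs(g - a) >= rel_delta) & near_quarter

    pairs: list[ConflictPair] = []
    for mask, label in ((dup, "DUPLICATE"), (par, "PARENTAGE")):
        for k in np.flatnonzero(mask):
            i, j = iu[0][k], iu[1][k]
            pairs.append(ConflictPair(G.ids[i], G.ids[j], float(a[k]), float(g[k]), label))

    corr_before = float(np.corrcoef(a, g)[0, 1]) if n > 2 else np.nan
    flagged_animals = sorted({p.id1 for p in pairs} | {p.id2 for p in pairs}, key=str)
    if flagged_animals and n - len(flagged_animals) > 2:
        keep = np.array([i for i, x in enumerate(G.ids) if x not in set(flagged_animals)])
        iu2 = np.triu_indices(len(keep), k=1)
        corr_after = float(
            np.corrcoef(A_gg[np.ix_(keep, keep)][iu2], V[np.ix_(keep, keep)][iu2])[0, 1]
        )
    else:
        corr_after = corr_before
    summary = {
        "corr_before": corr_before,
        "corr_after": corr_after,
        "flagged_animals": flagged_animals,
    }
    return pairs, summary


def chol_solve_jitter(M: np.ndarray, B: np.ndarray, jitter: float = 1e-8) -> np.ndarray:
    """Solve ``M X = B`` for symmetric PD ``M``, adding one diagonal jitter on failure."""
    try:
        c = sla.cho_factor(M, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        c = None
    if c is None:
        try:
            c = sla.cho_factor(
                M + jitter * np.eye(M.shape[0]), lower=True, check_finite=False
            )
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "matrix not positive definite even after diagonal jitter"
            ) from e
    return sla.cho_solve(c, B, check_finite=False)


def impute_nongenotyped(partition: NrmPartition, M_g: GenotypeMatrix) -> ImputedCovariates:
    """Pedigree-expected SNP covariates M_hat_n = A_ng A_gg^-1 M_g.

    Solved as a linear system; rows of A_ng that are all zero (non-genotyped
    animals unrelated to every genotyped animal) yield exactly zero rows.
    """
    if not np.array_equal(partition.genotyped_ids, M_g.animal_ids):
        raise ValueError("genotype rows must match the partition's genotyped ID order")
    X = chol_solve_jitter(partition.A_gg, M_g.codes)
    vals = partition.A_ng @ X
    zero_rows = ~np.any(partition.A_ng != 0.0, axis=1)
    vals[zero_rows] = 0.0
    return ImputedCovariates(values=vals, animal_ids=partition.nongenotyped_ids.copy())


def reweight_grm(
    G0: RelationshipMatrix,
    ebv_genotyped: np.ndarray,
    genotypes: GenotypeMatrix,
    n_iter: int,
    A_gg: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Iteratively reweighted GRM from SNP effects backsolved from EBVs.

    Each iteration: alpha = D T' G^-1 u, weights d_i proportional to
    alpha_i^2 * 2 q_i (1-q_i) normalized to sum to p, then
    G = T D T' / sum(2q(1-q)), rescaled to the means of ``A_gg`` when given.
    One iteration gives the first reweighted matrix, five the heavily
    reweighted variant.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    u = np.asarray(ebv_genotyped, dtype=np.float64)
    if u.shape[0] != G0.n:
        raise ValueError("EBV vector length must match G order")
    q = allele_freqs(genotypes)
    het = 2.0 * q * (1.0 - q)
    p = genotypes.n_markers
    T = _centered(genotypes.codes)
    G = G0
    D = np.ones(p)
    for _ in range(n_iter):
        Ginv_u = chol_solve_jitter(G.values, u)
        alpha = D * (T.T @ Ginv_u)
        w = alpha**2 * het
        if np.all(w == 0):
            log.warning("all backsolved SNP effects are zero; weights reset to uniform")
            D = np.ones(p)
        else:
            D = w * (p / w.sum())
        G = build_grm(genotypes, weights=D)
        if A_gg is not None:
            G = scale_grm(G, A_gg)
    return G


def write_qc_report_csv(report: QcReport, path) -> None:
    report.table.to_csv(path, index=False)


def write_conflicts_csv(pairs: list[ConflictPair], path) -> None:
    pd.DataFrame(
        [(p.id1, p.id2, p.a, p.g, p.conflict_class) for p in pairs],
        columns=["id1", "id2", "a", "g", "class"],
    ).to_csv(path, index=False)
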