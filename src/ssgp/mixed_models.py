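"""Linear mixed-model machinery for breeding-value prediction.

Provides the Henderson mixed-model solution for ``y = X beta + Z u + e`` with
``u ~ N(0, K sigma_g^2)`` (computed through the equivalent GLS form, which
also tolerates a singular K), pedigree BLUP, the combined pedigree/genomic
relationship matrix H, and single-step GBLUP with standard or iteratively
reweighted G.  Variance components can be held fixed or sampled by a Gibbs
chain with scaled-inverse-chi-square priors, run in the eigenbasis of the
observed-animal kernel so each sweep is O(n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg as sla

from .genotypes import GenotypeMatrix, chol_solve_jitter, reweight_grm
from .pedigree import NrmPartition, RelationshipMatrix

__all__ = [
    "PhenotypeTable",
    "VarianceComponents",
    "McmcSettings",
    "ModelFit",
    "solve_mme",
    "fit_pblup",
    "build_h_matrix",
    "fit_ssgblup",
    "gelman_rubin_split",
]

log = logging.getLogger(__name__)


@dataclass
class PhenotypeTable:
    """Single-trait, single-record phenotypes (already adjusted for fixed effects)."""

    animal_ids: np.ndarray
    y: np.ndarray
    raw: np.ndarray | None = None
    contemporary_group: np.ndarray | None = None
    age: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids)
        self.y = np.asarray(self.y, dtype=np.float64)
        if len(self.animal_ids) != len(self.y):
            raise ValueError("phenotype table: ID/value length mismatch")
        if len(set(self.animal_ids.tolist())) != len(self.animal_ids):
            raise ValueError("phenotype table: one record per animal required")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite phenotypes")

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, ids: Sequence) -> "PhenotypeTable":
        index = {a: i for i, a in enumerate(self.animal_ids.tolist())}
        idx = np.array([index[a] for a in ids], dtype=np.int64)
        return PhenotypeTable(
            animal_ids=self.animal_ids[idx],
            y=self.y[idx],
            raw=None if self.raw is None else self.raw[idx],
            contemporary_group=None
            if self.contemporary_group is None
            else self.contemporary_group[idx],
            age=None if self.age is None else self.age[idx],
        )


@dataclass
class VarianceComponents:
    """Genetic and residual variances plus their scaled-inverse-chi-square priors."""

    sigma_g2: float
    sigma_e2: float
    fixed: bool = True
    nu_g: float = 4.0
    S_g2: float | None = None
    nu_e: float = 4.0
    S_e2: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_g2 <= 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components must be positive")
        # default prior scales centre the prior on the starting values:
        # mode of nu*S^2/chi2_nu is nu S^2 / (nu + 2)
        if self.S_g2 is None:
            self.S_g2 = self.sigma_g2 * (self.nu_g + 2.0) / self.nu_g
        if self.S_e2 is None:
            self.S_e2 = self.sigma_e2 * (self.nu_e + 2.0) / self.nu_e

    @classmethod
    def from_h2(cls, h2: float, var_y: float = 1.0, fixed: bool = True, **kw):
        if not (0.0 < h2 < 1.0):
            raise ValueError("h2 must be in (0, 1)")
        return cls(sigma_g2=h2 * var_y, sigma_e2=(1.0 - h2) * var_y, fixed=fixed, **kw)

    @property
    def lam(self) -> float:
        return self.sigma_e2 / self.sigma_g2

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


@dataclass
class McmcSettings:
    n_iter: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def kept(self) -> int:
        return len(range(self.burn_in, self.n_iter, self.thin))


@dataclass
class ModelFit:
    method: str
    mu: float
    ebv: np.ndarray
    animal_ids: np.ndarray
    variance_components: VarianceComponents
    beta: np.ndarray | None = None
    chains: dict = field(default_factory=dict)

    def ebv_of(self, ids: Sequence) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.animal_ids.tolist())}
        return self.ebv[np.array([index[a] for a in ids], dtype=np.int64)]


def _as_matrix(K) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(K, RelationshipMatrix):
        return K.values, K.ids
    return np.asarray(K, dtype=np.float64), None


def solve_mme(
    y: np.ndarray,
    incidence: np.ndarray,
    K,
    vc: VarianceComponents,
    X: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the mixed-model equations for ``y = X beta + Z u + e``.

    ``incidence`` holds the row index in ``K`` of the animal behind each
    record (a 0/1 incidence Z).  Solutions are computed through the GLS form
    ``beta = (X'V^-1 X)^-1 X'V^-1 y``, ``u = sigma_g^2 K Z' V^-1 (y - X beta)``
    with ``V = sigma_g^2 Z K Z' + sigma_e^2 I``, which reproduces the MME
    solutions and stays defined for singular K.

    Returns ``(beta, u)`` with ``u`` covering every animal in ``K``.
    """
    Kv, _ = _as_matrix(K)
    y = np.asarray(y, dtype=np.float64)
    obs = np.asarray(incidence, dtype=np.int64)
    n = len(y)
    if len(obs) != n:
        raise ValueError("incidence length must match phenotype count")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=np.float64)
    K_oo = Kv[np.ix_(obs, obs)]
    V = vc.sigma_g2 * K_oo + vc.sigma_e2 * np.eye(n)
    Vi_X = chol_solve_jitter(V, X)
    Vi_y = chol_solve_jitter(V, y)
    XtViX = X.T @ Vi_X
    try:
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("fixed-effect block X'V^-1X is singular") from e
    r = y - X @ beta
    Vi_r = chol_solve_jitter(V, r)
    u = vc.sigma_g2 * (Kv[:, obs] @ Vi_r)
    return beta, u


def gelman_rubin_split(chain: np.ndarray) -> float:
    """Split-chain potential-scale-reduction diagnostic on a single chain."""
    x = np.asarray(chain, dtype=np.float64)
    m = len(x) // 2
    if m < 2:
        return np.nan
    halves = np.stack([x[:m], x[m : 2 * m]])
    w = halves.var(axis=1, ddof=1).mean()
    b = m * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (m - 1) / m * w + b / m
    return float(np.sqrt(var_plus / w))


def _gibbs_kernel_model(
    y: np.ndarray,
    K_oo: np.ndarray,
    X: np.ndarray,
    vc: VarianceComponents,
    chain: McmcSettings,
) -> dict:
    """Gibbs sampler for ``y = X beta + u_o + e`` with ``u_o ~ N(0, K_oo s_g^2)``.

    Runs in the eigenbasis of ``K_oo`` (one decomposition, O(n) sweeps).
    Returns posterior mean of the rotated genetic values and variance chains.
    """
    n = len(y)
    lam_eig, U = np.linalg.eigh(0.5 * (K_oo + K_oo.T))
    lam_eig = np.clip(lam_eig, 0.0, None)
    pos = lam_eig > 1e-10 * max(lam_eig.max(), 1.0)
    n_pos = int(pos.sum())
    y_rot = U.T @ y
    X_rot = U.T @ X
    f = X.shape[1]
    XtX = X.T @ X
    XtX_chol = sla.cho_factor(XtX + 1e-12 * np.eye(f))
    rng = np.random.default_rng(chain.seed)

    sg2, se2 = vc.sigma_g2, vc.sigma_e2
    beta = np.zeros(f)
    v = np.zeros(n)
    v_sum = np.zeros(n)
    beta_sum = np.zeros(f)
    sg2_chain, se2_chain = [], []
    kept = 0
    inv_lam = np.zeros(n)
    inv_lam[pos] = 1.0 / lam_eig[pos]

    for it in range(chain.n_iter):
        # v | rest : independent coordinates in the eigenbasis
        resid_rot = y_rot - X_rot @ beta
        c = 1.0 / (1.0 / se2 + inv_lam / sg2)
        c[~pos] = 0.0
        mean = c * resid_rot / se2
        v = mean + np.sqrt(c) * rng.standard_normal(n)
        v[~pos] = 0.0
        # beta | rest : flat prior
        rhs = X_rot.T @ (y_rot - v)
        bmean = sla.cho_solve(XtX_chol, rhs)
        L = np.linalg.cholesky(np.linalg.inv(XtX + 1e-12 * np.eye(f)) * se2)
        beta = bmean + L @ rng.standard_normal(f)
        if not vc.fixed:
            ss_g = float(np.sum(v[pos] ** 2 * inv_lam[pos]))
            sg2 = (ss_g + vc.nu_g * vc.S_g2) / rng.chisquare(vc.nu_g + n_pos)
            e_rot = y_rot - X_rot @ beta - v
            ss_e = float(e_rot @ e_rot)
            se2 = (ss_e + vc.nu_e * vc.S_e2) / rng.chisquare(vc.nu_e + n)
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            kept += 1
            v_sum += v
            beta_sum += beta
            sg2_chain.append(sg2)
            se2_chain.append(se2)

    sg2_chain = np.array(sg2_chain)
    se2_chain = np.array(se2_chain)
    v_mean = v_sum / kept
    out = {
        "u_obs": U @ v_mean,
        # K_oo^-1 u_obs in the eigenbasis (range-restricted pseudo-inverse)
        "Kinv_u_obs": U @ (inv_lam * v_mean),
        "beta": beta_sum / kept,
        "sigma_g2_chain": sg2_chain,
        "sigma_e2_chain": se2_chain,
    }
    if not vc.fixed:
        rhat = gelman_rubin_split(sg2_chain)
        log.info(
            "variance Gibbs: posterior mean sg2=%.4f se2=%.4f, split-Rhat(sg2)=%.3f",
            sg2_chain.mean(),
            se2_chain.mean(),
            rhat,
        )
        out["rhat_sigma_g2"] = rhat
    return out


def _fit_kernel_blup(
    method: str,
    phenos: PhenotypeTable,
    K: RelationshipMatrix,
    vc: VarianceComponents,
    chain: McmcSettings | None,
) -> ModelFit:
    obs = K.indices_of(phenos.animal_ids)
    y = phenos.y
    if vc.fixed:
        beta, u = solve_mme(y, obs, K, vc)
        return ModelFit(
            method=method,
            mu=float(beta[0]),
            ebv=u,
            animal_ids=K.ids.copy(),
            variance_components=vc,
            beta=beta,
        )
    chain = chain or McmcSettings(n_iter=6000, burn_in=2000, thin=2)
    K_oo = K.values[np.ix_(obs, obs)]
    X = np.ones((len(y), 1))
    res = _gibbs_kernel_model(y, K_oo, X, vc, chain)
    # propagate posterior-mean genetic values to unobserved animals
    u_all = K.values[:, obs] @ res["Kinv_u_obs"]
    u_all[obs] = res["u_obs"]
    vc_post = VarianceComponents(
        sigma_g2=float(res["sigma_g2_chain"].mean()),
        sigma_e2=float(res["sigma_e2_chain"].mean()),
        fixed=False,
        nu_g=vc.nu_g,
        S_g2=vc.S_g2,
        nu_e=vc.nu_e,
        S_e2=vc.S_e2,
    )
    return ModelFit(
        method=method,
        mu=float(res["beta"][0]),
        ebv=u_all,
        animal_ids=K.ids.copy(),
        variance_components=vc_post,
        beta=res["beta"],
        chains={
            "sigma_g2": res["sigma_g2_chain"],
            "sigma_e2": res["sigma_e2_chain"],
            "h2": res["sigma_g2_chain"] / (res["sigma_g2_chain"] + res["sigma_e2_chain"]),
        },
    )


def fit_pblup(
    phenos: PhenotypeTable,
    A: RelationshipMatrix,
    vc: VarianceComponents,
    genotyped_only: bool = False,
    genotyped_ids: Sequence | None = None,
    chain: McmcSettings | None = None,
) -> ModelFit:
    """Pedigree BLUP; with ``genotyped_only`` records shrink to genotyped animals."""
    if genotyped_only:
        if genotyped_ids is None:
            raise ValueError("genotyped_only requires genotyped_ids")
        keep = set(np.asarray(genotyped_ids).tolist())
        ids = [a for a in phenos.animal_ids.tolist() if a in keep]
        if not ids:
            raise ValueError("empty training set after restricting to genotyped animals")
        phenos = phenos.subset(ids)
        method = "PBLUP-G"
    else:
        method = "PBLUP"
    if len(phenos) == 0:
        raise ValueError("empty training set")
    return _fit_kernel_blup(method, phenos, A, vc, chain)


def build_h_matrix(partition: NrmPartition, G: RelationshipMatrix) -> RelationshipMatrix:
    """Combined relationship matrix H (non-genotyped block first, then genotyped).

    H_gg = G, H_ng = A_ng A_gg^-1 G, and
    H_nn = A_ng A_gg^-1 G A_gg^-1 A_gn + (A_nn - A_ng A_gg^-1 A_gn).
    """
    if not np.array_equal(np.asarray(G.ids), np.asarray(partition.genotyped_ids)):
        raise ValueError("G ID order must equal the partition's genotyped ID order")
    A_gg, A_ng, A_gn, A_nn = partition.A_gg, partition.A_ng, partition.A_gn, partition.A_nn
    # P = A_ng A_gg^-1, via A_gg X = A_gn  =>  X = A_gg^-1 A_gn, P = X'
    Xs = chol_solve_jitter(A_gg, A_gn)
    P = Xs.T
    PG = P @ G.values
    H_nn = PG @ P.T + (A_nn - P @ A_gn)
    n_n, n_g = partition.n_nongenotyped, partition.n_genotyped
    H = np.empty((n_n + n_g, n_n + n_g))
    H[:n_n, :n_n] = 0.5 * (H_nn + H_nn.T)
    H[:n_n, n_n:] = PG
    H[n_n:, :n_n] = PG.T
    H[n_n:, n_n:] = G.values
    ids = np.concatenate([partition.nongenotyped_ids, partition.genotyped_ids])
    return RelationshipMatrix(values=H, ids=ids, kind="H")


def fit_ssgblup(
    phenos: PhenotypeTable,
    partition: NrmPartition,
    G: RelationshipMatrix,
    vc: VarianceComponents,
    variant: str = "I",
    chain: McmcSettings | None = None,
    genotypes: GenotypeMatrix | None = None,
) -> ModelFit:
    """Single-step GBLUP on H; variants II/III reweight G from the variant-I fit.

    ``G`` should already be scaled to the A_gg means.  Variants II and III
    backsolve SNP effects from the variant-I genotyped EBVs and rebuild G
    with 1 or 5 reweighting iterations (``genotypes`` required).
    """
    variant = str(variant).upper()
    if variant not in ("I", "II", "III"):
        raise ValueError("variant must be I, II or III")
    H = build_h_matrix(partition, G)
    fit1 = _fit_kernel_blup("SSGBLUP-I", phenos, H, vc, chain)
    if variant == "I":
        return fit1
    if genotypes is None:
        raise ValueError("variants II/III require the genotype matrix for reweighting")
    n_iter = 1 if variant == "II" else 5
    u_g = fit1.ebv_of(partition.genotyped_ids)
    G_w = reweight_grm(G, u_g, genotypes, n_iter=n_iter, A_gg=partition.A_gg)
    H_w = build_h_matrix(partition, G_w)
    fit = _fit_kernel_blup(f"SSGBLUP-{variant}", phenos, H_w, vc, chain)
    return fit
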