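"""Gibbs samplers for whole-genome regression and its single-step extension.

Marker effects get a spike-and-slab prior: zero with probability ``pi``,
otherwise a normal with a locus-specific variance (family "B", marginally a
t-distribution) or one common variance (family "C"); ``pi`` itself can be
sampled under a uniform prior.  The single-step extension adds records on
non-genotyped animals through imputed covariates ``M_hat_n = A_ng A_gg^-1
M_g``, an imputation residual ``eps ~ N(0, (A_nn - A_ng A_gg^-1 A_gn)
sigma_g^2)`` sampled as a block in the eigenbasis of its covariance, and a
genotyped-vs-non-genotyped location shift ``mu_g``.

The per-locus sweep is compiled with numba; marker covariates are centered
on genotyped-animal means internally (location shifts are absorbed by the
fixed effects and cancel in correlation-based accuracies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genotypes import GenotypeMatrix, allele_freqs, impute_nongenotyped
from .mixed_models import McmcSettings, PhenotypeTable, VarianceComponents
from .pedigree import NrmPartition

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "SsbrDesign",
    "PosteriorSummary",
    "fit_bayes_regression",
    "build_ssbr_design",
    "fit_ssbr",
    "solve_ssbr_direct",
    "summarize_posterior",
    "PI_GRID",
]

log = logging.getLogger(__name__)

# search grid for the highest-accuracy pi workflow
PI_GRID = (0.9999, 0.999, 0.995, 0.99, 0.98) + tuple(
    round(0.95 - 0.05 * k, 2) for k in range(8)
)


@dataclass
class PriorSpec:
    """Mixture prior on marker effects.

    family "B": locus-specific effect variances; "C": one common variance.
    ``pi`` is the prior probability of a zero effect; with ``estimate_pi``
    it is only the initial value and is sampled from its Beta full
    conditional under a uniform prior.
    """

    family: str = "C"
    pi: float = 0.0
    estimate_pi: bool = False
    nu_alpha: float = 4.2
    S_alpha2: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("B", "C"):
            raise ValueError("family must be 'B' or 'C'")
        if not (0.0 <= self.pi < 1.0):
            raise ValueError("pi must be in [0, 1); pi=1 excludes every marker a priori")

    def label(self) -> str:
        if self.estimate_pi:
            return f"Bayes{self.family}pi"
        return f"Bayes{self.family}(pi={self.pi})"


@dataclass
class SsbrDesign:
    """Design pieces for single-step Bayesian regression.

    Row order is non-genotyped animals first, then genotyped (matching the H
    matrix).  ``X`` is the printed fixed-effect design ``[1, -A_ng A_gg^-1 1]``
    over non-genotyped rows and ``[1, -1]`` over genotyped rows; ``M`` the
    stacked ``[M_hat_n; M_g]`` covariates; ``epsilon_cov`` the imputation
    residual covariance ``A_nn - A_ng A_gg^-1 A_gn``.
    """

    animal_ids: np.ndarray
    is_genotyped: np.ndarray
    X: np.ndarray
    M: np.ndarray
    M_centered: np.ndarray
    epsilon_cov: np.ndarray
    sum_2pq: float
    marker_ids: np.ndarray

    @property
    def n_nongenotyped(self) -> int:
        return int((~self.is_genotyped).sum())

    @property
    def n_markers(self) -> int:
        return self.M.shape[1]

    def row_index(self) -> dict:
        return {a: i for i, a in enumerate(self.animal_ids.tolist())}


@dataclass
class PosteriorSummary:
    method: str
    animal_ids: np.ndarray
    ebv: np.ndarray
    marker_effect_means: np.ndarray
    inclusion_probs: np.ndarray
    mu: float
    mu_g: float | None = None
    pi_chain: np.ndarray | None = None
    sigma_e2_chain: np.ndarray | None = None
    sigma_g2_chain: np.ndarray | None = None
    genvar_chain: np.ndarray | None = None
    alpha_draws: np.ndarray | None = None  # kept x p, only when requested
    marker_ids: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def h2_chain(self) -> np.ndarray | None:
        if self.genvar_chain is None or self.sigma_e2_chain is None:
            return None
        return self.genvar_chain / (self.genvar_chain + self.sigma_e2_chain)

    def ebv_of(self, ids) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.animal_ids.tolist())}
        return self.ebv[np.array([index[a] for a in ids], dtype=np.int64)]


@njit(cache=True)
def _nb_seed(seed):  # numba keeps its own RNG state for jitted code
    np.random.seed(seed)


@njit(cache=True)
def _marker_sweep(
    W, wtw, r, alpha, delta, locus_var, common_var, pi, se2,
    family_b, nu_a, S_a2, sample_locus_var,
):
    """One single-site Gibbs sweep over loci; updates alpha/delta/r in place.

    Returns (number included, sum of squared included effects).
    """
    n, p = W.shape
    n_incl = 0
    ssq = 0.0
    for j in range(p):
        xx = wtw[j]
        aj_old = alpha[j]
        if xx <= 1e-12:
            alpha[j] = 0.0
            delta[j] = 0
            continue
        rhs = xx * aj_old
        for i in range(n):
            rhs += W[i, j] * r[i]
        vj = locus_var[j] if family_b else common_var
        include = True
        if pi > 0.0:
            v0 = xx * se2
            v1 = v0 + xx * xx * vj
            log_bf = -0.5 * (np.log(v1 / v0) + rhs * rhs * (1.0 / v1 - 1.0 / v0))
            h = np.log(pi / (1.0 - pi)) - log_bf
            if h > 35.0:
                p_incl = 0.0
            elif h < -35.0:
                p_incl = 1.0
            else:
                p_incl = 1.0 / (1.0 + np.exp(h))
            include = np.random.random() < p_incl
        if include:
            denom = xx + se2 / vj
            mean = rhs / denom
            sd = np.sqrt(se2 / denom)
            aj = mean + sd * np.random.normal(0.0, 1.0)
            delta[j] = 1
            n_incl += 1
            ssq += aj * aj
        else:
            aj = 0.0
            delta[j] = 0
        diff = aj_old - aj
        if diff != 0.0:
            for i in range(n):
                r[i] += W[i, j] * diff
        alpha[j] = aj
        if family_b and sample_locus_var:
            if delta[j] == 1:
                locus_var[j] = (nu_a * S_a2 + alpha[j] * alpha[j]) / np.random.chisquare(
                    nu_a + 1.0
                )
            else:
                locus_var[j] = (nu_a * S_a2) / np.random.chisquare(nu_a)
    return n_incl, ssq


def _default_marker_variance(prior: PriorSpec, vc: VarianceComponents, sum_2pq: float) -> float:
    if prior.S_alpha2 is not None:
        # scaled-inv-chi2 prior mean nu*S/(nu-2)
        return prior.S_alpha2 * prior.nu_alpha / max(prior.nu_alpha - 2.0, 1e-6)
    frac = max(1.0 - prior.pi, 1e-4)
    return vc.sigma_g2 / (frac * sum_2pq)


def _scale_from_mean(mean_var: float, nu: float) -> float:
    return mean_var * max(nu - 2.0, 1e-6) / nu


class _MixtureState:
    """Shared marker-mixture Gibbs state for genotyped-only and single-step fits."""

    def __init__(self, W, prior: PriorSpec, vc: VarianceComponents, sum_2pq, seed):
        self.W = np.asfortranarray(W)
        self.wtw = np.einsum("ij,ij->j", W, W)
        p = W.shape[1]
        self.alpha = np.zeros(p)
        self.delta = np.zeros(p, dtype=np.int64)
        self.pi = prior.pi
        var0 = _default_marker_variance(prior, vc, sum_2pq)
        self.common_var = var0
        self.locus_var = np.full(p, var0)
        self.nu_a = prior.nu_alpha
        self.S_a2 = (
            prior.S_alpha2
            if prior.S_alpha2 is not None
            else _scale_from_mean(var0, prior.nu_alpha)
        )
        self.family_b = prior.family == "B"
        self.prior = prior
        _nb_seed(seed)

    def sweep(self, r, se2, sample_vars: bool) -> tuple[int, float]:
        return _marker_sweep(
            self.W,
            self.wtw,
            r,
            self.alpha,
            self.delta,
            self.locus_var,
            self.common_var,
            self.pi,
            se2,
            self.family_b,
            self.nu_a,
            self.S_a2,
            sample_vars,
        )

    def update_hyper(self, rng, n_incl, ssq, sample_vars: bool) -> None:
        p = len(self.alpha)
        if sample_vars and not self.family_b:
            self.common_var = (ssq + self.nu_a * self.S_a2) / rng.chisquare(
                self.nu_a + n_incl
            )
        if self.prior.estimate_pi:
            self.pi = rng.beta(p - n_incl + 1.0, n_incl + 1.0)


def _update_flat_coeffs(X, coeffs, r, se2, rng) -> None:
    """Single-site draws for flat-prior fixed-effect coefficients."""
    for k in range(X.shape[1]):
        x = X[:, k]
        xx = float(x @ x)
        if xx <= 0.0:
            continue
        old = coeffs[k]
        rhs = float(x @ r) + xx * old
        new = rhs / xx + np.sqrt(se2 / xx) * rng.standard_normal()
        r += x * (old - new)
        coeffs[k] = new


def fit_bayes_regression(
    y_genotyped: PhenotypeTable,
    M_g: GenotypeMatrix,
    prior: PriorSpec,
    vc: VarianceComponents,
    chain: McmcSettings,
    store_draws: bool = False,
) -> PosteriorSummary:
    """BayesB / BayesC / BayesC-pi on genotyped animals only.

    Phenotyped animals must be a subset of the genotype matrix rows; EBVs
    are returned for every genotyped animal (training and not).
    """
    index = {a: i for i, a in enumerate(M_g.animal_ids.tolist())}
    try:
        rows = np.array([index[a] for a in y_genotyped.animal_ids], dtype=np.int64)
    except KeyError as e:
        raise KeyError(f"phenotyped animal {e.args[0]!r} has no genotype row") from None
    q = allele_freqs(M_g)
    sum_2pq = float(np.sum(2.0 * q * (1.0 - q)))
    M_c = M_g.codes - M_g.codes.mean(axis=0, keepdims=True)
    W = M_c[rows]
    y = y_genotyped.y.copy()
    n = len(y)

    rng = np.random.default_rng(chain.seed + 1)
    state = _MixtureState(W, prior, vc, sum_2pq, chain.seed)
    se2 = vc.sigma_e2
    mu = np.array([float(y.mean())])
    r = y - mu[0]
    ones = np.ones((n, 1))

    p = state.W.shape[1]
    kept = 0
    alpha_sum = np.zeros(p)
    incl_sum = np.zeros(p)
    pi_chain, se2_chain, genvar_chain = [], [], []
    draws = [] if store_draws else None
    mu_sum = 0.0

    for it in range(chain.n_iter):
        sample_vars = not vc.fixed
        n_incl, ssq = state.sweep(r, se2, sample_vars)
        _update_flat_coeffs(ones, mu, r, se2, rng)
        state.update_hyper(rng, n_incl, ssq, sample_vars)
        if sample_vars:
            se2 = (float(r @ r) + vc.nu_e * vc.S_e2) / rng.chisquare(vc.nu_e + n)
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            kept += 1
            alpha_sum += state.alpha
            incl_sum += state.delta
            mu_sum += mu[0]
            pi_chain.append(state.pi)
            se2_chain.append(se2)
            g_all = M_c @ state.alpha
            genvar_chain.append(float(g_all.var()))
            if store_draws:
                draws.append(state.alpha.copy())

    alpha_mean = alpha_sum / kept
    return PosteriorSummary(
        method=prior.label(),
        animal_ids=M_g.animal_ids.copy(),
        ebv=M_c @ alpha_mean,
        marker_effect_means=alpha_mean,
        inclusion_probs=incl_sum / kept,
        mu=mu_sum / kept,
        pi_chain=np.array(pi_chain) if prior.estimate_pi else None,
        sigma_e2_chain=np.array(se2_chain),
        genvar_chain=np.array(genvar_chain),
        alpha_draws=np.array(draws) if store_draws else None,
        marker_ids=M_g.marker_ids.copy(),
    )


def build_ssbr_design(partition: NrmPartition, M_g: GenotypeMatrix) -> SsbrDesign:
    """Assemble X, stacked covariates and the imputation-residual covariance."""
    from .genotypes import chol_solve_jitter

    if not np.array_equal(partition.genotyped_ids, M_g.animal_ids):
        raise ValueError("genotype rows must match the partition's genotyped ID order")
    n_n, n_g = partition.n_nongenotyped, partition.n_genotyped
    imput = impute_nongenotyped(partition, M_g)
    M = np.vstack([imput.values, M_g.codes])
    col_means = M_g.codes.mean(axis=0)

    if n_n > 0:
        Agg_inv_1 = chol_solve_jitter(partition.A_gg, np.ones(n_g))
        x2_n = -(partition.A_ng @ Agg_inv_1)
        # centered imputation: A_ng A_gg^-1 (M_g - 1 m') = M_hat_n - (A_ng A_gg^-1 1) m'
        imput_centered = imput.values + np.outer(x2_n, col_means)
        M_centered = np.vstack([imput_centered, M_g.codes - col_means])
        Agg_inv_Agn = chol_solve_jitter(partition.A_gg, partition.A_gn)
        eps_cov = partition.A_nn - partition.A_ng @ Agg_inv_Agn
        eps_cov = 0.5 * (eps_cov + eps_cov.T)
    else:
        x2_n = np.zeros(0)
        eps_cov = np.zeros((0, 0))
        M_centered = M - col_means
    X = np.ones((n_n + n_g, 2))
    X[:n_n, 1] = x2_n
    X[n_n:, 1] = -1.0

    q = allele_freqs(M_g)
    return SsbrDesign(
        animal_ids=np.concatenate([partition.nongenotyped_ids, partition.genotyped_ids]),
        is_genotyped=np.concatenate(
            [np.zeros(n_n, dtype=bool), np.ones(n_g, dtype=bool)]
        ),
        X=X,
        M=M,
        M_centered=M_centered,
        epsilon_cov=eps_cov,
        sum_2pq=float(np.sum(2.0 * q * (1.0 - q))),
        marker_ids=M_g.marker_ids.copy(),
    )


def fit_ssbr(
    phenos_all: PhenotypeTable,
    design: SsbrDesign,
    prior: PriorSpec,
    vc: VarianceComponents,
    chain: McmcSettings,
    store_draws: bool = False,
) -> PosteriorSummary:
    """Single-step Bayesian regression over genotyped and non-genotyped records.

    EBVs: genotyped animals get ``M_g alpha`` (posterior mean, centered
    covariates); non-genotyped get ``M_hat_n alpha + eps``.  The location
    shift ``mu_g`` is reported separately and is not folded into EBVs.
    """
    row_of = design.row_index()
    try:
        rows = np.array([row_of[a] for a in phenos_all.animal_ids], dtype=np.int64)
    except KeyError as e:
        raise KeyError(f"phenotyped animal {e.args[0]!r} not in the SSBR design") from None
    n_n = design.n_nongenotyped
    y = phenos_all.y.copy()
    n_rec = len(y)
    W = design.M_centered[rows]
    X = design.X[rows].copy()
    fit_mu_g = n_n > 0
    if not fit_mu_g:
        log.info("no non-genotyped animals: dropping the collinear mu_g column")
        X = X[:, :1]

    # epsilon bookkeeping: entry per non-genotyped animal; records link by row
    eps_rec = np.full(n_rec, -1, dtype=np.int64)
    for k, row in enumerate(rows):
        if row < n_n:
            eps_rec[k] = row
    has_eps_data = np.zeros(n_n, dtype=bool)
    has_eps_data[eps_rec[eps_rec >= 0]] = True
    all_observed = bool(has_eps_data.all()) if n_n else True

    if n_n:
        lam_eig, U = np.linalg.eigh(design.epsilon_cov)
        lam_eig = np.clip(lam_eig, 0.0, None)
        pos = lam_eig > 1e-10 * max(lam_eig.max(), 1.0)
        inv_lam = np.zeros(n_n)
        inv_lam[pos] = 1.0 / lam_eig[pos]
        n_pos = int(pos.sum())
        D_obs = has_eps_data.astype(np.float64)
        if not all_observed:
            UDU = (U.T * D_obs) @ U

    rng = np.random.default_rng(chain.seed + 1)
    state = _MixtureState(W, prior, vc, design.sum_2pq, chain.seed)
    se2, sg2 = vc.sigma_e2, vc.sigma_g2
    coeffs = np.zeros(X.shape[1])
    coeffs[0] = float(y.mean())
    eps = np.zeros(n_n)
    r = y - X @ coeffs

    p = design.n_markers
    kept = 0
    alpha_sum = np.zeros(p)
    incl_sum = np.zeros(p)
    eps_sum = np.zeros(n_n)
    coeff_sum = np.zeros(X.shape[1])
    pi_chain, se2_chain, sg2_chain, genvar_chain = [], [], [], []
    draws = [] if store_draws else None
    gen_rows_all = np.flatnonzero(design.is_genotyped)

    for it in range(chain.n_iter):
        sample_vars = not vc.fixed
        n_incl, ssq = state.sweep(r, se2, sample_vars)
        _update_flat_coeffs(X, coeffs, r, se2, rng)

        if n_n:
            # block draw of eps in the eigenbasis of its covariance
            t = np.zeros(n_n)
            obs_mask = eps_rec >= 0
            t[eps_rec[obs_mask]] = r[obs_mask] + eps[eps_rec[obs_mask]]
            if all_observed:
                c = np.where(pos, 1.0 / (1.0 / se2 + inv_lam / sg2), 0.0)
                w_mean = c * (U.T @ t) / se2
                w = w_mean + np.sqrt(c) * rng.standard_normal(n_n)
            else:
                B = UDU / se2 + np.diag(inv_lam / sg2)
                B = B[np.ix_(pos, pos)]
                rhs = (U.T @ (D_obs * t))[pos] / se2
                L = np.linalg.cholesky(B)
                w_mean = np.linalg.solve(B, rhs)
                z = np.linalg.solve(L.T, rng.standard_normal(n_pos))
                w = np.zeros(n_n)
                w[pos] = w_mean + z
            eps_new = U @ w
            r[obs_mask] += eps[eps_rec[obs_mask]] - eps_new[eps_rec[obs_mask]]
            eps = eps_new
            if sample_vars:
                ss_g = float(np.sum(w[pos] ** 2 * inv_lam[pos]))
                sg2 = (ss_g + vc.nu_g * vc.S_g2) / rng.chisquare(vc.nu_g + n_pos)

        state.update_hyper(rng, n_incl, ssq, sample_vars)
        if sample_vars:
            se2 = (float(r @ r) + vc.nu_e * vc.S_e2) / rng.chisquare(vc.nu_e + n_rec)

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            kept += 1
            alpha_sum += state.alpha
            incl_sum += state.delta
            eps_sum += eps
            coeff_sum += coeffs
            pi_chain.append(state.pi)
            se2_chain.append(se2)
            sg2_chain.append(sg2)
            g_gen = design.M_centered[gen_rows_all] @ state.alpha
            genvar_chain.append(float(g_gen.var()))
            if store_draws:
                draws.append(state.alpha.copy())

    alpha_mean = alpha_sum / kept
    ebv = design.M_centered @ alpha_mean
    if n_n:
        ebv[:n_n] += eps_sum / kept
    coeff_mean = coeff_sum / kept
    return PosteriorSummary(
        method=f"SSBR-{prior.family}" + ("pi" if prior.estimate_pi else f"(pi={prior.pi})"),
        animal_ids=design.animal_ids.copy(),
        ebv=ebv,
        marker_effect_means=alpha_mean,
        inclusion_probs=incl_sum / kept,
        mu=float(coeff_mean[0]),
        mu_g=float(coeff_mean[1]) if fit_mu_g else None,
        pi_chain=np.array(pi_chain) if prior.estimate_pi else None,
        sigma_e2_chain=np.array(se2_chain),
        sigma_g2_chain=np.array(sg2_chain),
        genvar_chain=np.array(genvar_chain),
        alpha_draws=np.array(draws) if store_draws else None,
        marker_ids=design.marker_ids.copy(),
    )


def solve_ssbr_direct(
    phenos_all: PhenotypeTable,
    design: SsbrDesign,
    vc: VarianceComponents,
    include_mu_g: bool = True,
) -> PosteriorSummary:
    """Closed-form SSBR-C with pi=0 and fixed variances (the GBLUP-equivalent case).

    Marker-effect variance is ``sigma_g^2 / sum(2q(1-q))``; solutions come
    from the GLS normal equations of ``y = X beta + W alpha + Z_n eps + e``.
    """
    row_of = design.row_index()
    rows = np.array([row_of[a] for a in phenos_all.animal_ids], dtype=np.int64)
    n_n = design.n_nongenotyped
    y = phenos_all.y
    W = design.M_centered[rows]
    X = design.X[rows][:, : (2 if include_mu_g and n_n else 1)]
    sig_a2 = vc.sigma_g2 / design.sum_2pq

    n_rec = len(y)
    V = sig_a2 * (W @ W.T) + vc.sigma_e2 * np.eye(n_rec)
    if n_n:
        Zn = np.zeros((n_rec, n_n))
        for k, row in enumerate(rows):
            if row < n_n:
                Zn[k, row] = 1.0
        V += vc.sigma_g2 * (Zn @ design.epsilon_cov @ Zn.T)
    from .genotypes import chol_solve_jitter

    Vi_X = chol_solve_jitter(V, X)
    Vi_y = chol_solve_jitter(V, y)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    resid = y - X @ beta
    Vi_r = chol_solve_jitter(V, resid)
    alpha = sig_a2 * (W.T @ Vi_r)
    ebv = design.M_centered @ alpha
    if n_n:
        eps = vc.sigma_g2 * (design.epsilon_cov @ (Zn.T @ Vi_r))
        ebv[:n_n] += eps
    return PosteriorSummary(
        method="SSBR-C(pi=0,direct)",
        animal_ids=design.animal_ids.copy(),
        ebv=ebv,
        marker_effect_means=alpha,
        inclusion_probs=np.ones(design.n_markers),
        mu=float(beta[0]),
        mu_g=float(beta[1]) if (include_mu_g and n_n) else None,
        marker_ids=design.marker_ids.copy(),
    )


def summarize_posterior(chains: dict, burn_in: int, thin: int) -> dict:
    """Means/SDs and inclusion frequencies over retained draws.

    ``chains`` maps names to arrays whose first axis indexes draws; the key
    ``"alpha"`` (draws x markers) additionally yields inclusion
    probabilities (fraction of retained draws with a nonzero effect).
    """
    out = {}
    for name, arr in chains.items():
        arr = np.asarray(arr)
        if len(arr) <= burn_in:
            raise ValueError(f"chain {name!r} shorter than burn_in")
        kept = arr[burn_in::thin]
        if kept.size == 0:
            raise ValueError("no retained draws")
        out[name] = {"mean": kept.mean(axis=0), "sd": kept.std(axis=0, ddof=0)}
        if name == "alpha":
            out[name]["inclusion_prob"] = (kept != 0.0).mean(axis=0)
    return out
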