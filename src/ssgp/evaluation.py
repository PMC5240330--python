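"""Cross-validation design and accuracy/bias metrics.

Genotyped animals are split into k mutually exclusive folds by K-means on
their rows of A_gg (relationship profiles), which keeps close relatives
together and minimizes training/validation relatedness.  Accuracy is the
correlation between adjusted phenotype and EBV in the validation set divided
by sqrt(h2); fold accuracies are pooled weighting by fold size.  Bias is the
OLS slope of adjusted phenotype on EBV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .bayes import (
    PosteriorSummary,
    PriorSpec,
    build_ssbr_design,
    fit_bayes_regression,
    fit_ssbr,
)
from .genotypes import GenotypeMatrix, build_grm, scale_grm
from .mixed_models import (
    McmcSettings,
    ModelFit,
    PhenotypeTable,
    VarianceComponents,
    fit_pblup,
    fit_ssgblup,
)
from .pedigree import Pedigree, RelationshipMatrix, build_nrm, partition_nrm

__all__ = [
    "FoldAssignment",
    "EvaluationReport",
    "CvData",
    "make_cv_folds",
    "pre_adjust_phenotypes",
    "compute_accuracy",
    "pool_accuracies",
    "compute_bias",
    "run_cv",
    "GENOTYPED_ONLY_METHODS",
    "ALL_METHODS",
]

log = logging.getLogger(__name__)

GENOTYPED_ONLY_METHODS = {"pblup-g", "bayesb", "bayesc", "bayescpi"}
ALL_METHODS = (
    "pblup",
    "pblup-g",
    "ssgblup1",
    "ssgblup2",
    "ssgblup3",
    "bayesb",
    "bayesc",
    "bayescpi",
    "ssbr-b",
    "ssbr-c",
    "ssbr-cpi",
)


@dataclass
class FoldAssignment:
    fold_of: dict  # genotyped animal id -> fold index in 1..k
    k: int

    def __post_init__(self) -> None:
        folds = set(self.fold_of.values())
        if folds != set(range(1, self.k + 1)):
            raise ValueError("folds must be non-empty and numbered 1..k")

    @property
    def fold_sizes(self) -> dict:
        sizes = {f: 0 for f in range(1, self.k + 1)}
        for f in self.fold_of.values():
            sizes[f] += 1
        return sizes

    def validation_ids(self, fold: int) -> list:
        return [a for a, f in self.fold_of.items() if f == fold]


@dataclass
class EvaluationReport:
    table: pd.DataFrame  # method, fold, n, cor, accuracy, bias_slope
    pooled: dict  # method -> pooled accuracy
    h2: float
    extras: dict = field(default_factory=dict)


def make_cv_folds(
    A_gg: np.ndarray,
    genotyped_ids,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 20,
) -> FoldAssignment:
    """K-means on relationship-profile rows of A_gg; best of ``n_restarts``."""
    A_gg = np.asarray(A_gg, dtype=np.float64)
    ids = list(genotyped_ids)
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("more folds than genotyped animals")
    if k == n:
        return FoldAssignment({a: i + 1 for i, a in enumerate(ids)}, k)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(A_gg)
    # stable fold numbering: order clusters by first occurrence
    order = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
    return FoldAssignment({a: order[lab] for a, lab in zip(ids, labels)}, k)


def pre_adjust_phenotypes(
    raw: PhenotypeTable, train_ids=None
) -> PhenotypeTable:
    """Remove contemporary-group and linear age effects estimated by OLS.

    Effects are estimated on ``train_ids`` (default: all records) and applied
    to every record; a group absent from training is adjusted by the mean
    estimated group effect, with a warning.
    """
    values = raw.raw if raw.raw is not None else raw.y
    if raw.contemporary_group is None and raw.age is None:
        return PhenotypeTable(
            animal_ids=raw.animal_ids.copy(),
            y=values.copy(),
            contemporary_group=None,
            age=None,
        )
    n = len(values)
    train = np.ones(n, dtype=bool)
    if train_ids is not None:
        keep = set(train_ids)
        train = np.array([a in keep for a in raw.animal_ids.tolist()])
    cols = []
    groups = None
    if raw.contemporary_group is not None:
        groups = np.unique(raw.contemporary_group[train])
        for g in groups:
            cols.append((raw.contemporary_group == g).astype(float))
    age_c = None
    if raw.age is not None:
        age_c = raw.age - raw.age[train].mean()
        cols.append(age_c)
        if groups is None:
            cols.insert(0, np.ones(n))
    Xf = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(Xf[train], values[train], rcond=None)

    adjust = np.zeros(n)
    offset = 0
    if groups is not None:
        g_eff = dict(zip(groups.tolist(), coef[: len(groups)]))
        mean_eff = float(np.mean(coef[: len(groups)]))
        unseen = set(np.unique(raw.contemporary_group)) - set(groups.tolist())
        if unseen:
            log.warning(
                "contemporary groups %s absent from training; using mean group effect",
                sorted(unseen),
            )
        adjust += np.array(
            [g_eff.get(g, mean_eff) for g in raw.contemporary_group.tolist()]
        )
        offset = len(groups)
    elif age_c is not None:
        adjust += coef[0]
        offset = 1
    if age_c is not None:
        adjust += coef[offset] * age_c
    return PhenotypeTable(
        animal_ids=raw.animal_ids.copy(),
        y=values - adjust,
        raw=values.copy(),
        contemporary_group=None
        if raw.contemporary_group is None
        else raw.contemporary_group.copy(),
        age=None if raw.age is None else raw.age.copy(),
    )


def compute_accuracy(y_adj: np.ndarray, ebv: np.ndarray, h2: float) -> float:
    """Validation accuracy: cor(adjusted phenotype, EBV) / sqrt(h2)."""
    y_adj = np.asarray(y_adj, dtype=np.float64)
    ebv = np.asarray(ebv, dtype=np.float64)
    if len(y_adj) < 3 or len(ebv) != len(y_adj):
        raise ValueError("need >= 3 matched validation records")
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must be in (0, 1]")
    if y_adj.std() == 0 or ebv.std() == 0:
        log.warning("zero variance in validation vectors; accuracy undefined")
        return np.nan
    acc = float(np.corrcoef(y_adj, ebv)[0, 1] / np.sqrt(h2))
    if acc > 1.0:
        log.info("accuracy %.3f exceeds 1 (small validation sample); not clipped", acc)
    return acc


def pool_accuracies(per_fold) -> float:
    """Size-weighted mean of per-fold accuracies; NaN folds dropped with warning."""
    ns = np.array([n for n, _ in per_fold], dtype=float)
    accs = np.array([a for _, a in per_fold], dtype=float)
    ok = np.isfinite(accs)
    if not ok.all():
        log.warning("%d fold accuracy value(s) missing; pooling over the rest", (~ok).sum())
    if not ok.any():
        return np.nan
    return float(np.sum(ns[ok] * accs[ok]) / np.sum(ns[ok]))


def compute_bias(y_adj: np.ndarray, ebv: np.ndarray) -> float:
    """OLS slope of adjusted phenotype on EBV (1 = unbiased)."""
    y_adj = np.asarray(y_adj, dtype=np.float64)
    ebv = np.asarray(ebv, dtype=np.float64)
    if ebv.std() == 0:
        log.warning("zero EBV variance; bias slope undefined")
        return np.nan
    e = ebv - ebv.mean()
    return float(e @ (y_adj - y_adj.mean()) / (e @ e))


@dataclass
class CvData:
    """Shared inputs for cross-validated model comparison.

    ``genotypes`` holds QC'd, mean-imputed codes for genotyped animals;
    ``phenotypes`` adjusted records on genotyped and (optionally)
    non-genotyped animals.  Relationship matrices and the SSBR design are
    built once and cached.
    """

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    h2: float
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def A(self) -> RelationshipMatrix:
        if "A" not in self._cache:
            self._cache["A"] = build_nrm(self.pedigree)
        return self._cache["A"]

    @property
    def partition(self):
        if "partition" not in self._cache:
            self._cache["partition"] = partition_nrm(self.A, self.genotypes.animal_ids)
        return self._cache["partition"]

    @property
    def G_scaled(self) -> RelationshipMatrix:
        if "G" not in self._cache:
            G0 = build_grm(self.genotypes)
            self._cache["G"] = scale_grm(G0, self.partition.A_gg)
        return self._cache["G"]

    @property
    def ssbr_design(self):
        if "design" not in self._cache:
            self._cache["design"] = build_ssbr_design(self.partition, self.genotypes)
        return self._cache["design"]

    def default_vc(self, fixed: bool = True) -> VarianceComponents:
        var_y = float(self.phenotypes.y.var())
        return VarianceComponents.from_h2(self.h2, var_y=var_y, fixed=fixed)


def _fit_one(
    method: str,
    data: CvData,
    train: PhenotypeTable,
    vc: VarianceComponents,
    chain: McmcSettings,
    pi: float,
):
    """Fit one model on a training set and return (validation-capable) EBVs."""
    method = method.lower()
    if method == "pblup":
        return fit_pblup(train, data.A, vc, chain=chain)
    if method == "pblup-g":
        return fit_pblup(
            train,
            data.A,
            vc,
            genotyped_only=True,
            genotyped_ids=data.genotypes.animal_ids,
            chain=chain,
        )
    if method in ("ssgblup1", "ssgblup2", "ssgblup3"):
        variant = {"ssgblup1": "I", "ssgblup2": "II", "ssgblup3": "III"}[method]
        return fit_ssgblup(
            train,
            data.partition,
            data.G_scaled,
            vc,
            variant=variant,
            chain=chain,
            genotypes=data.genotypes,
        )
    if method in ("bayesb", "bayesc", "bayescpi"):
        prior = PriorSpec(
            family="B" if method == "bayesb" else "C",
            pi=pi,
            estimate_pi=method == "bayescpi",
        )
        geno_set = set(data.genotypes.animal_ids.tolist())
        train_g = train.subset([a for a in train.animal_ids.tolist() if a in geno_set])
        return fit_bayes_regression(train_g, data.genotypes, prior, vc, chain)
    if method in ("ssbr-b", "ssbr-c", "ssbr-cpi"):
        prior = PriorSpec(
            family="B" if method == "ssbr-b" else "C",
            pi=pi,
            estimate_pi=method == "ssbr-cpi",
        )
        return fit_ssbr(train, data.ssbr_design, prior, vc, chain)
    raise ValueError(f"unknown method {method!r}")


def run_cv(
    methods,
    data: CvData,
    folds: FoldAssignment,
    vc: VarianceComponents | None = None,
    chain: McmcSettings | None = None,
    pi: float = 0.0,
) -> EvaluationReport:
    """K-fold cross-validation of the requested methods.

    For each fold, validation (genotyped) animals lose their phenotypes;
    all-animal methods keep non-genotyped records in training, while
    genotyped-only methods train on genotyped training animals alone.
    Metrics are computed on genotyped validation animals only.
    """
    if isinstance(methods, str):
        methods = [methods]
    if folds.k < 2:
        raise ValueError("cross-validation requires k >= 2")
    vc = vc or data.default_vc()
    chain = chain or McmcSettings(n_iter=2000, burn_in=500, thin=2)
    geno_set = set(data.genotypes.animal_ids.tolist())
    pheno_ids = data.phenotypes.animal_ids.tolist()
    rows = []
    for fold in range(1, folds.k + 1):
        valid_ids = [a for a in folds.validation_ids(fold) if a in set(pheno_ids)]
        valid_set = set(valid_ids)
        train_ids = [a for a in pheno_ids if a not in valid_set]
        train = data.phenotypes.subset(train_ids)
        y_valid = data.phenotypes.subset(valid_ids).y
        for method in methods:
            fit = _fit_one(method, data, train, vc, chain, pi)
            ebv_valid = fit.ebv_of(valid_ids)
            cor = float(np.corrcoef(y_valid, ebv_valid)[0, 1])
            rows.append(
                {
                    "method": method,
                    "fold": fold,
                    "n": len(valid_ids),
                    "cor": cor,
                    "accuracy": compute_accuracy(y_valid, ebv_valid, data.h2),
                    "bias_slope": compute_bias(y_valid, ebv_valid),
                }
            )
    table = pd.DataFrame(rows)
    pooled = {
        m: pool_accuracies(
            list(zip(g["n"], g["accuracy"]))
        )
        for m, g in table.groupby("method")
    }
    return EvaluationReport(table=table, pooled=pooled, h2=data.h2)
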