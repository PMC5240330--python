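"""End-to-end runner: QC -> conflicts -> relationship matrices -> CV -> GWAS."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .bayes import PriorSpec, fit_bayes_regression
from .evaluation import CvData, EvaluationReport, make_cv_folds, run_cv
from .genotypes import (
    build_grm,
    detect_conflicts,
    impute_sporadic_missing,
    qc_filter,
    scale_grm,
    write_conflicts_csv,
    write_qc_report_csv,
)
from .gwas import window_variance
from .io import DataBundle, RunConfig, read_inputs
from .mixed_models import McmcSettings
from .pedigree import build_nrm, partition_nrm

log = logging.getLogger(__name__)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig, bundle: DataBundle | None = None) -> EvaluationReport:
    """Execute the full analysis described by ``config``; artifacts go to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_inputs"
    try:
        if bundle is None:
            bundle = read_inputs(config)

        stage = "qc"
        geno_qc, qc_report = qc_filter(bundle.genotypes)
        keep = qc_report.table["retained"].to_numpy()
        marker_map = bundle.marker_map.subset(keep)
        geno_qc = impute_sporadic_missing(geno_qc)
        write_qc_report_csv(qc_report, out / "qc_report.csv")

        stage = "conflicts"
        A = build_nrm(bundle.pedigree)
        part = partition_nrm(A, geno_qc.animal_ids)
        G0 = build_grm(geno_qc)
        pairs, summary = detect_conflicts(G0, part.A_gg)
        write_conflicts_csv(pairs, out / "conflicts.csv")
        phenos = bundle.phenotypes
        flagged = summary["flagged_animals"]
        if config.remove_conflicts and len(flagged) > 0.2 * geno_qc.n_animals:
            log.warning(
                "conflict detection flagged %d/%d genotyped animals; thresholds "
                "look miscalibrated for this panel, skipping removal",
                len(flagged),
                geno_qc.n_animals,
            )
            flagged = []
        if config.remove_conflicts and flagged:
            drop = set(flagged)
            log.info("removing %d conflict-flagged animals", len(drop))
            keep_ids = [a for a in geno_qc.animal_ids.tolist() if a not in drop]
            geno_qc = geno_qc.subset_animals(keep_ids)
            keep_ph = [a for a in phenos.animal_ids.tolist() if a not in drop]
            phenos = phenos.subset(keep_ph)

        stage = "cross_validation"
        data = CvData(
            pedigree=bundle.pedigree,
            genotypes=geno_qc,
            phenotypes=phenos,
            h2=config.h2,
        )
        folds = make_cv_folds(
            data.partition.A_gg,
            geno_qc.animal_ids.tolist(),
            k=config.k_folds,
            seed=config.seed,
        )
        chain = McmcSettings(
            n_iter=config.chain_iter,
            burn_in=config.chain_burn_in,
            thin=config.chain_thin,
            seed=config.seed + 1,
        )
        vc = data.default_vc(fixed=not config.estimate_variances)
        report = run_cv(config.methods, data, folds, vc=vc, chain=chain, pi=config.pi)
        report.table.to_csv(out / "cv_report.csv", index=False)

        if config.gwas:
            stage = "gwas"
            prior = PriorSpec(family="B", pi=config.pi)
            geno_set = set(geno_qc.animal_ids.tolist())
            train_g = phenos.subset(
                [a for a in phenos.animal_ids.tolist() if a in geno_set]
            )
            post = fit_bayes_regression(
                train_g, geno_qc, prior, vc, chain, store_draws=True
            )
            wv = window_variance(post, geno_qc, marker_map, window_bp=config.window_bp)
            wv.table.to_csv(out / "gwas_windows.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "methods": list(config.methods),
        "inputs": {
            name: _checksum(getattr(config, name))
            for name in ("pedigree", "genotypes", "marker_map", "phenotypes")
            if Path(str(getattr(config, name))).exists()
        },
        "qc": {
            "n_input": qc_report.n_input_markers,
            "n_retained": qc_report.n_retained,
        },
        "conflicts": {
            "n_flagged_animals": len(summary["flagged_animals"]),
            "corr_before": summary["corr_before"],
            "corr_after": summary["corr_after"],
        },
        "pooled_accuracy": report.pooled,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return report
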