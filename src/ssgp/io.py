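"""Plain-text readers/writers and run configuration.

Formats: pedigree CSV (id,sire,dam[,generation]; 0 = unknown parent),
genotypes as whitespace-delimited text with a marker-ID header and an ``id``
first column (codes 0/1/2, NA = missing), marker map CSV
(marker,chrom,pos_bp), phenotype CSV (id,value[,cg,age]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix, MarkerMap
from .mixed_models import PhenotypeTable
from .pedigree import Pedigree, read_pedigree_csv

__all__ = [
    "RunConfig",
    "DataBundle",
    "read_inputs",
    "read_genotypes_raw",
    "write_genotypes_raw",
    "read_marker_map_csv",
    "write_marker_map_csv",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
]

log = logging.getLogger(__name__)


def write_genotypes_raw(genotypes: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("id " + " ".join(str(m) for m in genotypes.marker_ids) + "\n")
        for aid, row in zip(genotypes.animal_ids, genotypes.codes):
            cells = (
                "NA" if not np.isfinite(v) else ("%g" % v) for v in row
            )
            fh.write(f"{aid} " + " ".join(cells) + "\n")


def read_genotypes_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    if df.columns[0] != "id":
        raise ValueError(f"{path}: first genotype column must be 'id'")
    codes = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return GenotypeMatrix(
        codes=codes,
        animal_ids=df["id"].to_numpy(),
        marker_ids=np.array(df.columns[1:]),
    )


def write_marker_map_csv(marker_map: MarkerMap, path) -> None:
    pd.DataFrame(
        {
            "marker": marker_map.marker_ids,
            "chrom": marker_map.chromosome,
            "pos_bp": marker_map.position_bp,
        }
    ).to_csv(path, index=False)


def read_marker_map_csv(path) -> MarkerMap:
    df = pd.read_csv(path)
    return MarkerMap(
        marker_ids=df["marker"].to_numpy(),
        chromosome=df["chrom"].to_numpy(),
        position_bp=df["pos_bp"].to_numpy(),
    )


def write_phenotypes_csv(phenos: PhenotypeTable, path) -> None:
    df = pd.DataFrame({"id": phenos.animal_ids, "value": phenos.y})
    if phenos.raw is not None:
        df["raw"] = phenos.raw
    if phenos.contemporary_group is not None:
        df["cg"] = phenos.contemporary_group
    if phenos.age is not None:
        df["age"] = phenos.age
    df.to_csv(path, index=False)


def read_phenotypes_csv(path) -> PhenotypeTable:
    df = pd.read_csv(path)
    for col in ("id", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: phenotype CSV needs an '{col}' column")
    return PhenotypeTable(
        animal_ids=df["id"].to_numpy(),
        y=df["value"].to_numpy(dtype=np.float64),
        raw=df["raw"].to_numpy(dtype=np.float64) if "raw" in df.columns else None,
        contemporary_group=df["cg"].to_numpy() if "cg" in df.columns else None,
        age=df["age"].to_numpy(dtype=np.float64) if "age" in df.columns else None,
    )


@dataclass
class RunConfig:
    pedigree: str
    genotypes: str
    marker_map: str
    phenotypes: str
    out_dir: str = "ssgp_out"
    methods: list = field(default_factory=lambda: ["pblup", "ssgblup1"])
    h2: float = 0.5
    pi: float = 0.0
    k_folds: int = 5
    chain_iter: int = 2000
    chain_burn_in: int = 500
    chain_thin: int = 2
    estimate_variances: bool = False
    remove_conflicts: bool = True
    gwas: bool = False
    window_bp: int = 1_000_000
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


@dataclass
class DataBundle:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    phenotypes: PhenotypeTable


def read_inputs(config: RunConfig) -> DataBundle:
    """Read and cross-validate the four input files."""
    ped = read_pedigree_csv(config.pedigree)
    geno = read_genotypes_raw(config.genotypes)
    marker_map = read_marker_map_csv(config.marker_map)
    phenos = read_phenotypes_csv(config.phenotypes)

    ped_ids = set(ped.ids.tolist())
    missing_g = [a for a in geno.animal_ids.tolist() if a not in ped_ids]
    if missing_g:
        raise ValueError(
            f"{len(missing_g)} genotyped animal(s) absent from the pedigree "
            f"(first: {missing_g[0]!r})"
        )
    missing_p = [a for a in phenos.animal_ids.tolist() if a not in ped_ids]
    if missing_p:
        raise ValueError(
            f"{len(missing_p)} phenotyped animal(s) absent from the pedigree "
            f"(first: {missing_p[0]!r})"
        )
    if len(marker_map) != geno.n_markers:
        raise ValueError(
            f"marker map rows ({len(marker_map)}) != genotype columns ({geno.n_markers})"
        )
    if not np.array_equal(marker_map.marker_ids.astype(str), geno.marker_ids.astype(str)):
        raise ValueError("marker IDs differ between map and genotype file")
    return DataBundle(ped, geno, marker_map, phenos)
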