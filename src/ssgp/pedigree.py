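"""Pedigree container, numerator relationship matrix and its partitions.

The numerator relationship matrix (NRM, ``A``) is built with the tabular
method.  Partitions ``A_gg / A_ng / A_gn / A_nn`` split ``A`` between
genotyped and non-genotyped animals as required by single-step models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "NrmPartition",
    "build_nrm",
    "inbreeding",
    "partition_nrm",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "PedigreeError",
]

UNKNOWN = -1


class PedigreeError(ValueError):
    """Structural problem in a pedigree (ordering, unknown IDs, ...)."""


@dataclass
class Pedigree:
    """Ordered pedigree records with dense 0-based parent indices.

    Parameters
    ----------
    ids
        External animal IDs in record (chronological) order.
    sire, dam
        Dense indices into ``ids`` (``-1`` = unknown parent).
    generation
        Optional generation label per animal (0 = founder cohort).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray | None = None
    id_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if self.generation is not None:
            self.generation = np.asarray(self.generation, dtype=np.int64)
        if len(self.ids) != len(set(self.ids.tolist())):
            raise PedigreeError("duplicate animal IDs in pedigree")
        self.id_index = {a: i for i, a in enumerate(self.ids.tolist())}
        self.validate()

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        n = self.n
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if par.shape != (n,):
                raise PedigreeError(f"{name} index length mismatch")
            bad = par >= np.arange(n)
            bad &= par != UNKNOWN
            if np.any(bad):
                i = int(np.flatnonzero(bad)[0])
                raise PedigreeError(
                    f"pedigree not sorted parents-first: {name} of record {i} "
                    f"({self.ids[i]!r}) does not precede it"
                )
            if np.any(par < UNKNOWN) or np.any(par >= n):
                raise PedigreeError(f"{name} index out of range")
        if np.any((self.sire == self.dam) & (self.sire != UNKNOWN)):
            raise PedigreeError("an animal appears as both sire and dam of the same offspring")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        unknown=0,
        generations: Sequence[int] | None = None,
    ) -> "Pedigree":
        """Build from ``(animal, sire, dam)`` triples; ``unknown`` marks a missing parent."""
        recs = list(records)
        ids = np.array([r[0] for r in recs])
        index = {a: i for i, a in enumerate(ids.tolist())}

        def look(p, i):
            if p == unknown or (isinstance(p, float) and np.isnan(p)):
                return UNKNOWN
            if p not in index:
                raise PedigreeError(f"parent {p!r} of animal {ids[i]!r} not in pedigree")
            return index[p]

        sire = np.array([look(r[1], i) for i, r in enumerate(recs)], dtype=np.int64)
        dam = np.array([look(r[2], i) for i, r in enumerate(recs)], dtype=np.int64)
        gen = None if generations is None else np.asarray(generations)
        return cls(ids=ids, sire=sire, dam=dam, generation=gen)

    def indices_of(self, ids: Sequence) -> np.ndarray:
        try:
            return np.array([self.id_index[a] for a in ids], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"animal {e.args[0]!r} not in pedigree") from None


@dataclass
class RelationshipMatrix:
    """Symmetric additive-relationship matrix with its animal IDs.

    ``kind`` is one of ``"NRM"``, ``"GRM"``, ``"H"``.
    """

    values: np.ndarray
    ids: np.ndarray
    kind: str = "NRM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.ids = np.asarray(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match ID list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def indices_of(self, ids: Sequence) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.ids.tolist())}
        try:
            return np.array([index[a] for a in ids], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"animal {e.args[0]!r} not in relationship matrix") from None


@dataclass
class NrmPartition:
    """Blocks of ``A`` split between genotyped (g) and non-genotyped (n) animals."""

    A_gg: np.ndarray
    A_ng: np.ndarray
    A_gn: np.ndarray
    A_nn: np.ndarray
    genotyped_ids: np.ndarray
    nongenotyped_ids: np.ndarray

    def __post_init__(self) -> None:
        ng, g = len(self.nongenotyped_ids), len(self.genotyped_ids)
        if self.A_gg.shape != (g, g) or self.A_nn.shape != (ng, ng):
            raise ValueError("partition block dimensions inconsistent with ID lists")
        if self.A_ng.shape != (ng, g) or self.A_gn.shape != (g, ng):
            raise ValueError("partition block dimensions inconsistent with ID lists")
        if not np.allclose(self.A_gn, self.A_ng.T, atol=1e-12):
            raise ValueError("A_gn is not the transpose of A_ng")

    @property
    def n_genotyped(self) -> int:
        return len(self.genotyped_ids)

    @property
    def n_nongenotyped(self) -> int:
        return len(self.nongenotyped_ids)


def build_nrm(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    ``a_ii = 1 + 0.5 a_{s,d}``; ``a_ij = 0.5 (a_{j,s(i)} + a_{j,d(i)})`` for
    earlier ``j``; unknown parents contribute zero.
    """
    n = pedigree.n
    A = np.zeros((n, n))
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        if i == 0:
            continue
        row = np.zeros(i)
        if s != UNKNOWN:
            row += A[s, :i]
        if d != UNKNOWN:
            row += A[d, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix(values=A, ids=pedigree.ids.copy(), kind="NRM")


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficient ``F_i = a_ii - 1``."""
    return np.diag(build_nrm(pedigree).values) - 1.0


def partition_nrm(A: RelationshipMatrix, genotyped_ids: Sequence) -> NrmPartition:
    """Split ``A`` into g/n blocks; genotyped IDs keep the supplied order."""
    genotyped_ids = np.asarray(genotyped_ids)
    if len(genotyped_ids) == 0:
        raise ValueError("at least one genotyped animal is required to partition A")
    g_idx = A.indices_of(genotyped_ids)
    g_set = set(g_idx.tolist())
    n_idx = np.array([i for i in range(A.n) if i not in g_set], dtype=np.int64)
    V = A.values
    return NrmPartition(
        A_gg=V[np.ix_(g_idx, g_idx)],
        A_ng=V[np.ix_(n_idx, g_idx)],
        A_gn=V[np.ix_(g_idx, n_idx)],
        A_nn=V[np.ix_(n_idx, n_idx)],
        genotyped_ids=genotyped_ids,
        nongenotyped_ids=A.ids[n_idx],
    )


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree CSV must have columns {sorted(required)}")
    gen = df["generation"].to_numpy() if "generation" in df.columns else None
    return Pedigree.from_records(
        zip(df["id"], df["sire"], df["dam"]), unknown=0, generations=gen
    )


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    sire_ids = np.where(pedigree.sire == UNKNOWN, 0, pedigree.ids[pedigree.sire])
    dam_ids = np.where(pedigree.dam == UNKNOWN, 0, pedigree.ids[pedigree.dam])
    df = pd.DataFrame({"id": pedigree.ids, "sire": sire_ids, "dam": dam_ids})
    if pedigree.generation is not None:
        df["generation"] = pedigree.generation
    df.to_csv(path, index=False)


def write_matrix_txt(mat: RelationshipMatrix, path) -> None:
    """Plain-text matrix dump: header of IDs then one row per animal."""
    df = pd.DataFrame(mat.values, columns=[str(i) for i in mat.ids])
    df.insert(0, "id", mat.ids)
    df.to_csv(path, index=False, float_format="%.10g")
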