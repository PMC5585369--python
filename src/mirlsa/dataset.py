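"""In-memory container for the heterogeneous miRNA data sources.

A :class:`MirnaDataset` bundles the five per-miRNA data sources — disease
associations (MD), target genes (MT), families (MF), genomic coordinates
(behind the neighbour matrix MN) and per-source word counts (MW) — together
with the disease hierarchy used for semantic similarity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .hierarchy import DiseaseHierarchy

__all__ = ["Coord", "MirnaDataset", "TEXT_SOURCES"]

#: Recognised plain-text description sources, in assembly order.
TEXT_SOURCES = ("pubmed", "mirbase_abstract", "mirbase_description")


class Coord(NamedTuple):
    """Genomic location of a miRNA hairpin (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    strand: str


def _as_binary(m, name: str) -> np.ndarray:
    a = np.asarray(m, dtype=np.int8)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-d matrix")
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary (entries in {{0, 1}})")
    return a


@dataclass
class MirnaDataset:
    """Raw inputs for the predictor.

    Invariants (checked by :meth:`validate`): all matrices have one row per
    miRNA; ``md`` has one column per disease; ``mt``/``md``/``mf`` are binary;
    each miRNA belongs to at most one family; coordinate ``start <= end``.
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    md: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    mt: np.ndarray | None = None
    family_ids: list[str] = field(default_factory=list)
    mf: np.ndarray | None = None
    coords: dict[str, Coord] = field(default_factory=dict)
    docs: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    hierarchy: DiseaseHierarchy = field(default_factory=DiseaseHierarchy)

    def __post_init__(self):
        n = len(self.mirna_ids)
        self.md = _as_binary(self.md, "md")
        if self.mt is None:
            self.mt = np.zeros((n, len(self.gene_ids)), dtype=np.int8)
        if self.mf is None:
            self.mf = np.zeros((n, len(self.family_ids)), dtype=np.int8)
        self.mt = _as_binary(self.mt, "mt")
        self.mf = _as_binary(self.mf, "mf")
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        n = len(self.mirna_ids)
        if len(set(self.mirna_ids)) != n:
            raise ValueError("duplicate miRNA identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        for name, m, ids in (
            ("md", self.md, self.disease_ids),
            ("mt", self.mt, self.gene_ids),
            ("mf", self.mf, self.family_ids),
        ):
            if m.shape != (n, len(ids)):
                raise ValueError(
                    f"{name} has shape {m.shape}, expected ({n}, {len(ids)})"
                )
        if self.mf.size and (self.mf.sum(axis=1) > 1).any():
            raise ValueError("each miRNA may belong to at most one family")
        for mid, c in self.coords.items():
            if c.start > c.end:
                raise ValueError(f"coordinate start > end for {mid!r}")

    # -- convenience -----------------------------------------------------

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def mirna_index(self, mirna: str) -> int:
        try:
            return self.mirna_ids.index(mirna)
        except ValueError:
            raise KeyError(f"unknown miRNA: {mirna!r}") from None

    def disease_index(self, disease: str) -> int:
        try:
            return self.disease_ids.index(disease)
        except ValueError:
            raise KeyError(f"unknown disease: {disease!r}") from None

    def with_md(self, md: np.ndarray) -> "MirnaDataset":
        """A shallow copy sharing every source except a replaced MD matrix."""
        return dataclasses.replace(self, md=md)

    def disease_association_counts(self) -> np.ndarray:
        """Number of annotated miRNAs per disease column."""
        return np.asarray(self.md.sum(axis=0)).ravel()
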