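"""Readers and writers for the tab-separated exchange formats.

A dataset directory holds up to six UTF-8 TSV files, each with a header row;
lines starting with ``#`` are ignored:

========================  =============================================
file                      columns
========================  =============================================
``mirna_disease.tsv``     ``mirna<TAB>disease``   (required)
``mirna_gene.tsv``        ``mirna<TAB>gene``
``mirna_family.tsv``      ``mirna<TAB>family``
``coordinates.tsv``       ``mirna<TAB>chrom<TAB>start<TAB>end<TAB>strand``
``hierarchy.tsv``         ``parent<TAB>child``
``documents.tsv``         ``mirna<TAB>source<TAB>text``
========================  =============================================

Real HMDD / miRBase exports reduced to these column layouts load unchanged;
identifiers are treated as opaque strings and ordered lexicographically.
"""

from __future__ import annotations

import re
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import TEXT_SOURCES, Coord, MirnaDataset
from .hierarchy import DiseaseHierarchy

__all__ = ["load_dataset", "write_dataset", "tokenize", "write_ranking"]

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumerics, drop tokens shorter than 3."""
    return [t for t in _TOKEN_RE.split(str(text).lower()) if len(t) >= 3]


def _read_tsv(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    if not path.exists():
        return pd.DataFrame(columns=list(columns))
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).dropna()
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {sorted(missing)}")
    return df


def load_dataset(directory: str | Path) -> MirnaDataset:
    """Load a dataset directory into a validated :class:`MirnaDataset`."""
    directory = Path(directory)
    md_df = _read_tsv(directory / "mirna_disease.tsv", ("mirna", "disease"))
    if md_df.empty:
        raise ValueError(f"{directory}: mirna_disease.tsv is required and must be non-empty")
    mt_df = _read_tsv(directory / "mirna_gene.tsv", ("mirna", "gene"))
    mf_df = _read_tsv(directory / "mirna_family.tsv", ("mirna", "family"))
    co_df = _read_tsv(directory / "coordinates.tsv", ("mirna", "chrom", "start", "end", "strand"))
    hi_df = _read_tsv(directory / "hierarchy.tsv", ("parent", "child"))
    do_df = _read_tsv(directory / "documents.tsv", ("mirna", "source", "text"))

    mirnas = sorted(
        set(md_df["mirna"])
        | set(mt_df["mirna"])
        | set(mf_df["mirna"])
        | set(co_df["mirna"])
        | set(do_df["mirna"])
    )
    diseases = sorted(set(md_df["disease"]))
    genes = sorted(set(mt_df["gene"]))
    families = sorted(set(mf_df["family"]))

    m_idx = {m: i for i, m in enumerate(mirnas)}

    def pair_matrix(df: pd.DataFrame, col: str, col_ids: list[str]) -> np.ndarray:
        out = np.zeros((len(mirnas), len(col_ids)), dtype=np.int8)
        c_idx = {c: j for j, c in enumerate(col_ids)}
        for m, c in zip(df["mirna"], df[col]):
            out[m_idx[m], c_idx[c]] = 1
        return out

    edges = list(zip(hi_df["parent"], hi_df["child"]))
    terms = {t for e in edges for t in e} | set(diseases)
    hierarchy = DiseaseHierarchy(terms, edges)

    coords: dict[str, Coord] = {}
    for row in co_df.itertuples(index=False):
        coords[row.mirna] = Coord(row.chrom, int(row.start), int(row.end), row.strand)

    docs: dict[str, dict[str, dict[str, int]]] = {s: {} for s in TEXT_SOURCES}
    for row in do_df.itertuples(index=False):
        if row.source not in docs:
            raise ValueError(
                f"documents.tsv: unknown source {row.source!r}; expected one of {TEXT_SOURCES}"
            )
        counts = docs[row.source].setdefault(row.mirna, Counter())
        counts.update(tokenize(row.text))

    return MirnaDataset(
        mirna_ids=mirnas,
        disease_ids=diseases,
        md=pair_matrix(md_df, "disease", diseases),
        gene_ids=genes,
        mt=pair_matrix(mt_df, "gene", genes),
        family_ids=families,
        mf=pair_matrix(mf_df, "family", families),
        coords=coords,
        docs={s: dict(d) for s, d in docs.items()},
        hierarchy=hierarchy,
    )


def write_dataset(dataset: MirnaDataset, directory: str | Path) -> None:
    """Write *dataset* as the TSV dialect read back by :func:`load_dataset`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def dump_pairs(name: str, header: tuple[str, str], matrix: np.ndarray, col_ids: list[str]):
        lines = ["\t".join(header)]
        rows, cols = np.nonzero(matrix)
        for i, j in zip(rows, cols):
            lines.append(f"{dataset.mirna_ids[i]}\t{col_ids[j]}")
        (directory / name).write_text("\n".join(lines) + "\n", encoding="utf-8")

    dump_pairs("mirna_disease.tsv", ("mirna", "disease"), dataset.md, dataset.disease_ids)
    if dataset.gene_ids:
        dump_pairs("mirna_gene.tsv", ("mirna", "gene"), dataset.mt, dataset.gene_ids)
    if dataset.family_ids:
        dump_pairs("mirna_family.tsv", ("mirna", "family"), dataset.mf, dataset.family_ids)

    if dataset.coords:
        lines = ["mirna\tchrom\tstart\tend\tstrand"]
        for mid in dataset.mirna_ids:
            c = dataset.coords.get(mid)
            if c is not None:
                lines.append(f"{mid}\t{c.chrom}\t{c.start}\t{c.end}\t{c.strand}")
        (directory / "coordinates.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    edges = sorted(dataset.hierarchy._g.edges())  # direct edges only
    if edges:
        lines = ["parent\tchild"] + [f"{p}\t{c}" for p, c in edges]
        (directory / "hierarchy.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    if any(dataset.docs.get(s) for s in TEXT_SOURCES):
        lines = ["mirna\tsource\ttext"]
        for source in TEXT_SOURCES:
            per_mirna = dataset.docs.get(source, {})
            for mid in dataset.mirna_ids:
                counts = per_mirna.get(mid)
                if counts:
                    words = " ".join(
                        w for w in sorted(counts) for _ in range(counts[w])
                    )
                    lines.append(f"{mid}\t{source}\t{words}")
        (directory / "documents.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_ranking(path: str | Path, rows: list[tuple[str, int, str, float]]) -> None:
    """Write ranked predictions as ``disease<TAB>rank<TAB>mirna<TAB>cosine``."""
    lines = ["disease\trank\tmirna\tcosine"]
    for disease, rank, mirna, cosine in rows:
        lines.append(f"{disease}\t{rank}\t{mirna}\t{cosine:.6f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
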