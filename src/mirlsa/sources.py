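"""Per-source weighted-matrix transforms.

Each raw data source (targets, diseases, families, genomic neighbours,
plain-text word counts) is turned into a weighted miRNA x feature matrix:

* network-based inference (NBI): two-step equal-split mass diffusion on the
  bipartite miRNA-gene graph, re-weighting binary target links;
* TF-IDF: raw term count x ln(N/df) on the word-count matrices;
* disease-similarity augmentation: each (miRNA, disease) pair receives the
  maximum ancestor-Dice similarity between the disease and the miRNA's
  annotated diseases, then the measure is discretized into overlapping
  indicator bins (one column per disease x bin);
* genomic neighbour weights: linear decay of the start-position distance on
  a shared chromosome (clustered miRNAs are commonly co-transcribed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset import Coord, MirnaDataset
from .hierarchy import DiseaseHierarchy

__all__ = [
    "WeightedMatrix",
    "apply_nbi",
    "apply_tfidf",
    "word_count_matrix",
    "infer_diseases",
    "disease_similarity",
    "association_weight",
    "discretize",
    "neighbor_weights",
    "build_disease_block",
    "DEFAULT_NEIGHBOR_WINDOW",
]

logger = logging.getLogger(__name__)

#: Window (bp) over which two miRNAs on the same chromosome are considered
#: genomic neighbours, with linearly decaying weight.
DEFAULT_NEIGHBOR_WINDOW = 50_000.0

NO_ASSOC = "no_assoc"


@dataclass
class WeightedMatrix:
    """A miRNA x feature block with namespaced column identifiers."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.row_ids)}, {len(self.col_ids)}) identifiers"
            )
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("column identifiers must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("weighted matrix contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("weighted matrix contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @staticmethod
    def hstack(blocks: list["WeightedMatrix"]) -> "WeightedMatrix":
        if not blocks:
            raise ValueError("no blocks to concatenate")
        rows = blocks[0].row_ids
        for b in blocks[1:]:
            if b.row_ids != rows:
                raise ValueError("all blocks must share the same row identifiers")
        col_ids = [c for b in blocks for c in b.col_ids]
        values = np.hstack([b.values for b in blocks]) if blocks else np.zeros((len(rows), 0))
        return WeightedMatrix(rows, col_ids, values)


def _default_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


def _require_binary(m, name: str) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if not np.isin(a, (0.0, 1.0)).all():
        raise ValueError(f"{name} must be a binary matrix")
    return a


# ---------------------------------------------------------------------------
# NBI
# ---------------------------------------------------------------------------

def apply_nbi(mt, row_ids=None, col_ids=None) -> WeightedMatrix:
    """Two-step mass diffusion on the bipartite miRNA-gene graph.

    Starting from row *i*'s unit resource on each of its target genes, each
    gene splits its resource equally among the miRNAs targeting it, then each
    miRNA splits what it received equally among its own targets.  Row sums
    are conserved; miRNAs with no targets yield all-zero rows.
    """
    a = _require_binary(mt, "mt")
    gene_deg = a.sum(axis=0)
    mirna_deg = a.sum(axis=1)
    inv_g = np.divide(1.0, gene_deg, out=np.zeros_like(gene_deg), where=gene_deg > 0)
    inv_m = np.divide(1.0, mirna_deg, out=np.zeros_like(mirna_deg), where=mirna_deg > 0)
    received = (a * inv_g) @ a.T          # resource landing on each miRNA
    weights = (received * inv_m) @ a      # redistributed back onto genes
    row_ids = list(row_ids) if row_ids is not None else _default_ids("m", a.shape[0])
    col_ids = list(col_ids) if col_ids is not None else _default_ids("g", a.shape[1])
    return WeightedMatrix(row_ids, col_ids, weights)


# ---------------------------------------------------------------------------
# TF-IDF
# ---------------------------------------------------------------------------

def apply_tfidf(word_counts, row_ids=None, word_ids=None) -> WeightedMatrix:
    """Weight raw term counts by ``count * ln(N / df)``.

    A *document* is a row with at least one word; ``N`` is the number of
    documents and ``df`` the number of documents containing the word.  Words
    absent from every document are dropped.  An empty document set yields a
    zero-column matrix.
    """
    counts = np.asarray(word_counts, dtype=float)
    if (counts < 0).any() or not np.isfinite(counts).all():
        raise ValueError("word counts must be non-negative and finite")
    row_ids = list(row_ids) if row_ids is not None else _default_ids("m", counts.shape[0])
    word_ids = list(word_ids) if word_ids is not None else _default_ids("w", counts.shape[1])

    is_doc = counts.sum(axis=1) > 0
    n_docs = int(is_doc.sum())
    df = (counts[is_doc] > 0).sum(axis=0) if n_docs else np.zeros(counts.shape[1])
    keep = df > 0
    if n_docs == 0 or not keep.any():
        return WeightedMatrix(row_ids, [], np.zeros((counts.shape[0], 0)))
    idf = np.log(n_docs / df[keep])
    weights = counts[:, keep] * idf
    kept_ids = [w for w, k in zip(word_ids, keep) if k]
    return WeightedMatrix(row_ids, kept_ids, weights)


def word_count_matrix(
    docs: dict[str, dict[str, int]], mirna_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Dense miRNA x word count matrix from per-miRNA word-count mappings."""
    vocab = sorted({w for counts in docs.values() for w in counts})
    out = np.zeros((len(mirna_ids), len(vocab)), dtype=float)
    w_idx = {w: j for j, w in enumerate(vocab)}
    for i, mid in enumerate(mirna_ids):
        for w, c in docs.get(mid, {}).items():
            out[i, w_idx[w]] = c
    return out, vocab


# ---------------------------------------------------------------------------
# Disease inference / similarity / discretization
# ---------------------------------------------------------------------------

def infer_diseases(md, disease_ids: list[str], hierarchy: DiseaseHierarchy) -> np.ndarray:
    """Propagate each annotation to every ancestor (broader) disease column.

    Idempotent and monotone (only adds 1s).  Disease columns whose term is
    absent from the hierarchy pass through untouched (logged).
    """
    a = _require_binary(md, "md").astype(np.int8)
    d_idx = {d: j for j, d in enumerate(disease_ids)}
    # closure[j, k] = 1 if column k is column j itself or an ancestor of it
    closure = np.eye(len(disease_ids), dtype=bool)
    for d, j in d_idx.items():
        if d not in hierarchy:
            logger.info("disease term %r absent from hierarchy; skipped by inference", d)
            continue
        for anc in hierarchy.ancestors(d):
            k = d_idx.get(anc)
            if k is not None:
                closure[j, k] = True
    return ((a.astype(bool) @ closure) > 0).astype(np.int8)


def _lenient_similarity(d1: str, d2: str, hierarchy: DiseaseHierarchy) -> float:
    # terms missing from the hierarchy are similar only to themselves
    if d1 == d2:
        return 1.0
    if d1 not in hierarchy or d2 not in hierarchy:
        return 0.0
    return hierarchy.similarity(d1, d2)


def disease_similarity(d1: str, d2: str, hierarchy: DiseaseHierarchy) -> float:
    """Ancestor-Dice similarity between two hierarchy terms (strict lookup)."""
    return hierarchy.similarity(d1, d2)


def association_weight(
    mirna: str,
    disease: str,
    md,
    mirna_ids: list[str],
    disease_ids: list[str],
    hierarchy: DiseaseHierarchy,
    exclude_disease: str | None = None,
) -> float:
    """Strength m in [0, 1] of the (miRNA, disease) association.

    m is the maximum similarity between *disease* and any disease annotated
    to the miRNA (0 if the miRNA has no annotations).  ``exclude_disease``
    drops one disease's annotations from the maximisation, as required by the
    cross-validation protocol.
    """
    a = _require_binary(md, "md")
    try:
        i = mirna_ids.index(mirna)
    except ValueError:
        raise KeyError(f"unknown miRNA: {mirna!r}") from None
    if disease not in disease_ids:
        raise KeyError(f"unknown disease: {disease!r}")
    best = 0.0
    for j, d in enumerate(disease_ids):
        if a[i, j] and d != exclude_disease:
            best = max(best, _lenient_similarity(disease, d, hierarchy))
    return best


def discretize(m: float, cutoffs) -> set[str]:
    """Map m in [0, 1] onto overlapping indicator bins.

    Returns ``{"no_assoc"}`` when m is below the smallest cutoff, otherwise
    one ``">=c"`` indicator per cutoff ``c <= m`` (values exactly at a cutoff
    go to the upper bin).
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"association weight {m} outside [0, 1]")
    cutoffs = tuple(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly increasing")
    if not cutoffs or m < cutoffs[0]:
        return {NO_ASSOC}
    return {f">={c:g}" for c in cutoffs if m >= c}


# ---------------------------------------------------------------------------
# Genomic neighbours
# ---------------------------------------------------------------------------

def neighbor_weights(
    coords: dict[str, Coord],
    mirna_ids: list[str],
    window: float = DEFAULT_NEIGHBOR_WINDOW,
) -> WeightedMatrix:
    """Symmetric miRNA x miRNA proximity weights.

    ``w_ij = max(0, 1 - |start_i - start_j| / window)`` when the chromosomes
    match, else 0; the diagonal is forced to 0.  miRNAs without coordinates
    get all-zero rows (logged).
    """
    n = len(mirna_ids)
    chroms = np.array([coords[m].chrom if m in coords else "" for m in mirna_ids])
    starts = np.array([coords[m].start if m in coords else 0 for m in mirna_ids], dtype=float)
    missing = [m for m in mirna_ids if m not in coords]
    if missing:
        logger.info("no genomic coordinates for %d miRNA(s): %s", len(missing), missing[:5])
    same_chrom = (chroms[:, None] == chroms[None, :]) & (chroms[:, None] != "")
    dist = np.abs(starts[:, None] - starts[None, :])
    w = np.where(same_chrom, np.maximum(0.0, 1.0 - dist / float(window)), 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightedMatrix(list(mirna_ids), [f"nbr:{m}" for m in mirna_ids], w)


# ---------------------------------------------------------------------------
# Disease block
# ---------------------------------------------------------------------------

def _pairwise_similarity(disease_ids: list[str], hierarchy: DiseaseHierarchy) -> np.ndarray:
    d = len(disease_ids)
    s = np.eye(d)
    for j in range(d):
        for k in range(j + 1, d):
            s[j, k] = s[k, j] = _lenient_similarity(disease_ids[j], disease_ids[k], hierarchy)
    return s


def build_disease_block(
    md,
    disease_ids: list[str],
    hierarchy: DiseaseHierarchy,
    config,
    mirna_ids: list[str] | None = None,
    exclude_similarity_for: str | None = None,
) -> WeightedMatrix:
    """The mandatory disease block of the assembled matrix.

    With ``config.infer_in_matrix`` the annotations are first propagated to
    ancestor diseases.  With an empty cutoff set the (possibly inferred)
    binary MD matrix is returned as-is; otherwise each (miRNA, disease) pair
    is scored with :func:`association_weight` and expanded into the
    overlapping indicator bins of :func:`discretize`, one column per
    disease x bin.  ``exclude_similarity_for`` removes one disease's
    annotations from the similarity augmentation (cross-validation masking).
    """
    a = _require_binary(md, "md")
    n, d = a.shape
    if mirna_ids is None:
        mirna_ids = _default_ids("m", n)
    if config.infer_in_matrix:
        a = infer_diseases(a, disease_ids, hierarchy).astype(float)
    cutoffs = tuple(config.cutoffs)
    if not cutoffs:
        return WeightedMatrix(list(mirna_ids), [f"disease:{t}" for t in disease_ids], a)

    if any(b <= x for x, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly increasing")
    sim = _pairwise_similarity(disease_ids, hierarchy)
    annotated = a.astype(bool).copy()
    if exclude_similarity_for is not None and exclude_similarity_for in disease_ids:
        annotated[:, disease_ids.index(exclude_similarity_for)] = False
    # m[i, t] = max over annotated diseases j of sim(j, t)
    m = np.zeros((n, d))
    for j in range(d):
        col = annotated[:, j]
        if col.any():
            m[col] = np.maximum(m[col], sim[j][None, :])

    bins = [NO_ASSOC] + [f">={c:g}" for c in cutoffs]
    col_ids = [f"disease:{t}@{b}" for t in disease_ids for b in bins]
    values = np.zeros((n, d * len(bins)))
    for t in range(d):
        base = t * len(bins)
        values[:, base] = (m[:, t] < cutoffs[0]).astype(float)
        for k, c in enumerate(cutoffs, start=1):
            values[:, base + k] = (m[:, t] >= c).astype(float)
    return WeightedMatrix(list(mirna_ids), col_ids, values)
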