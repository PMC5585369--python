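"""Latent semantic analysis of the concatenated source matrices.

The selected weighted blocks are concatenated column-wise (disease block
first, then targets, family, neighbours and the three text sources), the
result is factorised with a truncated SVD ``M ~ U S V^T``, and both miRNAs
(rows, ``U S``) and features (columns, ``V S``) are embedded in the same
reduced space.  A disease is queried by taking the centroid of its feature
vectors and ranking miRNAs by cosine similarity to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse.linalg
from sklearn.base import BaseEstimator

from .dataset import TEXT_SOURCES, MirnaDataset
from .encoding import Configuration
from .hierarchy import DiseaseHierarchy
from .sources import (
    DEFAULT_NEIGHBOR_WINDOW,
    NO_ASSOC,
    WeightedMatrix,
    apply_nbi,
    apply_tfidf,
    build_disease_block,
    neighbor_weights,
    word_count_matrix,
)

__all__ = [
    "LatentSpace",
    "assemble",
    "build_latent",
    "query_disease",
    "save_latent",
    "load_latent",
    "MiraiModel",
]

#: below this size the exact dense SVD is used instead of the sparse solver
_DENSE_LIMIT = 200


@dataclass
class LatentSpace:
    """miRNA and feature embeddings in the reduced SVD space."""

    dim: int
    mirna_ids: list[str]
    col_ids: list[str]
    mirna_vectors: np.ndarray     # (n_mirnas, dim) = U S
    feature_vectors: np.ndarray   # (n_features, dim) = V S
    singular_values: np.ndarray

    def __post_init__(self):
        if self.mirna_vectors.shape != (len(self.mirna_ids), self.dim):
            raise ValueError("miRNA vector block does not match dim")
        if self.feature_vectors.shape != (len(self.col_ids), self.dim):
            raise ValueError("feature vector block does not match dim")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble(
    dataset: MirnaDataset,
    config: Configuration,
    exclude_similarity_for: str | None = None,
    neighbor_window: float = DEFAULT_NEIGHBOR_WINDOW,
) -> WeightedMatrix:
    """Concatenate the configured source blocks into one weighted matrix.

    The disease block is always present; the other blocks follow in fixed
    order (targets, family, neighbours, pubmed, mirbase abstracts, mirbase
    descriptions) when their source flag is set.  Transform flags whose
    source flag is off have no effect.  Raises ``ValueError`` naming the
    source if a selected source is absent from the dataset.
    """
    blocks = [
        build_disease_block(
            dataset.md,
            dataset.disease_ids,
            dataset.hierarchy,
            config,
            mirna_ids=dataset.mirna_ids,
            exclude_similarity_for=exclude_similarity_for,
        )
    ]
    if config.use_targets:
        if dataset.mt is None or dataset.mt.shape[1] == 0:
            raise ValueError("selected source 'targets' missing from dataset")
        if config.nbi_on_targets:
            block = apply_nbi(dataset.mt, dataset.mirna_ids, dataset.gene_ids)
            block.col_ids = [f"gene:{g}" for g in dataset.gene_ids]
        else:
            block = WeightedMatrix(
                list(dataset.mirna_ids),
                [f"gene:{g}" for g in dataset.gene_ids],
                dataset.mt.astype(float),
            )
        blocks.append(block)
    if config.use_family:
        if dataset.mf is None or dataset.mf.shape[1] == 0:
            raise ValueError("selected source 'family' missing from dataset")
        blocks.append(
            WeightedMatrix(
                list(dataset.mirna_ids),
                [f"fam:{f}" for f in dataset.family_ids],
                dataset.mf.astype(float),
            )
        )
    if config.use_neighbors:
        if not dataset.coords:
            raise ValueError("selected source 'neighbors' missing from dataset")
        blocks.append(neighbor_weights(dataset.coords, dataset.mirna_ids, neighbor_window))

    text_flags = {
        "pubmed": (config.use_pubmed, config.tfidf_pubmed),
        "mirbase_abstract": (config.use_mirbase_abstracts, config.tfidf_mirbase_abstracts),
        "mirbase_description": (config.use_mirbase_description, config.tfidf_mirbase_description),
    }
    for source in TEXT_SOURCES:
        use, tfidf = text_flags[source]
        if not use:
            continue
        per_mirna = dataset.docs.get(source) or {}
        if not per_mirna:
            raise ValueError(f"selected source {source!r} missing from dataset")
        counts, vocab = word_count_matrix(per_mirna, dataset.mirna_ids)
        if tfidf:
            block = apply_tfidf(counts, dataset.mirna_ids, vocab)
            block.col_ids = [f"word:{source}:{w}" for w in block.col_ids]
        else:
            block = WeightedMatrix(
                list(dataset.mirna_ids), [f"word:{source}:{w}" for w in vocab], counts
            )
        blocks.append(block)
    return WeightedMatrix.hstack(blocks)


# ---------------------------------------------------------------------------
# Truncated SVD
# ---------------------------------------------------------------------------

def _fix_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic sign convention: the largest-magnitude component of each
    # left singular vector is made positive
    for k in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, k])))
        if u[i, k] < 0:
            u[:, k] = -u[:, k]
            v[:, k] = -v[:, k]
    return u, v


def build_latent(matrix: WeightedMatrix, dim: int) -> LatentSpace:
    """Truncated SVD embedding of rows and columns in one space.

    ``dim`` is clamped (with a warning) to ``min(rows, cols)`` when the
    matrix is smaller than the requested dimension.  Deterministic: the sign
    convention fixes the decomposition, and the dense exact SVD is used for
    matrices below 200 x 200.
    """
    m = matrix.values
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if not m.any():
        raise ValueError("cannot build a latent space from an all-zero matrix")
    max_dim = min(m.shape)
    k = dim
    if k > max_dim:
        warnings.warn(
            f"requested dimension {dim} exceeds matrix rank bound {max_dim}; clamping",
            stacklevel=2,
        )
        k = max_dim
    if max_dim <= _DENSE_LIMIT or k >= max_dim - 1:
        u, s, vt = np.linalg.svd(m, full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    else:
        u, s, vt = scipy.sparse.linalg.svds(
            scipy.sparse.csr_matrix(m), k=k, v0=np.ones(m.shape[1])
        )
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    u, vt_t = _fix_signs(u.copy(), vt.T.copy())
    return LatentSpace(
        dim=k,
        mirna_ids=list(matrix.row_ids),
        col_ids=list(matrix.col_ids),
        mirna_vectors=u * s,
        feature_vectors=vt_t * s,
        singular_values=s,
    )


# ---------------------------------------------------------------------------
# Query
# ---------------------------------------------------------------------------

def _positive_disease_columns(col_ids: list[str], disease: str) -> list[int]:
    exact = f"disease:{disease}"
    prefix = f"disease:{disease}@"
    cols = []
    for j, c in enumerate(col_ids):
        if c == exact or (c.startswith(prefix) and not c.endswith(f"@{NO_ASSOC}")):
            cols.append(j)
    return cols


def disease_query_vector(
    space: LatentSpace,
    disease: str,
    expand: bool = False,
    hierarchy: DiseaseHierarchy | None = None,
) -> np.ndarray:
    """Centroid of the disease's positive-bin feature vectors.

    With ``expand`` the centroid also averages the columns of every
    descendant (more specific) disease present in the space.
    """
    cols = _positive_disease_columns(space.col_ids, disease)
    if expand:
        if hierarchy is None:
            raise ValueError("query expansion requires a disease hierarchy")
        if disease in hierarchy:
            for child in sorted(hierarchy.descendants(disease)):
                cols.extend(_positive_disease_columns(space.col_ids, child))
    if not cols:
        raise ValueError(f"unknown disease: {disease!r} (no feature column in the space)")
    return space.feature_vectors[cols].mean(axis=0)


def _cosines(vectors: np.ndarray, query: np.ndarray) -> np.ndarray:
    qn = float(np.linalg.norm(query))
    vn = np.linalg.norm(vectors, axis=1)
    if qn == 0.0:
        return np.zeros(len(vectors))
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = vectors @ query / (vn * qn)
    return np.where(vn > 0, scores, 0.0)


def query_disease(
    space: LatentSpace,
    disease: str,
    expand: bool = False,
    hierarchy: DiseaseHierarchy | None = None,
) -> list[tuple[str, float]]:
    """miRNAs ranked by descending cosine to the disease query vector.

    Ties are broken by miRNA identifier (stable, reproducible ordering).
    """
    query = disease_query_vector(space, disease, expand=expand, hierarchy=hierarchy)
    scores = _cosines(space.mirna_vectors, query)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], space.mirna_ids[i]))
    return [(space.mirna_ids[i], float(scores[i])) for i in order]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_latent(space: LatentSpace, path: str | Path) -> None:
    """Archive a latent space as a single ``.npz`` file.

    Layout: ``dim`` (scalar), ``mirna_ids``/``col_ids`` (string arrays),
    ``mirna_vectors``/``feature_vectors`` (float64 blocks),
    ``singular_values``.
    """
    np.savez(
        path,
        dim=space.dim,
        mirna_ids=np.array(space.mirna_ids),
        col_ids=np.array(space.col_ids),
        mirna_vectors=space.mirna_vectors,
        feature_vectors=space.feature_vectors,
        singular_values=space.singular_values,
    )


def load_latent(path: str | Path) -> LatentSpace:
    with np.load(path, allow_pickle=False) as z:
        return LatentSpace(
            dim=int(z["dim"]),
            mirna_ids=[str(s) for s in z["mirna_ids"]],
            col_ids=[str(s) for s in z["col_ids"]],
            mirna_vectors=z["mirna_vectors"],
            feature_vectors=z["feature_vectors"],
            singular_values=z["singular_values"],
        )


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class MiraiModel(BaseEstimator):
    """Latent-semantic miRNA-disease association predictor.

    scikit-learn-style estimator: ``fit`` assembles the configured weighted
    matrix from a :class:`~mirlsa.dataset.MirnaDataset` and builds the latent
    space; ``rank_disease`` returns the cosine-ranked miRNA list for a
    disease; ``transform`` exposes the fitted miRNA embedding.

    Parameters
    ----------
    config
        Decoded :class:`~mirlsa.encoding.Configuration`; ``None`` means the
        all-defaults configuration (disease block only, dim 50).
    neighbor_window
        Window in bp for the genomic-neighbour weighting.
    """

    def __init__(self, config: Configuration | None = None,
                 neighbor_window: float = DEFAULT_NEIGHBOR_WINDOW):
        self.config = config
        self.neighbor_window = neighbor_window

    def fit(self, dataset: MirnaDataset, y=None) -> "MiraiModel":
        config = self.config if self.config is not None else Configuration()
        self.config_ = config
        self.hierarchy_ = dataset.hierarchy
        self.matrix_ = assemble(dataset, config, neighbor_window=self.neighbor_window)
        self.space_ = build_latent(self.matrix_, config.dim)
        return self

    def _check_fitted(self):
        if not hasattr(self, "space_"):
            raise RuntimeError("MiraiModel is not fitted; call fit(dataset) first")

    def rank_disease(self, disease: str) -> list[tuple[str, float]]:
        self._check_fitted()
        return query_disease(
            self.space_, disease, expand=self.config_.expand_query, hierarchy=self.hierarchy_
        )

    def transform(self, dataset: MirnaDataset | None = None) -> np.ndarray:
        """The fitted miRNA embedding (rows follow ``space_.mirna_ids``)."""
        self._check_fitted()
        return self.space_.mirna_vectors
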