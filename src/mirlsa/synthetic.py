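"""Synthetic datasets with planted, recoverable co-cluster structure.

The generator partitions miRNAs, diseases, genes and families into groups
and draws every source from the same low-rank block signal plus Bernoulli
noise: miRNA-disease and miRNA-gene links appear with probability ``p_in``
inside a group and ``p_out`` across groups, families and genomic clusters
are group-determined, documents share group-specific vocabulary, and a
disease hierarchy nests each group's diseases under a broader group term.
A configurable number of deliberately wrong cross-group associations is
injected (for testing invalidation) and a configurable number of genuine
within-group associations is deleted (for testing novel-association
recovery); both are recorded in the returned ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .dataset import Coord, MirnaDataset, TEXT_SOURCES
from .encoding import GENOME_LENGTH
from .hierarchy import DiseaseHierarchy

__all__ = [
    "PlantedSpec",
    "GroundTruth",
    "generate",
    "benchmark_fitness",
    "shuffle_associations",
    "TINY_SPEC",
]


@dataclass(frozen=True)
class PlantedSpec:
    """Generator settings; the defaults define the standard study fixture."""

    n_mirnas: int = 60
    n_diseases: int = 12
    n_genes: int = 40
    n_families: int = 8
    n_groups: int = 4
    p_in: float = 0.7
    p_out: float = 0.02
    hierarchy_depth: int = 2
    cluster_span: int = 50_000
    doc_vocab: int = 120
    doc_length: int = 50
    n_planted_errors: int = 1
    n_held_out: int = 1
    seed: int = 42

    def validate(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        for n, what in (
            (self.n_mirnas, "miRNAs"),
            (self.n_diseases, "diseases"),
            (self.n_genes, "genes"),
            (self.n_families, "families"),
        ):
            if n < self.n_groups:
                raise ValueError(f"fewer {what} ({n}) than groups ({self.n_groups})")
        if self.hierarchy_depth < 1:
            raise ValueError("hierarchy_depth must be >= 1")
        if self.p_in * (self.n_mirnas // self.n_groups) < 5:
            raise ValueError(
                "infeasible spec: expected within-group associations per disease "
                f"({self.p_in * (self.n_mirnas // self.n_groups):.1f}) below 5"
            )


#: smaller fixture for fast CLI smoke runs
TINY_SPEC = PlantedSpec(
    n_mirnas=20,
    n_diseases=6,
    n_genes=12,
    n_families=4,
    n_groups=2,
    doc_vocab=40,
    doc_length=20,
)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery tests."""

    mirna_groups: dict[str, int]
    disease_groups: dict[str, int]
    gene_groups: dict[str, int]
    planted_errors: list[tuple[str, str]]   # (mirna, disease) wrong cross-group links
    held_out: list[tuple[str, str]]         # (mirna, disease) deleted genuine links


def _group_split(n: int, n_groups: int) -> list[np.ndarray]:
    return np.array_split(np.arange(n), n_groups)


def _block_bernoulli(
    rng: np.random.Generator,
    row_groups: np.ndarray,
    col_groups: np.ndarray,
    p_in: float,
    p_out: float,
) -> np.ndarray:
    probs = np.where(row_groups[:, None] == col_groups[None, :], p_in, p_out)
    return (rng.random(probs.shape) < probs).astype(np.int8)


def generate(spec: PlantedSpec = PlantedSpec()) -> tuple[MirnaDataset, GroundTruth]:
    """Draw a dataset with planted group structure; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    mirna_ids = [f"mir-{i:03d}" for i in range(spec.n_mirnas)]
    disease_ids = [f"disease_{j:02d}" for j in range(spec.n_diseases)]
    gene_ids = [f"gene{k:03d}" for k in range(spec.n_genes)]
    family_ids = [f"fam{k:02d}" for k in range(spec.n_families)]

    def groups_of(n: int) -> np.ndarray:
        out = np.empty(n, dtype=int)
        for g, idx in enumerate(_group_split(n, spec.n_groups)):
            out[idx] = g
        return out

    m_grp = groups_of(spec.n_mirnas)
    d_grp = groups_of(spec.n_diseases)
    g_grp = groups_of(spec.n_genes)
    f_grp = groups_of(spec.n_families)

    md = _block_bernoulli(rng, m_grp, d_grp, spec.p_in, spec.p_out)
    mt = _block_bernoulli(rng, m_grp, g_grp, spec.p_in, spec.p_out)

    # families: one per miRNA, drawn from the own group with high probability
    mf = np.zeros((spec.n_mirnas, spec.n_families), dtype=np.int8)
    for i in range(spec.n_mirnas):
        own = np.flatnonzero(f_grp == m_grp[i])
        fam = rng.choice(own) if rng.random() < 0.95 else rng.integers(spec.n_families)
        mf[i, fam] = 1

    # genomic clusters: one chromosome per group, starts within cluster_span
    coords: dict[str, Coord] = {}
    for i, mid in enumerate(mirna_ids):
        g = m_grp[i]
        start = int(1_000_000 * (g + 1) + rng.integers(0, spec.cluster_span + 1))
        coords[mid] = Coord(f"chr{g + 1}", start, start + int(rng.integers(60, 100)), rng.choice(["+", "-"]))

    # documents: group vocabulary plus a shared noise block
    per_group = max(spec.doc_vocab // (spec.n_groups + 1), 3)
    group_vocab = [
        [f"biogroup{g}term{k:02d}" for k in range(per_group)] for g in range(spec.n_groups)
    ]
    shared_vocab = [f"commonterm{k:02d}" for k in range(per_group)]
    docs: dict[str, dict[str, dict[str, int]]] = {s: {} for s in TEXT_SOURCES}
    for source in TEXT_SOURCES:
        for i, mid in enumerate(mirna_ids):
            vocab = group_vocab[m_grp[i]] + shared_vocab
            probs = np.concatenate(
                [np.full(per_group, 0.8 / per_group), np.full(per_group, 0.2 / per_group)]
            )
            counts = rng.multinomial(spec.doc_length, probs)
            docs[source][mid] = {
                w: int(c) for w, c in zip(vocab, counts) if c > 0
            }

    # hierarchy: root -> (chain of intermediates) -> group term -> leaf
    terms = set(disease_ids) | {"all_disease"}
    edges: list[tuple[str, str]] = []
    for g in range(spec.n_groups):
        chain = ["all_disease"]
        for level in range(spec.hierarchy_depth - 1):
            node = f"group{g}_level{level}"
            terms.add(node)
            chain.append(node)
        for a, b in zip(chain, chain[1:]):
            edges.append((a, b))
        parent = chain[-1]
        for j in np.flatnonzero(d_grp == g):
            edges.append((parent, disease_ids[j]))
    hierarchy = DiseaseHierarchy(terms, edges)

    # planted wrong associations: a strongly in-group miRNA annotated to a
    # "pure" disease of another group
    planted: list[tuple[str, str]] = []
    used_m: set[int] = set()
    used_d: set[int] = set()
    cross_free_m = md.copy()
    for _ in range(spec.n_planted_errors):
        pure_d = [
            j
            for j in range(spec.n_diseases)
            if j not in used_d
            and not md[m_grp != d_grp[j], j].any()
        ]
        if not pure_d:
            pure_d = [j for j in range(spec.n_diseases) if j not in used_d]
        # strongest pure disease: most annotations -> tightest query centroid,
        # so the injected inconsistency is maximally recoverable
        j = pure_d[int(np.argmax([md[:, jj].sum() for jj in pure_d]))]
        candidates = [
            i
            for i in range(spec.n_mirnas)
            if i not in used_m
            and m_grp[i] != d_grp[j]
            and not cross_free_m[i, d_grp != m_grp[i]].any()
        ]
        if not candidates:
            candidates = [i for i in range(spec.n_mirnas) if m_grp[i] != d_grp[j]]
        # choose the candidate with the highest within-group degree
        degrees = [md[i, d_grp == m_grp[i]].sum() for i in candidates]
        i = candidates[int(np.argmax(degrees))]
        md[i, j] = 1
        planted.append((mirna_ids[i], disease_ids[j]))
        used_m.add(i)
        used_d.add(j)

    # held-out genuine associations: delete recoverable within-group links
    held: list[tuple[str, str]] = []
    planted_set = set(planted)
    for _ in range(spec.n_held_out):
        eligible = [
            (i, j)
            for i in range(spec.n_mirnas)
            for j in range(spec.n_diseases)
            if md[i, j]
            and m_grp[i] == d_grp[j]
            and (mirna_ids[i], disease_ids[j]) not in planted_set
            and (mirna_ids[i], disease_ids[j]) not in set(held)
            and md[:, j].sum() > 5
            and md[i, d_grp == m_grp[i]].sum() > 2
        ]
        if not eligible:
            break
        i, j = eligible[int(rng.integers(len(eligible)))]
        md[i, j] = 0
        held.append((mirna_ids[i], disease_ids[j]))

    dataset = MirnaDataset(
        mirna_ids=mirna_ids,
        disease_ids=disease_ids,
        md=md,
        gene_ids=gene_ids,
        mt=mt,
        family_ids=family_ids,
        mf=mf,
        coords=coords,
        docs=docs,
        hierarchy=hierarchy,
    )
    truth = GroundTruth(
        mirna_groups=dict(zip(mirna_ids, m_grp.tolist())),
        disease_groups=dict(zip(disease_ids, d_grp.tolist())),
        gene_groups=dict(zip(gene_ids, g_grp.tolist())),
        planted_errors=planted,
        held_out=held,
    )
    return dataset, truth


def shuffle_associations(md: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Null model: permute each disease column independently.

    Preserves per-disease association counts but destroys the coherence of
    each miRNA's annotation profile, so ranked retrieval should be random.
    """
    out = np.asarray(md).copy()
    for j in range(out.shape[1]):
        out[:, j] = out[rng.permutation(out.shape[0]), j]
    return out


# ---------------------------------------------------------------------------
# Benchmark fitness functions for optimizer testing
# ---------------------------------------------------------------------------

def _hash_noise(genome: np.ndarray, seed: int, amplitude: float) -> float:
    digest = hashlib.blake2b(
        np.asarray(genome, dtype=np.int8).tobytes() + seed.to_bytes(8, "little"),
        digest_size=8,
    ).digest()
    u = int.from_bytes(digest, "little") / 2**64  # in [0, 1)
    return amplitude * (2.0 * u - 1.0)


def benchmark_fitness(name: str, seed: int = 0):
    """Pure, seed-deterministic benchmark functions on 35-bit genomes.

    * ``onemax`` — number of ones; optimum 35 at the all-ones genome.
    * ``leading_ones`` — length of the leading run of ones; optimum 35.
    * ``noisy_quadratic`` — smooth unimodal ``1 - ((s - 29) / 35)**2`` of the
      bit sum *s*, plus a +-0.005 deterministic per-genome perturbation;
      optimum ~1 at genomes with 29 ones (well away from the random-init mean
      of 17.5, so reaching it requires actual optimization).
    """
    if name == "onemax":
        return lambda g: float(np.sum(g))
    if name == "leading_ones":
        def leading_ones(g):
            g = np.asarray(g).ravel()
            nz = np.flatnonzero(g == 0)
            return float(nz[0]) if len(nz) else float(g.size)

        return leading_ones
    if name == "noisy_quadratic":
        def noisy_quadratic(g):
            s = float(np.sum(g))
            base = 1.0 - ((s - 29.0) / GENOME_LENGTH) ** 2
            return base + _hash_noise(np.asarray(g), seed, 0.005)

        return noisy_quadratic
    raise ValueError(f"unknown benchmark fitness: {name!r}")
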