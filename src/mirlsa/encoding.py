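"""Bijective mapping between the 35-bit tuning genome and a configuration.

Bit layout (1-based positions):

====== ==================================================================
bits   meaning
====== ==================================================================
1-6    include source: targets, family, neighbours, pubmed,
       mirbase abstracts, mirbase description
7      apply NBI to the target links
8-10   apply TF-IDF to pubmed / mirbase abstracts / mirbase description
11     infer subsumed diseases in the matrix
12-30  discretization cutoffs: bit 11+k toggles cutoff 0.05*k (k = 1..19)
31-34  latent dimension: 4-bit reflected-binary (Gray) field, bit 31 most
       significant; dim = 50 * (gray_to_int(bits) + 1), spanning 50..800
35     expand the query with subsumed (descendant) diseases
====== ==================================================================

The disease-association source is mandatory and has no bit.  Transform bits
whose source bit is off are preserved by :func:`decode` (so that
``encode(decode(g)) == g``) and ignored at assembly time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GENOME_LENGTH",
    "CUTOFF_GRID",
    "DIM_GRID",
    "Configuration",
    "decode",
    "encode",
    "gray_to_int",
    "int_to_gray",
    "genome_from_string",
    "genome_to_string",
    "random_genome",
]

GENOME_LENGTH = 35
CUTOFF_GRID = tuple(round(0.05 * k, 2) for k in range(1, 20))
DIM_GRID = tuple(50 * k for k in range(1, 17))
_GRAY_WIDTH = 4


@dataclass(frozen=True)
class Configuration:
    """Decoded parameter set controlling matrix assembly and the query."""

    use_targets: bool = False
    use_family: bool = False
    use_neighbors: bool = False
    use_pubmed: bool = False
    use_mirbase_abstracts: bool = False
    use_mirbase_description: bool = False
    nbi_on_targets: bool = False
    tfidf_pubmed: bool = False
    tfidf_mirbase_abstracts: bool = False
    tfidf_mirbase_description: bool = False
    infer_in_matrix: bool = False
    cutoffs: tuple[float, ...] = ()
    dim: int = 50
    expand_query: bool = False

    def __post_init__(self):
        object.__setattr__(self, "cutoffs", tuple(sorted(self.cutoffs)))


def _validate_bits(bits, width: int) -> np.ndarray:
    a = np.asarray(bits, dtype=np.int8).ravel()
    if a.size != width:
        raise ValueError(f"expected {width} bits, got {a.size}")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("bits must be 0 or 1")
    return a


def gray_to_int(bits) -> int:
    """Reflected-binary-code to integer; first bit is most significant."""
    a = _validate_bits(bits, _GRAY_WIDTH)
    n = 0
    bit = 0
    for g in a:
        bit ^= int(g)
        n = (n << 1) | bit
    return n


def int_to_gray(n: int) -> np.ndarray:
    """Integer in [0, 15] to its 4-bit reflected binary code."""
    if not 0 <= n < 2 ** _GRAY_WIDTH:
        raise ValueError(f"value {n} outside [0, {2 ** _GRAY_WIDTH - 1}]")
    g = n ^ (n >> 1)
    return np.array([(g >> k) & 1 for k in reversed(range(_GRAY_WIDTH))], dtype=np.int8)


def decode(genome) -> Configuration:
    """Decode a 35-bit genome into a :class:`Configuration`."""
    bits = _validate_bits(genome, GENOME_LENGTH)
    flags = bits[:11].astype(bool)
    cutoffs = tuple(c for c, b in zip(CUTOFF_GRID, bits[11:30]) if b)
    dim = 50 * (gray_to_int(bits[30:34]) + 1)
    return Configuration(
        use_targets=bool(flags[0]),
        use_family=bool(flags[1]),
        use_neighbors=bool(flags[2]),
        use_pubmed=bool(flags[3]),
        use_mirbase_abstracts=bool(flags[4]),
        use_mirbase_description=bool(flags[5]),
        nbi_on_targets=bool(flags[6]),
        tfidf_pubmed=bool(flags[7]),
        tfidf_mirbase_abstracts=bool(flags[8]),
        tfidf_mirbase_description=bool(flags[9]),
        infer_in_matrix=bool(flags[10]),
        cutoffs=cutoffs,
        dim=dim,
        expand_query=bool(bits[34]),
    )


def encode(config: Configuration) -> np.ndarray:
    """Inverse of :func:`decode`; raises on values off the encoding grid."""
    if config.dim not in DIM_GRID:
        raise ValueError(f"dim must be a multiple of 50 in [50, 800], got {config.dim}")
    grid = {c: k for k, c in enumerate(CUTOFF_GRID)}
    bits = np.zeros(GENOME_LENGTH, dtype=np.int8)
    bits[:11] = [
        config.use_targets,
        config.use_family,
        config.use_neighbors,
        config.use_pubmed,
        config.use_mirbase_abstracts,
        config.use_mirbase_description,
        config.nbi_on_targets,
        config.tfidf_pubmed,
        config.tfidf_mirbase_abstracts,
        config.tfidf_mirbase_description,
        config.infer_in_matrix,
    ]
    for c in config.cutoffs:
        k = grid.get(round(float(c), 2))
        if k is None or abs(c - CUTOFF_GRID[k]) > 1e-9:
            raise ValueError(f"cutoff {c} is not on the 0.05 grid")
        bits[11 + k] = 1
    bits[30:34] = int_to_gray(config.dim // 50 - 1)
    bits[34] = config.expand_query
    return bits


def genome_from_string(s: str) -> np.ndarray:
    """Parse a 35-character 0/1 literal (bit 1 leftmost)."""
    s = s.strip()
    if len(s) != GENOME_LENGTH or set(s) - {"0", "1"}:
        raise ValueError(f"genome literal must be {GENOME_LENGTH} characters of 0/1")
    return np.array([int(c) for c in s], dtype=np.int8)


def genome_to_string(genome) -> str:
    return "".join(str(int(b)) for b in _validate_bits(genome, GENOME_LENGTH))


def random_genome(rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 2, size=GENOME_LENGTH, dtype=np.int8)
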