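"""Disease vocabulary as a rooted DAG (MeSH-style) with semantic similarity.

Edges run parent -> child, i.e. from the broader term to the more specific
one.  Similarity between two terms is an ancestor-Dice coefficient computed
on the sets of ancestors (self-inclusive, root-exclusive): terms that share
no non-root ancestor are maximally dissimilar, a term is identical to itself.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx

__all__ = ["DiseaseHierarchy"]


class DiseaseHierarchy:
    """A directed acyclic hierarchy of disease terms.

    Parameters
    ----------
    terms
        All term labels, including any that never appear in an edge.
    edges
        ``(parent, child)`` pairs; every endpoint must be in *terms*.
    """

    def __init__(self, terms: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for parent, child in edges:
            if parent not in g or child not in g:
                raise ValueError(f"hierarchy edge endpoint not declared as a term: {(parent, child)!r}")
            g.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("disease hierarchy contains a cycle")
        self._g = g
        self._roots = frozenset(n for n in g if g.in_degree(n) == 0)
        self._anchor_cache: dict[str, frozenset[str]] = {}

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "DiseaseHierarchy":
        edges = list(edges)
        terms = {t for e in edges for t in e}
        return cls(terms, edges)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def roots(self) -> frozenset[str]:
        return self._roots

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def _check(self, term: str) -> None:
        if term not in self._g:
            raise KeyError(f"unknown disease term: {term!r}")

    def ancestors(self, term: str, include_self: bool = False) -> set[str]:
        """Transitive parents (broader terms) of *term*."""
        self._check(term)
        anc = set(nx.ancestors(self._g, term))
        if include_self:
            anc.add(term)
        return anc

    def descendants(self, term: str) -> set[str]:
        """Transitive children (more specific terms) of *term*."""
        self._check(term)
        return set(nx.descendants(self._g, term))

    def _anchors(self, term: str) -> frozenset[str]:
        # self-inclusive, root-exclusive ancestor set used by the Dice similarity
        cached = self._anchor_cache.get(term)
        if cached is None:
            cached = frozenset(self.ancestors(term, include_self=True) - self._roots)
            self._anchor_cache[term] = cached
        return cached

    def similarity(self, d1: str, d2: str) -> float:
        """Ancestor-Dice similarity in [0, 1].

        ``sim(d, d) = 1``; terms whose (self-inclusive, root-exclusive)
        ancestor sets are disjoint score 0.
        """
        self._check(d1)
        self._check(d2)
        if d1 == d2:
            return 1.0
        a, b = self._anchors(d1), self._anchors(d2)
        denom = len(a) + len(b)
        if denom == 0:
            return 0.0
        return 2.0 * len(a & b) / denom
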