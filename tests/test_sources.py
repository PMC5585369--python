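"""Per-source matrix transforms: NBI diffusion, TF-IDF, disease similarity,
discretization and genomic neighbour weighting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirlsa.dataset import Coord
from mirlsa.encoding import Configuration
from mirlsa.hierarchy import DiseaseHierarchy
from mirlsa.sources import (
    apply_nbi,
    apply_tfidf,
    association_weight,
    build_disease_block,
    discretize,
    disease_similarity,
    infer_diseases,
    neighbor_weights,
)


class TestNBI:
    def test_two_step_diffusion_hand_example(self):
        # m1 -> {g1, g2}, m2 -> {g2, g3}: step 1 gives m1 = 1.5, m2 = 0.5,
        # step 2 redistributes to (0.75, 1.0, 0.25) on m1's row
        mt = np.array([[1, 1, 0], [0, 1, 1]])
        wm = apply_nbi(mt)
        np.testing.assert_allclose(wm.values[0], [0.75, 1.0, 0.25])
        np.testing.assert_allclose(wm.values[1], [0.25, 1.0, 0.75])

    def test_single_link_is_fixed_point(self):
        np.testing.assert_allclose(apply_nbi(np.array([[1]])).values, [[1.0]])

    def test_empty_row_stays_zero(self):
        wm = apply_nbi(np.array([[1, 1], [0, 0]]))
        np.testing.assert_array_equal(wm.values[1], [0.0, 0.0])

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            apply_nbi(np.array([[0.5, 1.0]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_conservation_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        mt = (rng.random((12, 17)) < 0.3).astype(int)
        wm = apply_nbi(mt)
        np.testing.assert_allclose(wm.values.sum(axis=1), mt.sum(axis=1), atol=1e-12)


class TestTfidf:
    def test_ubiquitous_word_weighs_zero(self):
        wm = apply_tfidf(np.array([[2, 1], [1, 3]]))
        # both words occur in both documents: idf = ln(1) = 0
        np.testing.assert_allclose(wm.values, 0.0)

    def test_exclusive_word_weight(self):
        wm = apply_tfidf(np.array([[3, 1], [0, 1]]))
        assert wm.values[0, 0] == pytest.approx(3 * np.log(2))

    def test_empty_document_set_yields_no_columns(self):
        assert apply_tfidf(np.zeros((3, 4))).shape == (3, 0)

    def test_absent_words_are_dropped(self):
        wm = apply_tfidf(np.array([[1, 0], [2, 0]]), word_ids=["kept", "absent"])
        assert wm.col_ids == ["kept"]


class TestDiseaseHierarchy:
    def chain(self):
        return DiseaseHierarchy.from_edges(
            [("root", "A"), ("A", "B"), ("A", "C")]
        )

    def test_identity_similarity(self):
        assert disease_similarity("B", "B", self.chain()) == 1.0

    def test_siblings_share_one_ancestor(self):
        # anchors(B) = {B, A}, anchors(C) = {C, A}: Dice = 2*1 / (2+2)
        assert disease_similarity("B", "C", self.chain()) == pytest.approx(0.5)

    def test_children_of_root_are_dissimilar(self):
        h = DiseaseHierarchy.from_edges([("root", "x"), ("root", "y")])
        assert disease_similarity("x", "y", h) == 0.0

    def test_unknown_term_is_named_in_error(self):
        with pytest.raises(KeyError, match="nope"):
            disease_similarity("B", "nope", self.chain())

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            DiseaseHierarchy.from_edges([("a", "b"), ("b", "a")])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        terms = [f"t{i}" for i in range(n)]
        # edges only from lower to higher index: acyclic by construction
        edges = [
            (terms[i], terms[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.15
        ]
        h = DiseaseHierarchy(terms, edges)

        parents = {t: set() for t in terms}
        for p, c in edges:
            parents[c].add(p)

        def brute_ancestors(t):  # independent transitive closure
            out, stack = set(), [t]
            while stack:
                for p in parents[stack.pop()]:
                    if p not in out:
                        out.add(p)
                        stack.append(p)
            return out

        roots = {t for t in terms if not parents[t]}
        for _ in range(30):
            a, b = rng.choice(terms, 2)
            sa = (brute_ancestors(a) | {a}) - roots
            sb = (brute_ancestors(b) | {b}) - roots
            if a == b:
                expected = 1.0
            elif not sa or not sb:
                expected = 0.0
            else:
                expected = 2 * len(sa & sb) / (len(sa) + len(sb))
            assert disease_similarity(a, b, h) == pytest.approx(expected)


class TestInference:
    def test_annotation_propagates_to_broader_term(self):
        h = DiseaseHierarchy.from_edges([("Colorectal Neoplasms", "Colonic Neoplasms")])
        ids = ["Colonic Neoplasms", "Colorectal Neoplasms"]
        out = infer_diseases(np.array([[1, 0]]), ids, h)
        np.testing.assert_array_equal(out, [[1, 1]])

    def test_flat_hierarchy_is_noop(self):
        h = DiseaseHierarchy(terms=["a", "b"])
        md = np.array([[1, 0], [0, 1]])
        np.testing.assert_array_equal(infer_diseases(md, ["a", "b"], h), md)

    @pytest.mark.parametrize("seed", range(3))
    def test_idempotent_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"d{i}" for i in range(8)]
        edges = [(ids[i], ids[j]) for i in range(8) for j in range(i + 1, 8)
                 if rng.random() < 0.2]
        h = DiseaseHierarchy(ids, edges)
        md = (rng.random((6, 8)) < 0.3).astype(int)
        once = infer_diseases(md, ids, h)
        assert (once >= md).all()
        np.testing.assert_array_equal(infer_diseases(once, ids, h), once)

    def test_unknown_terms_pass_through(self):
        h = DiseaseHierarchy.from_edges([("p", "c")])
        md = np.array([[1, 1]])
        out = infer_diseases(md, ["c", "stranger"], h)
        np.testing.assert_array_equal(out, [[1, 1]])


class TestAssociationWeight:
    def setup_method(self):
        self.h = DiseaseHierarchy.from_edges([("root", "A"), ("A", "B"), ("A", "C")])
        self.ids = ["B", "C"]

    def test_direct_annotation_scores_one(self):
        md = np.array([[1, 0]])
        assert association_weight("m", "B", md, ["m"], self.ids, self.h) == 1.0

    def test_no_annotation_scores_zero(self):
        md = np.array([[0, 0]])
        assert association_weight("m", "B", md, ["m"], self.ids, self.h) == 0.0

    def test_sibling_annotation_scores_half(self):
        md = np.array([[0, 1]])
        assert association_weight("m", "B", md, ["m"], self.ids, self.h) == pytest.approx(0.5)

    def test_exclusion_masks_direct_annotation(self):
        md = np.array([[1, 1]])
        m = association_weight("m", "B", md, ["m"], self.ids, self.h, exclude_disease="B")
        assert m == pytest.approx(0.5)


class TestDiscretize:
    def test_value_above_both_cutoffs_gets_two_indicators(self):
        assert discretize(0.8, (1 / 3, 2 / 3)) == {">=0.333333", ">=0.666667"}

    def test_zero_maps_to_no_assoc_only(self):
        assert discretize(0.0, (0.25, 0.5)) == {"no_assoc"}

    def test_one_hits_every_cutoff(self):
        cutoffs = (0.1, 0.4, 0.9)
        assert len(discretize(1.0, cutoffs)) == len(cutoffs)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            discretize(1.2, (0.5,))

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(derandomize=True, max_examples=50)
    def test_bin_count_contract(self, m):
        cutoffs = (0.2, 0.5, 0.8)
        bins = discretize(m, cutoffs)
        if m < cutoffs[0]:
            assert bins == {"no_assoc"}
        else:
            assert len(bins) == sum(m >= c for c in cutoffs)


class TestNeighborWeights:
    def coords(self):
        return {
            "a": Coord("chr1", 100, 180, "+"),
            "b": Coord("chr1", 100, 170, "-"),
            "c": Coord("chr1", 25_100, 25_200, "+"),
            "d": Coord("chr2", 100, 190, "+"),
        }

    def test_same_start_full_weight(self):
        w = neighbor_weights(self.coords(), ["a", "b", "c", "d"]).values
        assert w[0, 1] == 1.0

    def test_linear_decay_at_half_window(self):
        w = neighbor_weights(self.coords(), ["a", "b", "c", "d"], window=50_000).values
        assert w[0, 2] == pytest.approx(0.5)

    def test_different_chromosome_zero(self):
        w = neighbor_weights(self.coords(), ["a", "b", "c", "d"]).values
        assert w[0, 3] == 0.0

    def test_symmetric_zero_diagonal_missing_coords(self):
        w = neighbor_weights(self.coords(), ["a", "b", "ghost"]).values
        np.testing.assert_allclose(w, w.T)
        assert np.diagonal(w).sum() == 0.0
        np.testing.assert_array_equal(w[2], 0.0)


class TestDiseaseBlock:
    def setup(self):
        h = DiseaseHierarchy.from_edges([("root", "A"), ("A", "B"), ("A", "C")])
        md = np.array([[1, 0], [0, 1], [0, 0]])
        return md, ["B", "C"], h

    def test_passthrough_without_cutoffs(self):
        md, ids, h = self.setup()
        block = build_disease_block(md, ids, h, Configuration())
        np.testing.assert_array_equal(block.values, md)
        assert block.col_ids == ["disease:B", "disease:C"]

    def test_single_cutoff_doubles_columns(self):
        md, ids, h = self.setup()
        block = build_disease_block(md, ids, h, Configuration(cutoffs=(0.05,)))
        assert block.shape[1] == 2 * len(ids)

    def test_annotated_pairs_hit_upper_bin(self):
        md, ids, h = self.setup()
        block = build_disease_block(md, ids, h, Configuration(cutoffs=(0.5,)))
        cols = dict(zip(block.col_ids, block.values.T))
        np.testing.assert_array_equal(cols["disease:B@>=0.5"], [1, 1, 0])
        np.testing.assert_array_equal(cols["disease:B@no_assoc"], [0, 0, 1])

    def test_similarity_exclusion_softens_column(self):
        md, ids, h = self.setup()
        block = build_disease_block(
            md, ids, h, Configuration(cutoffs=(0.4, 0.8)), exclude_similarity_for="B"
        )
        cols = dict(zip(block.col_ids, block.values.T))
        # row 0 annotated to B directly, but only the sibling similarity (0.5)
        # may support column B once B's own annotations are masked
        np.testing.assert_array_equal(cols["disease:B@>=0.8"], [0, 0, 0])
        np.testing.assert_array_equal(cols["disease:B@>=0.4"], [0, 1, 0])
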