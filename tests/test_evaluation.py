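"""Ranking metrics, the cross-validation protocol and the derived predictions."""

import itertools

import numpy as np
import pytest

from mirlsa.encoding import Configuration, encode
from mirlsa.evaluation import (
    auc,
    cross_validate,
    detect_invalid,
    fitness_of_genome,
    partition_folds,
    precision_at_recall,
    predict_novel,
    r_precision,
)
from mirlsa.synthetic import shuffle_associations


def brute_force_auc(ranked, positives):
    """Independent oracle: enumerate every (positive, negative) pair."""
    pos = [i for i, m in enumerate(ranked) if m in positives]
    neg = [i for i, m in enumerate(ranked) if m not in positives]
    wins = sum(1 for p, n in itertools.product(pos, neg) if p < n)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_ranking(self):
        assert auc(["a", "b", "c", "d"], {"a", "b"}) == 1.0

    def test_interleaved_ranking(self):
        # positives at ranks 1 and 3 of 4: 3 of 4 pairs correct
        assert auc(["p1", "n1", "p2", "n2"], {"p1", "p2"}) == 0.75

    def test_single_negative_last(self):
        assert auc(["a", "b", "c"], {"a", "b"}) == 1.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            auc(["a", "b"], {"a", "b"})

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        items = [f"x{i}" for i in range(n)]
        rng.shuffle(items)
        k = int(rng.integers(1, n))
        positives = set(rng.choice(items, size=k, replace=False))
        assert auc(items, positives) == pytest.approx(brute_force_auc(items, positives))

    @pytest.mark.parametrize("seed", range(4))
    def test_reversal_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        items = [f"x{i}" for i in range(12)]
        positives = set(items[:5])
        rng.shuffle(items)
        assert auc(items, positives) + auc(items[::-1], positives) == pytest.approx(1.0)


class TestPrecisionMetrics:
    def test_perfect_ranking_all_levels(self):
        p = precision_at_recall(["a", "b", "c", "d"], {"a", "b"}, levels=(0.5, 1.0))
        assert p == {0.5: 1.0, 1.0: 1.0}

    def test_depth_enumeration_case(self):
        p = precision_at_recall(["p", "n", "n", "p2"], {"p", "p2"}, levels=(0.5, 1.0))
        assert p[0.5] == 1.0 and p[1.0] == 0.5

    def test_single_positive_ranked_last(self):
        p = precision_at_recall(["n1", "n2", "n3", "p"], {"p"}, levels=(1.0,))
        assert p[1.0] == pytest.approx(1 / 4)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            precision_at_recall(["a", "b"], {"a"}, levels=(0.0,))

    def test_r_precision_counts_top_r(self):
        ranked = [f"p{i}" for i in range(6)] + [f"n{i}" for i in range(10)]
        positives = {f"p{i}" for i in range(6)} | {"n7", "n8", "n9", "n5"}
        # R = 10, six positives in the top ten
        assert r_precision(ranked, positives) == pytest.approx(0.6)

    def test_r_precision_extremes(self):
        assert r_precision(["a", "b", "c"], {"a"}) == 1.0
        assert r_precision(["b", "c", "a"], {"a"}) == 0.0

    def test_r_precision_equals_precision_at_full_recall_for_unique_ranks(self):
        rng = np.random.default_rng(0)
        items = [f"x{i}" for i in range(15)]
        rng.shuffle(items)
        positives = set(items[::3])
        # holds whenever the R-th positive sits exactly at the capture depth
        p100 = precision_at_recall(items, positives, levels=(1.0,))[1.0]
        assert r_precision(items, positives) >= p100


class TestFoldPartition:
    @pytest.mark.parametrize("n_items,n_folds", [(13, 5), (25, 5), (5, 5)])
    def test_each_index_appears_exactly_once(self, n_items, n_folds):
        rng = np.random.default_rng(0)
        idx = np.arange(100, 100 + n_items)
        folds = partition_folds(idx, n_folds, rng)
        assert len(folds) == n_folds
        merged = sorted(np.concatenate(folds).tolist())
        assert merged == idx.tolist()
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1


class TestCrossValidate:
    def test_deterministic_given_seed(self, default_fixture, tuned_config):
        dataset, _ = default_fixture
        a = cross_validate(dataset, tuned_config, disease_min=5, seed=3)
        b = cross_validate(dataset, tuned_config, disease_min=5, seed=3)
        assert a.mean_auc == b.mean_auc
        assert a.per_disease.keys() == b.per_disease.keys()

    def test_mean_auc_is_average_of_diseases(self, default_fixture, tuned_config):
        dataset, _ = default_fixture
        res = cross_validate(dataset, tuned_config, disease_min=5, seed=0)
        assert res.mean_auc == pytest.approx(
            np.mean([m.auc for m in res.per_disease.values()])
        )

    def test_filter_excludes_sparse_diseases(self, default_fixture, tuned_config):
        dataset, _ = default_fixture
        res = cross_validate(dataset, tuned_config, disease_min=12, seed=0)
        counts = dict(zip(dataset.disease_ids, dataset.disease_association_counts()))
        assert all(counts[d] >= 12 for d in res.per_disease)

    def test_unmeetable_filter_rejected(self, default_fixture, tuned_config):
        dataset, _ = default_fixture
        with pytest.raises(ValueError):
            cross_validate(dataset, tuned_config, disease_min=1000)


class TestFitness:
    def test_deterministic(self, default_fixture, tuned_config):
        dataset, _ = default_fixture
        genome = encode(tuned_config)
        a = fitness_of_genome(dataset, genome, disease_min=5, seed=1)
        b = fitness_of_genome(dataset, genome, disease_min=5, seed=1)
        assert a == b

    def test_all_zero_genome_still_evaluates(self, default_fixture):
        dataset, _ = default_fixture
        value = fitness_of_genome(dataset, np.zeros(35, dtype=np.int8), disease_min=5, seed=1)
        assert 0.0 <= value <= 1.0

    def test_signal_beats_shuffled_labels(self, default_fixture, tuned_config):
        dataset, _ = default_fixture
        genome = encode(tuned_config)
        rng = np.random.default_rng(9)
        shuffled = dataset.with_md(shuffle_associations(dataset.md, rng))
        signal = fitness_of_genome(dataset, genome, disease_min=5, seed=1)
        noise = fitness_of_genome(shuffled, genome, disease_min=5, seed=1)
        assert signal > noise


class TestDetectInvalid:
    def test_planted_outlier_tops_noise_free_fixture(self, clean_fixture, tuned_config):
        dataset, truth = clean_fixture
        flagged = detect_invalid(dataset, tuned_config, threshold=2.0)
        assert flagged, "expected at least one flagged pair"
        assert flagged[0][:2] == truth.planted_errors[0]

    def test_no_flag_when_cosines_identical(self):
        # two identical miRNAs annotated to the same disease: zero variance
        from mirlsa.dataset import MirnaDataset
        from mirlsa.hierarchy import DiseaseHierarchy

        ds = MirnaDataset(
            mirna_ids=["a", "b"],
            disease_ids=["d0", "d1"],
            md=np.array([[1, 1], [1, 1]]),
            hierarchy=DiseaseHierarchy(terms=["d0", "d1"]),
        )
        assert detect_invalid(ds, Configuration(), threshold=2.0) == []

    def test_flag_count_monotone_in_threshold(self, clean_fixture, tuned_config):
        dataset, _ = clean_fixture
        counts = [
            len(detect_invalid(dataset, tuned_config, threshold=t))
            for t in (0.5, 1.5, 2.5, 4.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestPredictNovel:
    def test_zero_top_k_empty(self, default_fixture, tuned_config):
        dataset, _ = default_fixture
        assert predict_novel(dataset, tuned_config, top_k=0) == []

    def test_annotated_pairs_never_predicted(self, default_fixture, tuned_config):
        dataset, _ = default_fixture
        annotated = {
            (dataset.disease_ids[j], dataset.mirna_ids[i])
            for i, j in zip(*np.nonzero(dataset.md))
        }
        novel = predict_novel(dataset, tuned_config, top_k=5)
        assert not annotated & {(d, m) for d, m, _ in novel}

    def test_held_out_pair_recovered(self, default_fixture, tuned_config):
        dataset, truth = default_fixture
        novel = {(d, m) for d, m, _ in predict_novel(dataset, tuned_config, top_k=5)}
        for mirna, disease in truth.held_out:
            assert (disease, mirna) in novel
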