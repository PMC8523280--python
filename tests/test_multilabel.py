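"""RAKEL / Binary Relevance ensembles against independent oracles."""

import itertools

import numpy as np
import pytest

from mptype.annotation_io import LabelMatrix
from mptype.embedding import FeatureMatrix
from mptype.multilabel import (
    BaseClassifierSpec,
    LabelSubset,
    MemorizingClassifier,
    RakelEnsemble,
    br_fit,
    br_predict,
    load_ensemble,
    rakel_fit,
    rakel_predict,
    restrict_labels,
    sample_label_subsets,
    save_ensemble,
)
from tests.conftest import random_multilabel_problem

MEMO = BaseClassifierSpec(algorithm="memorizing")


def brute_force_votes(ensemble: RakelEnsemble, X: np.ndarray) -> np.ndarray:
    """Exhaustive per-label vote counting, independent of rakel_predict.

    Loops sample-by-sample and label-by-label over raw model outputs.
    """
    n, l = len(X), ensemble.l
    props = np.zeros((n, l))
    for i in range(n):
        for j in range(l):
            involved = voted = 0
            for subset, model, inventory in zip(
                ensemble.subsets, ensemble.models, ensemble.class_inventories
            ):
                if j not in subset.indices:
                    continue
                involved += 1
                code = int(model.predict(X[i : i + 1])[0])
                if j in inventory[code]:
                    voted += 1
            props[i, j] = voted / involved if involved else 0.0
    return props


class TestRestrictLabels:
    def test_partial_overlap(self):
        subset = LabelSubset((0, 1, 2))
        assert restrict_labels({0, 1, 3}, subset) == frozenset({0, 1})

    def test_identity_when_contained(self):
        assert restrict_labels({1, 2}, LabelSubset((0, 1, 2))) == {1, 2}

    def test_disjoint_gives_empty_class(self):
        assert restrict_labels({3, 4}, LabelSubset((0, 1))) == frozenset()


class TestSampleLabelSubsets:
    def test_exhausts_all_two_subsets_of_four(self):
        subsets = sample_label_subsets(4, 2, 6, seed=0)
        assert sorted(s.indices for s in subsets) == list(
            itertools.combinations(range(4), 2)
        )

    def test_with_replacement_fallback_at_k_equals_l(self):
        subsets = sample_label_subsets(6, 6, 10, seed=0)
        assert len(subsets) == 10
        assert all(s.indices == tuple(range(6)) for s in subsets)

    def test_singletons_at_k_one(self):
        subsets = sample_label_subsets(5, 1, 5, seed=3)
        assert sorted(s.indices for s in subsets) == [(j,) for j in range(5)]

    def test_deterministic_given_seed(self):
        assert sample_label_subsets(6, 3, 8, 7) == sample_label_subsets(6, 3, 8, 7)

    @pytest.mark.parametrize("l,k,m", [(3, 4, 1), (3, 2, 0)])
    def test_invalid_parameters_error(self, l, k, m):
        with pytest.raises(ValueError):
            sample_label_subsets(l, k, m, seed=0)


class TestRakelRoundTrip:
    def test_k_equals_l_m1_memorizer_reproduces_training_labels(self):
        rng = np.random.default_rng(1)
        features, labels = random_multilabel_problem(rng, n=12, l=4)
        ensemble = rakel_fit(features, labels, MEMO, k=4, m=1, seed=0)
        _, pred = rakel_predict(ensemble, features)
        assert np.array_equal(pred, labels.indicators)

    def test_two_sample_toy_class_inventories(self):
        features = FeatureMatrix(["a", "b"], np.array([[0.0], [1.0]]))
        labels = LabelMatrix(
            ["a", "b"], ["x", "y", "z"], np.array([[1, 1, 0], [0, 0, 1]])
        )
        ensemble = rakel_fit(features, labels, MEMO, k=2, m=3, seed=5)
        assert ensemble.m == 3
        assert all(len(inv) <= 2 for inv in ensemble.class_inventories)


class TestRakelVoting:
    def _fixed_ensemble(self, outputs):
        """l=3 ensemble with subsets {0,1},{1,2},{0,2} and fixed outputs."""

        class Fixed:
            def __init__(self, code):
                self.code = code

            def predict(self, X):
                return np.full(len(X), self.code)

        subsets = [LabelSubset((0, 1)), LabelSubset((1, 2)), LabelSubset((0, 2))]
        inventories = [[frozenset(o)] for o in outputs]
        models = [Fixed(0) for _ in outputs]
        return RakelEnsemble(
            subsets=subsets, models=models, class_inventories=inventories,
            l=3, n_features=1,
        )

    def test_hand_counted_votes_and_strict_threshold(self):
        # models predict {0}, {1,2}, {2}: label proportions (1/2, 1/2, 1)
        ensemble = self._fixed_ensemble([{0}, {1, 2}, {2}])
        X = FeatureMatrix(["q"], np.zeros((1, 1)))
        props, pred = rakel_predict(ensemble, X)
        assert props.tolist() == [[0.5, 0.5, 1.0]]
        assert pred.tolist() == [[0, 0, 1]]  # exactly 0.5 is a negative

    def test_full_subset_predictions_assign_every_label(self):
        ensemble = self._fixed_ensemble([{0, 1}, {1, 2}, {0, 2}])
        X = FeatureMatrix(["q"], np.zeros((1, 1)))
        props, pred = rakel_predict(ensemble, X)
        assert props.tolist() == [[1.0, 1.0, 1.0]]
        assert pred.tolist() == [[1, 1, 1]]

    def test_empty_class_predictions_assign_nothing(self):
        ensemble = self._fixed_ensemble([set(), set(), set()])
        X = FeatureMatrix(["q"], np.zeros((1, 1)))
        props, pred = rakel_predict(ensemble, X)
        assert props.sum() == 0.0
        assert pred.sum() == 0

    def test_dimension_mismatch_errors(self):
        rng = np.random.default_rng(2)
        features, labels = random_multilabel_problem(rng, n=6, l=3)
        ensemble = rakel_fit(features, labels, MEMO, k=2, m=2, seed=0)
        bad = FeatureMatrix(["q"], np.zeros((1, 7)))
        with pytest.raises(ValueError):
            rakel_predict(ensemble, bad)


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("l", [2, 3, 4])
    def test_votes_match_exhaustive_counting(self, l):
        rng = np.random.default_rng(l)
        features, labels = random_multilabel_problem(rng, n=12, l=l)
        queries = FeatureMatrix(
            ["q1", "q2"], rng.random((2, features.values.shape[1]))
        )
        for k in range(1, l + 1):
            for m in (1, 3, 6):
                ensemble = rakel_fit(
                    features, labels, MEMO, k=k, m=m, seed=10 * k + m
                )
                for X in (features, queries):
                    props, pred = rakel_predict(ensemble, X)
                    expected = brute_force_votes(ensemble, X.values)
                    assert np.allclose(props, expected)
                    assert np.array_equal(
                        pred, (expected > 0.5).astype(np.int8)
                    )


class TestReductions:
    def test_k_equals_l_m1_is_label_powerset(self):
        """RAKEL with one full-size subset is exactly a powerset classifier."""
        rng = np.random.default_rng(4)
        features, labels = random_multilabel_problem(rng, n=10, l=3)
        ensemble = rakel_fit(features, labels, MEMO, k=3, m=1, seed=0)

        # independent label-powerset reference on the same memorizing base
        sets = labels.label_sets()
        classes = {s: i for i, s in enumerate(dict.fromkeys(sets))}
        lp = MemorizingClassifier().fit(
            features.values, [classes[s] for s in sets]
        )
        inv = {i: s for s, i in classes.items()}
        lp_pred = np.zeros_like(labels.indicators)
        for i, code in enumerate(lp.predict(features.values)):
            lp_pred[i, sorted(inv[int(code)])] = 1

        _, pred = rakel_predict(ensemble, features)
        assert np.array_equal(pred, lp_pred)

    def test_k1_votes_equal_binary_relevance(self):
        """One singleton subset per label makes RAKEL vote like BR."""
        rng = np.random.default_rng(5)
        features, labels = random_multilabel_problem(rng, n=10, l=4)
        queries = FeatureMatrix(
            ["q1", "q2", "q3"], rng.random((3, features.values.shape[1]))
        )
        ensemble = rakel_fit(features, labels, MEMO, k=1, m=4, seed=0)
        br = br_fit(features, labels, MEMO)
        for X in (features, queries):
            props, _ = rakel_predict(ensemble, X)
            assert np.array_equal(props.astype(np.int8), br_predict(br, X))


class TestModelOrderInvariance:
    def test_prediction_invariant_to_stored_model_order(self):
        rng = np.random.default_rng(6)
        features, labels = random_multilabel_problem(rng, n=12, l=4)
        ensemble = rakel_fit(features, labels, MEMO, k=2, m=6, seed=1)
        perm = rng.permutation(ensemble.m)
        shuffled = RakelEnsemble(
            subsets=[ensemble.subsets[i] for i in perm],
            models=[ensemble.models[i] for i in perm],
            class_inventories=[ensemble.class_inventories[i] for i in perm],
            l=ensemble.l,
            threshold=ensemble.threshold,
            n_features=ensemble.n_features,
        )
        p1, _ = rakel_predict(ensemble, features)
        p2, _ = rakel_predict(shuffled, features)
        assert np.allclose(p1, p2)


class TestBinaryRelevance:
    def test_one_model_per_label(self):
        rng = np.random.default_rng(7)
        features, labels = random_multilabel_problem(rng, n=10, l=6)
        assert len(br_fit(features, labels, MEMO).models) == 6

    def test_memorizer_reproduces_training_labels(self):
        rng = np.random.default_rng(8)
        features, labels = random_multilabel_problem(rng, n=10, l=4)
        ensemble = br_fit(features, labels, MEMO)
        assert np.array_equal(br_predict(ensemble, features), labels.indicators)

    def test_label_column_permutation_permutes_models(self):
        rng = np.random.default_rng(9)
        features, labels = random_multilabel_problem(rng, n=10, l=4)
        perm = [2, 0, 3, 1]
        permuted = LabelMatrix(
            labels.protein_ids,
            [labels.label_names[j] for j in perm],
            labels.indicators[:, perm],
        )
        a = br_predict(br_fit(features, labels, MEMO), features)
        b = br_predict(br_fit(features, permuted, MEMO), features)
        assert np.array_equal(a[:, perm], b)

    def test_single_class_column_becomes_constant_predictor(self):
        features = FeatureMatrix(["a", "b"], np.array([[0.0], [1.0]]))
        labels = LabelMatrix(
            ["a", "b"], ["x", "y"], np.array([[1, 1], [1, 0]])
        )
        ensemble = br_fit(features, labels, MEMO)
        pred = br_predict(ensemble, FeatureMatrix(["q"], np.array([[9.0]])))
        assert pred[0, 0] == 1  # constant-positive column


class TestSerialization:
    def test_save_load_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(10)
        features, labels = random_multilabel_problem(rng, n=10, l=4)
        base = BaseClassifierSpec(algorithm="random_forest", trees=10, seed=0)
        ensemble = rakel_fit(features, labels, base, k=2, m=4, seed=1)
        save_ensemble(ensemble, tmp_path / "model")
        loaded = load_ensemble(tmp_path / "model")
        p1, _ = rakel_predict(ensemble, features)
        p2, _ = rakel_predict(loaded, features)
        assert np.array_equal(p1, p2)
        assert loaded.base == base
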