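"""From-scratch weighted-sampling forest: splits, sampling, importance, votes."""

import json

import numpy as np
import pytest

from ehrweights.errors import DegenerateWeightsError, ValidationError
from ehrweights.weighted_forest import (
    ForestParams,
    WeightedRandomForestClassifier,
    error_decomposition,
    fit_forest,
    forest_feature_usage,
    gini_importance,
    gini_impurity,
    sample_candidates,
)


class TestGiniImpurity:
    @pytest.mark.parametrize(
        "counts,expected", [((5, 5), 0.5), ((10, 0), 0.0), ((3, 1), 0.375), ((1, 3), 0.375)]
    )
    def test_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node_rejected(self):
        with pytest.raises(ValidationError):
            gini_impurity((0, 0))


class TestSampleCandidates:
    def test_single_nonzero_mass(self):
        for state in range(20):
            assert list(sample_candidates(np.array([0.0, 1.0, 0.0]), 1, state)) == [1]

    def test_uniform_exhaustive_draw(self):
        out = sample_candidates(np.full(6, 1 / 6), 6, rng_state=3)
        assert sorted(out) == list(range(6))

    def test_zero_probability_columns_never_drawn(self):
        probs = np.array([0.5, 0.5, 0.0])
        for state in range(10000):
            got = set(sample_candidates(probs, 2, state))
            assert got == {0, 1}

    def test_distinct_indices_and_count(self):
        probs = np.array([0.4, 0.3, 0.2, 0.1, 0.0])
        got = sample_candidates(probs, 10, rng_state=1)
        assert len(got) == len(set(got)) == 4  # only 4 nonzero-prob columns

    def test_deterministic_given_state(self):
        probs = np.array([0.2, 0.3, 0.1, 0.4])
        a = sample_candidates(probs, 2, rng_state=99)
        b = sample_candidates(probs, 2, rng_state=99)
        assert list(a) == list(b)

    def test_first_draw_frequencies_follow_probabilities(self):
        probs = np.array([0.7, 0.2, 0.1])
        hits = np.zeros(3)
        for state in range(4000):
            hits[sample_candidates(probs, 1, state)[0]] += 1
        freq = hits / hits.sum()
        assert np.allclose(freq, probs, atol=0.03)

    def test_all_zero_probabilities_error(self):
        with pytest.raises(DegenerateWeightsError):
            sample_candidates(np.zeros(3), 1, rng_state=0)


def _separable_data(n=40):
    rng = np.random.default_rng(0)
    X = rng.uniform(size=(n, 3))
    y = (X[:, 1] > 0.5).astype(int)
    X[:, 1] = np.where(y == 1, X[:, 1] + 1.0, X[:, 1])  # make feature 1 fully separating
    return X, y


class TestForestFit:
    def test_single_class_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ValidationError):
            WeightedRandomForestClassifier(n_trees=2).fit(X, np.zeros(5))

    def test_separable_feature_with_all_mass_gives_pure_stump(self):
        X, y = _separable_data()
        probs = np.array([0.0, 1.0, 0.0])
        f = WeightedRandomForestClassifier(
            n_trees=5, mtry=1, bootstrap=False, feature_probabilities=probs, random_state=1
        ).fit(X, y)
        assert (f.predict(X) == y).all()
        for feature, thr, left, right, n0, n1 in f.trees_:
            assert feature[0] == 1  # root splits on the separating feature
            # depth 1: both children are leaves and pure
            assert feature[left[0]] == -1 and feature[right[0]] == -1
            assert n0[left[0]] * n1[left[0]] == 0 and n0[right[0]] * n1[right[0]] == 0

    def test_training_error_zero_on_separable_data(self):
        X, y = _separable_data()
        f = WeightedRandomForestClassifier(n_trees=20, random_state=2).fit(X, y)
        assert (f.predict(X) == y).all()

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(0.3, size=(60, 30)).astype(float)
        y = rng.integers(0, 2, size=60)
        y[:5] = 1
        y[-5:] = 0
        a = WeightedRandomForestClassifier(n_trees=25, random_state=7).fit(X, y)
        b = WeightedRandomForestClassifier(n_trees=25, random_state=7).fit(X, y)
        assert a.to_json() == b.to_json()
        Xt = rng.poisson(0.3, size=(20, 30)).astype(float)
        assert (a.predict_proba(Xt) == b.predict_proba(Xt)).all()
        c = WeightedRandomForestClassifier(n_trees=25, random_state=8).fit(X, y)
        assert c.to_json() != a.to_json()

    def test_excluded_features_never_used(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(0.5, size=(80, 40)).astype(float)
        y = rng.integers(0, 2, size=80)
        y[:5] = 1
        y[-5:] = 0
        probs = np.ones(40)
        excluded = {1, 7, 13, 20, 39}
        for j in excluded:
            probs[j] = 0.0
        f = WeightedRandomForestClassifier(
            n_trees=50, feature_probabilities=probs, random_state=5
        ).fit(X, y)
        assert forest_feature_usage(f).isdisjoint(excluded)

    def test_vote_count_conservation(self):
        X, y = _separable_data()
        n_trees = 17
        f = WeightedRandomForestClassifier(n_trees=n_trees, random_state=6).fit(X, y)
        scores = f.predict_proba(X)[:, 1]
        votes = scores * n_trees
        assert np.allclose(votes, np.rint(votes))  # integral positive-vote counts
        assert ((votes >= 0) & (votes <= n_trees)).all()

    def test_importance_concentrates_on_separating_feature(self):
        # one perfectly separating feature among constant (unsplittable) ones
        rng = np.random.default_rng(7)
        n = 40
        y = rng.integers(0, 2, size=n)
        y[:2], y[-2:] = 0, 1
        X = np.zeros((n, 4))
        X[:, 2] = y + rng.uniform(0, 0.5, size=n)
        f = WeightedRandomForestClassifier(n_trees=50, random_state=7).fit(X, y)
        imp = gini_importance(f)
        assert imp[2] >= 0.99
        assert imp.sum() == pytest.approx(1.0)
        assert forest_feature_usage(f) == {2}

    def test_mtry_larger_than_p_rejected(self):
        X, y = _separable_data()
        with pytest.raises(ValidationError):
            WeightedRandomForestClassifier(n_trees=1, mtry=4).fit(X, y)


class TestStumpImportanceOracle:
    def _brute_force_tree(self, X, y, min_node_size=1):
        """Greedy CART with all features as candidates; returns total decrease
        per feature accumulated with the (n_node/n_root) weighting."""
        n_root = len(y)
        imp = np.zeros(X.shape[1])

        def gini(c0, c1):
            n = c0 + c1
            if n == 0:
                return 0.0
            p0, p1 = c0 / n, c1 / n
            return 1.0 - p0 * p0 - p1 * p1

        def split(idx):
            yv = y[idx]
            n_node = len(idx)
            c0, c1 = int((yv == 0).sum()), int((yv == 1).sum())
            if c0 == 0 or c1 == 0 or n_node < 2 * min_node_size:
                return
            # score in the same un-normalized form as the tree builder so that
            # exact float ties resolve identically
            base = n_node * gini(c0, c1)
            best = (0.0, None, None)
            for f in range(X.shape[1]):
                vals = np.unique(X[idx, f])
                for a, b in zip(vals, vals[1:]):
                    thr = (a + b) / 2
                    lmask = X[idx, f] <= thr
                    l0, l1 = int(((yv == 0) & lmask).sum()), int(((yv == 1) & lmask).sum())
                    r0, r1 = c0 - l0, c1 - l1
                    if min(l0 + l1, r0 + r1) < min_node_size:
                        continue
                    score = base - ((l0 + l1) * gini(l0, l1) + (r0 + r1) * gini(r0, r1))
                    if score > 1e-12 and (
                        score > best[0]
                        or (
                            score == best[0]
                            and best[1] is not None
                            and (f, thr) < (best[1], best[2])
                        )
                    ):
                        best = (score, f, thr)
            if best[1] is None:
                return
            score, f, thr = best
            imp[f] += score / n_root
            lidx = idx[X[idx, f] <= thr]
            ridx = idx[X[idx, f] > thr]
            split(lidx)
            split(ridx)

        split(np.arange(len(y)))
        return imp

    def test_importance_matches_hand_computed_decrease(self):
        # 6-sample two-feature fixture with a known greedy tree
        X = np.array(
            [[0, 0], [0, 1], [1, 0], [1, 1], [2, 0], [2, 1]], dtype=float
        )
        y = np.array([0, 0, 0, 1, 1, 1])
        f = WeightedRandomForestClassifier(
            n_trees=1, mtry=2, bootstrap=False, random_state=0
        ).fit(X, y)
        oracle = self._brute_force_tree(X, y)
        total = oracle.sum()
        np.testing.assert_allclose(f.feature_importances_, oracle / total, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_single_tree_importance_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 3, size=(12, 3)).astype(float)
        y = rng.integers(0, 2, size=12)
        y[0], y[1] = 0, 1
        f = WeightedRandomForestClassifier(
            n_trees=1, mtry=3, bootstrap=False, random_state=seed
        ).fit(X, y)
        oracle = self._brute_force_tree(X, y)
        expected = oracle / oracle.sum() if oracle.sum() > 0 else oracle
        np.testing.assert_allclose(f.feature_importances_, expected, atol=1e-12)


def _manual_forest(trees, n_features=1, classes=(0, 1)):
    """Build a forest from explicit node arrays via the JSON codec."""
    payload = {
        "format": "ehrweights-forest/1",
        "params": {
            "n_trees": len(trees), "mtry": 1, "min_node_size": 1,
            "bootstrap": False, "seed": 0,
        },
        "classes": list(classes),
        "n_features": n_features,
        "trees": trees,
        "feature_importances": [0.0] * n_features,
    }
    return WeightedRandomForestClassifier.from_json(json.dumps(payload))


def _stump(thr, left_votes, right_votes):
    def leaf_counts(vote):
        return (0, 1) if vote == 1 else (1, 0)

    l0, l1 = leaf_counts(left_votes)
    r0, r1 = leaf_counts(right_votes)
    return {
        "feature": [0, -1, -1],
        "threshold": [float(thr).hex(), float(0).hex(), float(0).hex()],
        "left": [1, -1, -1],
        "right": [2, -1, -1],
        "n0": [0, l0, r0],
        "n1": [0, l1, r1],
    }


def _leaf(vote):
    n0, n1 = (0, 1) if vote == 1 else (1, 0)
    return {
        "feature": [-1], "threshold": [float(0).hex()], "left": [-1], "right": [-1],
        "n0": [n0], "n1": [n1],
    }


class TestPredictionAndDecomposition:
    def test_tied_vote_goes_negative(self):
        forest = _manual_forest([_leaf(1), _leaf(0)])
        X = np.zeros((3, 1))
        assert (forest.predict_proba(X)[:, 1] == 0.5).all()
        assert (forest.predict(X) == 0).all()

    def test_unanimous_positive(self):
        forest = _manual_forest([_leaf(1), _leaf(1), _leaf(1)])
        X = np.zeros((2, 1))
        assert (forest.predict_proba(X)[:, 1] == 1.0).all()
        assert (forest.predict(X) == 1).all()

    def test_single_tree_scores_are_votes(self):
        forest = _manual_forest([_stump(0.5, 0, 1)])
        X = np.array([[0.0], [1.0]])
        assert list(forest.predict_proba(X)[:, 1]) == [0.0, 1.0]

    def test_error_decomposition_enumerated_votes(self):
        # three trees, each wrong on a different one of three samples,
        # majority always right -> (1/3, 0, 1/3)
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0, 1, 0])
        trees = [
            _stump(1.5, 1, 0),  # predicts (1,1,0): wrong on sample 0
            _leaf(0),           # predicts (0,0,0): wrong on sample 1
            _stump(0.5, 0, 1),  # predicts (0,1,1): wrong on sample 2
        ]
        forest = _manual_forest(trees)
        avg, ens, div = error_decomposition(forest, X, y)
        assert avg == pytest.approx(1 / 3)
        assert ens == 0.0
        assert div == pytest.approx(1 / 3)

    def test_identical_trees_have_zero_diversity(self):
        forest = _manual_forest([_stump(0.5, 0, 1)] * 5)
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0, 1, 0])
        avg, ens, div = error_decomposition(forest, X, y)
        assert avg == ens == pytest.approx(1 / 3)
        assert div == 0.0

    def test_perfect_forest_decomposition(self):
        X, y = _separable_data()
        f = WeightedRandomForestClassifier(n_trees=10, random_state=1).fit(X, y)
        avg, ens, div = f.decompose_error(X, y)
        assert ens == 0.0
        assert div == pytest.approx(avg)

    def test_empty_evaluation_set_rejected(self):
        forest = _manual_forest([_leaf(0)])
        with pytest.raises(ValidationError):
            error_decomposition(forest, np.zeros((0, 1)), np.zeros(0))

    def test_column_mismatch_rejected(self):
        forest = _manual_forest([_leaf(0)])
        with pytest.raises(ValidationError):
            forest.predict(np.zeros((2, 3)))


class TestSerialization:
    def test_roundtrip_preserves_predictions_and_thresholds(self):
        X, y = _separable_data()
        f = fit_forest(X, y, None, ForestParams(n_trees=8, seed=3))
        back = WeightedRandomForestClassifier.from_json(f.to_json())
        rng = np.random.default_rng(0)
        Xt = rng.uniform(size=(30, 3))
        assert (back.predict_proba(Xt) == f.predict_proba(Xt)).all()
        for (fa, ta, *_), (fb, tb, *_) in zip(f.trees_, back.trees_):
            assert (fa == fb).all()
            assert (ta == tb).all()  # bit-exact threshold round-trip

    def test_bad_format_rejected(self):
        with pytest.raises(ValidationError):
            WeightedRandomForestClassifier.from_json('{"format": "other"}')
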