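import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gaitphase as gp
from gaitphase import knn
from gaitphase.phases import ALL_PHASES, Phase

from conftest import make_frames


# ---------------------------------------------------------------------------
# Independent brute-force oracle: full distance list, explicit sort, explicit
# vote, written without numpy vector tricks.  Tie rules match the documented
# contract: neighbor rank ties -> insertion order; vote ties -> smaller summed
# neighbor distance, then phase enumeration order.
# ---------------------------------------------------------------------------

def brute_force_knn(train_x, train_y, query, k, weighted):
    dists = []
    for i, row in enumerate(train_x):
        d = math.sqrt(sum((a - b) ** 2 for a, b in zip(row, query)))
        dists.append((d, i))
    dists.sort(key=lambda pair: (pair[0], pair[1]))
    nbrs = dists[:k]
    d1, dk = nbrs[0][0], nbrs[-1][0]
    scores, dsums = {}, {}
    for d, i in nbrs:
        if weighted and k != 1 and dk != d1:
            w = (dk - d) / (dk - d1)
        else:
            w = 1.0
        label = int(train_y[i])
        scores[label] = scores.get(label, 0.0) + w
        dsums[label] = dsums.get(label, 0.0) + d
    best = max(scores.values())
    tied = [label for label, s in scores.items() if s == best]
    return min(tied, key=lambda label: (dsums[label], label))


def _model_from_arrays(x, y, k, weighting):
    return knn.KnnModel(k=k, weighting=weighting, x=np.asarray(x, float),
                        y=np.asarray(y), scaling=None)


class TestEuclideanDistance:
    @pytest.mark.parametrize(
        "p,q,expected",
        [
            ([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], 0.0),
            ([0, 0, 0, 0, 0], [3, 4, 0, 0, 0], 5.0),
            ([1, 1, 1, 1, 1], [2, 2, 2, 2, 2], math.sqrt(5)),
        ],
    )
    def test_values(self, p, q, expected):
        assert gp.euclidean_distance(np.array(p, float), np.array(q, float)) == pytest.approx(expected)

    def test_symmetry_on_feature_vectors(self):
        p = gp.FeatureVector(values=np.array([1, 0, 2, 0, 3.0]))
        q = gp.FeatureVector(values=np.array([0, 1, 0, 2, 0.0]))
        assert gp.euclidean_distance(p, q) == gp.euclidean_distance(q, p)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            gp.euclidean_distance(np.zeros(5), np.zeros(4))


class TestFindNeighbors:
    def test_exact_match_at_distance_zero(self):
        x = [[0, 0, 0, 0, 0], [1, 1, 1, 1, 1]]
        model = _model_from_arrays(x, [0, 1], k=1, weighting=knn.UNIFORM)
        nbrs = gp.find_neighbors(model, np.zeros(5))
        assert nbrs.distances[0] == 0.0 and nbrs.indices[0] == 0

    def test_full_training_set_sorted(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(9, 5))
        model = _model_from_arrays(x, np.arange(9) % 3, k=9, weighting=knn.UNIFORM)
        nbrs = gp.find_neighbors(model, np.zeros(5))
        assert nbrs.k == 9
        assert np.all(np.diff(nbrs.distances) >= 0)

    def test_equidistant_tie_prefers_earliest_inserted(self):
        # four candidates all at distance 1 competing for three slots
        x = [[1, 0, 0, 0, 0], [0, 1, 0, 0, 0], [0, 0, 1, 0, 0], [0, 0, 0, 1, 0]]
        model = _model_from_arrays(x, [0, 1, 2, 3], k=3, weighting=knn.UNIFORM)
        nbrs = gp.find_neighbors(model, np.zeros(5))
        assert list(nbrs.indices) == [0, 1, 2]

    def test_k_larger_than_training_set_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            _model_from_arrays([[0] * 5], [0], k=3, weighting=knn.UNIFORM)


class TestDudaniWeights:
    def test_single_neighbor(self):
        assert gp.dudani_weights(np.array([7.3])) == pytest.approx([1.0])

    def test_linear_interpolation(self):
        np.testing.assert_allclose(gp.dudani_weights(np.array([1.0, 2.0, 3.0])), [1.0, 0.5, 0.0])

    def test_degenerate_equal_distances_vote_uniformly(self):
        np.testing.assert_array_equal(gp.dudani_weights(np.array([2.0, 2.0, 2.0])), [1, 1, 1])

    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=15)
    )
    def test_weights_sorted_between_zero_and_one(self, distances):
        d = np.sort(np.asarray(distances))
        w = gp.dudani_weights(d)
        assert np.all(np.diff(w) <= 1e-12)  # non-increasing
        assert np.all((w >= 0) & (w <= 1))
        if d[0] < d[-1]:
            assert w[0] == 1.0 and w[-1] == 0.0


class TestClassify:
    def _two_class_model(self, weighting):
        # neighbors of the origin: A at d=1, B at d=2, B at d=3
        x = [[1, 0, 0, 0, 0], [2, 0, 0, 0, 0], [3, 0, 0, 0, 0]]
        y = [Phase.STAND.value, Phase.HEEL_STRIKE.value, Phase.HEEL_STRIKE.value]
        return _model_from_arrays(x, y, k=3, weighting=weighting)

    def test_weighting_overturns_majority(self):
        label, scores = gp.classify(self._two_class_model(knn.DISTANCE_WEIGHTED), np.zeros(5))
        assert label is Phase.STAND
        assert scores[Phase.STAND] == pytest.approx(1.0)
        assert scores[Phase.HEEL_STRIKE] == pytest.approx(0.5)

    def test_uniform_majority_wins(self):
        label, scores = gp.classify(self._two_class_model(knn.UNIFORM), np.zeros(5))
        assert label is Phase.HEEL_STRIKE
        assert scores[Phase.HEEL_STRIKE] == 2.0

    def test_exact_training_point_with_k1(self):
        x = np.eye(5)[:3]
        model = _model_from_arrays(x, [2, 4, 6], k=1, weighting=knn.DISTANCE_WEIGHTED)
        label, _ = gp.classify(model, x[1])
        assert label is Phase(4)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            _model_from_arrays(np.eye(5), np.arange(5), k=2, weighting=knn.UNIFORM)


class TestOracleEquivalence:
    """Library classifier vs the independent brute-force oracle."""

    @pytest.mark.parametrize("weighting", [knn.UNIFORM, knn.DISTANCE_WEIGHTED])
    def test_random_instances_including_ties(self, weighting):
        rng = np.random.default_rng(20240917)
        weighted = weighting == knn.DISTANCE_WEIGHTED
        n_checked = 0
        for trial in range(250):
            n = int(rng.integers(3, 51))
            n_classes = int(rng.integers(2, 8))
            if trial % 2 == 0:
                # integer grid coordinates force exact distance ties
                x = rng.integers(0, 3, size=(n, 5)).astype(float)
                query = rng.integers(0, 3, size=5).astype(float)
            else:
                x = rng.uniform(size=(n, 5))
                query = rng.uniform(size=5)
            y = rng.integers(0, n_classes, size=n)
            k = int(rng.choice([1, 3, 5, 7, 9]))
            if k > n:
                k = 1
            model = _model_from_arrays(x, y, k=k, weighting=weighting)
            label, _ = gp.classify(model, query)
            assert label.value == brute_force_knn(x, y, query, k, weighted), (
                f"trial {trial}: k={k}, weighted={weighted}"
            )
            n_checked += 1
        assert n_checked >= 200

    def test_sklearn_cross_check_uniform_two_class(self):
        """Independent library oracle on tie-free two-class instances."""
        sklearn_neighbors = pytest.importorskip("sklearn.neighbors")
        rng = np.random.default_rng(5)
        for _ in range(40):
            n = int(rng.integers(10, 40))
            x = rng.uniform(size=(n, 5))
            y = rng.integers(0, 2, size=n)
            if len(set(y)) < 2:
                continue
            query = rng.uniform(size=(1, 5))
            for k in (1, 3, 5):
                ref = sklearn_neighbors.KNeighborsClassifier(n_neighbors=k).fit(x, y)
                model = _model_from_arrays(x, y, k=k, weighting=knn.UNIFORM)
                assert gp.classify(model, query[0])[0].value == int(ref.predict(query)[0])


class TestInvariants:
    def test_k1_weighted_equals_uniform_equals_nearest(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=(20, 5))
        y = rng.integers(0, 7, size=20)
        for _ in range(20):
            q = rng.uniform(size=5)
            nearest = int(y[np.argmin(np.linalg.norm(x - q, axis=1))])
            for mode in (knn.UNIFORM, knn.DISTANCE_WEIGHTED):
                model = _model_from_arrays(x, y, k=1, weighting=mode)
                assert gp.classify(model, q)[0].value == nearest

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_permutation_invariance_with_distinct_distances(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=(15, 5))
        y = rng.integers(0, 4, size=15)
        q = rng.uniform(size=5)
        d = np.linalg.norm(x - q, axis=1)
        if len(np.unique(np.round(d, 12))) < 15:
            return  # degenerate draw
        perm = rng.permutation(15)
        for mode in (knn.UNIFORM, knn.DISTANCE_WEIGHTED):
            a = gp.classify(_model_from_arrays(x, y, 5, mode), q)[0]
            b = gp.classify(_model_from_arrays(x[perm], y[perm], 5, mode), q)[0]
            assert a is b

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_uniform_predictions_scale_invariant(self, scale):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(12, 5))
        y = rng.integers(0, 3, size=12)
        q = rng.uniform(size=5)
        a = gp.classify(_model_from_arrays(x, y, 3, knn.UNIFORM), q)[0]
        b = gp.classify(_model_from_arrays(x * scale, y, 3, knn.UNIFORM), q * scale)[0]
        assert a is b

    def test_perfect_training_accuracy_at_k1(self):
        prototypes = np.eye(5)[:5] * 3
        frames = make_frames(
            np.repeat(prototypes, 4, axis=0),
            labels=[Phase(i) for i in np.repeat(np.arange(5), 4)],
        )
        model = gp.fit(frames, k=1, weighting=knn.UNIFORM, scale=False)
        preds = gp.predict(model, frames)
        assert all(p is fv.label for p, fv in zip(preds, frames))


class TestSelectK:
    def test_engineered_case_where_k3_wins(self):
        # One wrong-class outlier sits nearest the validation point: k=1 trusts
        # it (wrong); k=3 lets the two nearby correct points outvote it; k=5
        # pulls in two more far-away wrong-class points (wrong again).
        a, b = Phase.STAND, Phase.HEEL_STRIKE
        train = make_frames(
            [[1.0, 0, 0, 0, 0],   # A outlier, d=0.01 from the query
             [1.03, 0, 0, 0, 0],  # B, d=0.02
             [1.06, 0, 0, 0, 0],  # B, d=0.05
             [0.8, 0, 0, 0, 0],   # A, d=0.21
             [0.7, 0, 0, 0, 0]],  # A, d=0.31
            labels=[a, b, b, a, a],
        )
        val = make_frames([[1.01, 0, 0, 0, 0]], labels=[b])
        best, accs = gp.select_k(train, val, k_candidates=(1, 3, 5),
                                 weighting=knn.UNIFORM, scale=False)
        assert accs == {1: 0.0, 3: 100.0, 5: 0.0}
        assert best == 3

    def test_single_candidate(self, small_dataset):
        best, accs = gp.select_k(small_dataset[:70], small_dataset[70:80], k_candidates=(1,))
        assert best == 1 and set(accs) == {1}

    def test_accuracy_tie_prefers_smaller_k(self):
        # perfectly separable: every candidate scores 100%
        frames = make_frames(
            np.repeat(np.eye(5)[:2] * 5, 5, axis=0),
            labels=[Phase(i) for i in np.repeat([1, 2], 5)],
        )
        best, accs = gp.select_k(frames, frames, k_candidates=(1, 3, 5), scale=False)
        assert accs == {1: 100.0, 3: 100.0, 5: 100.0}
        assert best == 1

    def test_even_candidate_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="odd"):
            gp.select_k(small_dataset[:20], small_dataset[20:25], k_candidates=(1, 2))


class TestModelRoundTrip:
    def test_save_load_lossless(self, tmp_path, small_dataset):
        model = gp.fit(small_dataset, k=3, weighting=knn.DISTANCE_WEIGHTED)
        path = tmp_path / "model.json"
        gp.save_model(model, path)
        loaded = gp.load_model(path)
        assert loaded.k == model.k and loaded.weighting == model.weighting
        np.testing.assert_array_equal(loaded.x, model.x)
        np.testing.assert_array_equal(loaded.y, model.y)
        np.testing.assert_array_equal(loaded.scaling.mins, model.scaling.mins)
        np.testing.assert_array_equal(loaded.scaling.ranges, model.scaling.ranges)
        probe = small_dataset[::7]
        assert gp.predict(loaded, probe) == gp.predict(model, probe)
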