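from functools import lru_cache

import numpy as np
import pytest
from sklearn.ensemble import ExtraTreesRegressor

from ovicount.annotations import ROI, DotAnnotation
from ovicount.density import DensityConfig, count_from_density
from ovicount.features import FeatureConfig, compute_feature_stack
from ovicount.regressor import (
    ModelFormatError,
    TrainingSet,
    build_training_set,
    fit,
    load_model,
    predict_count,
    predict_density,
    save_model,
)


def toy_training_set(X, y):
    X = np.asarray(X, dtype=np.float32).reshape(-1, 1)
    y = np.asarray(y, dtype=np.float64)
    return TrainingSet(X=X, y=y, provenance=[("toy", ROI(0, 0, 1, len(y)))],
                       feature_names=["f0"])


class TestBuildTrainingSet:
    def test_row_count_equals_roi_area(self, small_scene):
        img, ann = small_scene
        ts = build_training_set([img], [ann], [[ROI(40, 40, 50, 50)]])
        assert ts.X.shape == (2500, 60)
        assert ts.y.shape == (2500,)

    def test_gaussian_tails_cross_roi_border(self):
        # an ROI with no dots, 2 px away from a labelled egg, still gets
        # positive density targets from the kernel tail
        img = np.zeros((60, 60, 3))
        ann = DotAnnotation("i", [(30, 28)])  # just left of the ROI
        ts = build_training_set([img], [ann], [[ROI(20, 30, 20, 20)]])
        assert (ts.y > 0).any()
        assert ts.y.sum() < 0.5  # only the tail, not the whole egg

    def test_two_disjoint_rois_concatenate_deterministically(self, small_scene):
        img, ann = small_scene
        rois = [[ROI(0, 0, 30, 40), ROI(100, 100, 20, 20)]]
        ts = build_training_set([img], [ann], rois)
        assert ts.X.shape[0] == 30 * 40 + 20 * 20
        ts2 = build_training_set([img], [ann], rois)
        assert np.array_equal(ts.X, ts2.X) and np.array_equal(ts.y, ts2.y)

    def test_empty_roi_list_rejected(self, small_scene):
        img, ann = small_scene
        with pytest.raises(ValueError, match="ROI"):
            build_training_set([img], [ann], [[]])

    def test_subsample_is_seeded_and_capped(self, small_scene):
        img, ann = small_scene
        a = build_training_set([img], [ann], max_pixels=500, seed=3)
        b = build_training_set([img], [ann], max_pixels=500, seed=3)
        assert a.X.shape[0] == 500
        assert np.array_equal(a.X, b.X)


class TestFit:
    def test_zero_targets_predict_exactly_zero(self):
        ts = toy_training_set(np.arange(10), np.zeros(10))
        m = fit(ts, n_trees=10, seed=0)
        pred = m.ensemble.predict(np.linspace(0, 9, 30).reshape(-1, 1))
        assert (pred == 0.0).all()

    def test_same_seed_same_predictions(self):
        rng = np.random.default_rng(0)
        ts = toy_training_set(rng.random(100), rng.random(100))
        probe = rng.random((50, 1)).astype(np.float32)
        p1 = fit(ts, 30, seed=5).ensemble.predict(probe)
        p2 = fit(ts, 30, seed=5).ensemble.predict(probe)
        assert np.array_equal(p1, p2)

    def test_plateau_toy_recovers_extremes(self):
        ts = toy_training_set(np.arange(10), (np.arange(10) >= 5).astype(float))
        m = fit(ts, 30, seed=1)
        lo, hi = m.ensemble.predict(np.array([[0.0], [9.0]], dtype=np.float32))
        assert lo == pytest.approx(0.0, abs=0.05)
        assert hi == pytest.approx(1.0, abs=0.05)

    def test_predictions_bounded_by_training_targets(self):
        rng = np.random.default_rng(2)
        ts = toy_training_set(rng.random(200), rng.random(200))
        m = fit(ts, 20, seed=0)
        pred = m.ensemble.predict(rng.random((100, 1)).astype(np.float32))
        assert pred.min() >= ts.y.min() - 1e-12
        assert pred.max() <= ts.y.max() + 1e-12

    def test_degenerate_identical_features_predict_mean(self):
        ts = toy_training_set(np.ones(6), [0, 0, 1, 1, 2, 2])
        m = fit(ts, 10, seed=0)
        pred = m.ensemble.predict(np.array([[1.0]], dtype=np.float32))
        assert pred[0] == pytest.approx(1.0)

    def test_invalid_tree_count_rejected(self):
        ts = toy_training_set(np.arange(4), np.arange(4.0))
        with pytest.raises(ValueError):
            fit(ts, n_trees=0)


def expected_random_split_prediction(xs, ys, q):
    """Enumeration oracle for the 1-feature random-threshold tree family.

    The threshold is uniform on (min, max) of the node's feature values, so
    each inter-value gap is cut with probability proportional to its width.
    Returns the exact expected leaf mean for query q.
    """
    values = sorted(set(xs))
    groups = {v: [y for x, y in zip(xs, ys) if x == v] for v in values}

    @lru_cache(maxsize=None)
    def node(i, j, qi):
        vs = values[i:j + 1]
        ys_node = [y for v in vs for y in groups[v]]
        if i == j or len(set(ys_node)) == 1:
            return sum(ys_node) / len(ys_node)
        span = vs[-1] - vs[0]
        out = 0.0
        for k in range(i, j):
            p = (values[k + 1] - values[k]) / span
            out += p * (node(i, k, qi) if qi <= k else node(k + 1, j, qi))
        return out

    return node(0, len(values) - 1, values.index(q))


class TestOracleEquivalence:
    def test_large_ensemble_converges_to_enumerated_expectation(self):
        xs = list(range(10))
        ys = [0.0] * 5 + [1.0] * 5
        ens = ExtraTreesRegressor(n_estimators=200, max_features=1,
                                  bootstrap=False, random_state=0, n_jobs=1)
        ens.fit(np.array(xs, dtype=np.float64).reshape(-1, 1), ys)
        preds = ens.predict(np.array(xs, dtype=np.float64).reshape(-1, 1))
        for q, pred in zip(xs, preds):
            expected = expected_random_split_prediction(xs, ys, q)
            assert pred == pytest.approx(expected, abs=0.05), f"query {q}"

    def test_oracle_on_irregular_spacing(self):
        xs = [0.0, 1.0, 10.0]
        ys = [0.0, 0.0, 1.0]
        # first cut lands in (1, 10) with probability 0.9 -> query 10 almost
        # always isolated immediately
        assert expected_random_split_prediction(xs, ys, 10.0) == pytest.approx(1.0)
        # query 0: with p=0.1 the cut lands in (0,1) isolating it (pred 0);
        # with p=0.9 it joins {0,1} which is pure (pred 0)
        assert expected_random_split_prediction(xs, ys, 0.0) == pytest.approx(0.0)
        ens = ExtraTreesRegressor(n_estimators=200, max_features=1,
                                  bootstrap=False, random_state=1, n_jobs=1)
        ens.fit(np.array(xs).reshape(-1, 1), ys)
        preds = ens.predict(np.array(xs).reshape(-1, 1))
        np.testing.assert_allclose(preds, [0.0, 0.0, 1.0], atol=0.05)


class TestPredict:
    def test_feature_mismatch_lists_names(self, small_scene):
        img, ann = small_scene
        ts = build_training_set([img], [ann], max_pixels=2000, seed=0)
        m = fit(ts, 5, seed=0)
        other = compute_feature_stack(np.asarray(img, dtype=np.float64) / 255.0,
                                      FeatureConfig(scales=(0.8, 1.6)))
        with pytest.raises(ValueError, match="sigma=3.2"):
            predict_density(m, other)

    def test_self_evaluation_recovers_count(self, small_scene):
        img, ann = small_scene
        stack = compute_feature_stack(img, dtype=np.float32)
        ts = build_training_set([img], [ann], stacks=[stack],
                                max_pixels=25_000, seed=4)
        m = fit(ts, 30, seed=4)
        pc = count_from_density(predict_density(m, stack))
        assert pc == pytest.approx(len(ann), rel=0.15)

    def test_predict_count_is_deterministic(self, small_scene):
        img, ann = small_scene
        ts = build_training_set([img], [ann], max_pixels=5000, seed=0)
        m = fit(ts, 10, seed=0)
        assert predict_count(m, img) == predict_count(m, img)
        assert predict_count(m, img) >= 0.0


@pytest.fixture(scope="module")
def archived(small_scene, tmp_path_factory):
    img, ann = small_scene
    ts = build_training_set([img], [ann], max_pixels=5000, seed=0)
    m = fit(ts, 10, seed=0)
    path = tmp_path_factory.mktemp("models") / "model.ovc"
    save_model(m, path)
    return m, path, img


class TestModelArchive:
    def test_round_trip_predictions_bit_identical(self, archived):
        m, path, img = archived
        loaded = load_model(path)
        stack = compute_feature_stack(img, dtype=np.float32)
        np.testing.assert_array_equal(
            predict_density(m, stack).values,
            predict_density(loaded, stack).values)

    def test_tampered_header_rejected(self, archived, tmp_path):
        import json
        import shutil
        import zipfile

        _, path, _ = archived
        bad = tmp_path / "tampered.ovc"
        shutil.copy(path, bad)
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            ensemble = zf.read("ensemble.joblib")
        header["feature_config"]["scales"] = [1.0, 2.0]
        with zipfile.ZipFile(bad, "w") as zf:
            zf.writestr("header.json", json.dumps(header))
            zf.writestr("ensemble.joblib", ensemble)
        with pytest.raises(ModelFormatError, match="digest"):
            load_model(bad)

    def test_unsupported_format_version_rejected(self, archived, tmp_path):
        import json
        import zipfile

        _, path, _ = archived
        bad = tmp_path / "future.ovc"
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            ensemble = zf.read("ensemble.joblib")
        header["format_version"] = 99
        with zipfile.ZipFile(bad, "w") as zf:
            zf.writestr("header.json", json.dumps(header))
            zf.writestr("ensemble.joblib", ensemble)
        with pytest.raises(ModelFormatError, match="version"):
            load_model(bad)

    def test_different_seeds_give_different_archives(self, small_scene, tmp_path):
        img, ann = small_scene
        ts = build_training_set([img], [ann], max_pixels=3000, seed=0)
        p1, p2 = tmp_path / "a.ovc", tmp_path / "b.ovc"
        save_model(fit(ts, 5, seed=1), p1)
        save_model(fit(ts, 5, seed=2), p2)
        assert p1.read_bytes() != p2.read_bytes()
        assert load_model(p1).seed == 1 and load_model(p2).seed == 2
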