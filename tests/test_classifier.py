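"""Autoscaling, PCA, NIPALS PLS-DA and the nested double cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elphase import classifier as clf
from elphase.synthetic import ClusterSpec, gen_descriptor_dataset


@pytest.fixture(scope="module")
def small_dataset():
    """Reduced two-cluster dataset (fast folds, same fold structure)."""
    spec = ClusterSpec(n_elps_per_class=4, n_replicas=1, n_timepoints=20, seed=7)
    return gen_descriptor_dataset(spec)


class TestAutoscale:
    def test_population_sd_convention(self):
        xs, model = clf.autoscale(np.array([[3.0], [5.0], [7.0]]))
        assert np.allclose(xs.ravel(), [-1.22474487, 0.0, 1.22474487])

    def test_idempotent_on_scaled_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (200, 4))
        xs, _ = clf.autoscale(x)
        xs2, _ = clf.autoscale(xs)
        assert np.allclose(xs, xs2, atol=1e-10)

    def test_constant_column_dropped(self):
        x = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.warns(UserWarning, match="constant"):
            xs, model = clf.autoscale(x)
        assert xs.shape[1] == 1
        assert model.dropped == ["x1"]

    def test_apply_then_invert_round_trips(self):
        rng = np.random.default_rng(1)
        x = rng.normal(3, 2, (50, 3))
        xs, model = clf.autoscale(x)
        assert np.allclose(model.invert(xs), x, atol=1e-10)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            clf.autoscale(np.ones((4, 2)))


class TestPCA:
    def test_rank_one_data_single_component(self):
        v = np.array([1.0, -2.0, 0.5])
        t = np.linspace(-1, 1, 30)
        x = np.outer(t, v)
        model = clf.fit_pca(x, 2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (50, 10))
        x -= x.mean(axis=0)
        model = clf.fit_pca(x, 4)
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        for a in range(4):
            dot = abs(model.loadings[:, a] @ vt[a])
            assert dot == pytest.approx(1.0, abs=1e-10)

    def test_reconstruction_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (40, 8))
        x -= x.mean(axis=0)
        for k in (1, 3, 8):
            m = clf.fit_pca(x, k)
            assert np.linalg.norm(x - m.scores @ m.loadings.T - m.residual) < 1e-8

    def test_full_rank_residual_vanishes(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (30, 5))
        x -= x.mean(axis=0)
        m = clf.fit_pca(x, 5)
        assert np.linalg.norm(m.residual) < 1e-8

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            clf.fit_pca(np.zeros((4, 10)), 5)


class TestPLSDA:
    def _random_problem(self, seed, n=60, p=8):
        rng = np.random.default_rng(seed)
        y = (rng.uniform(size=n) > 0.5).astype(float)
        x = rng.normal(0, 1, (n, p)) + np.outer(y, rng.normal(0, 1, p))
        xs, _ = clf.autoscale(x)
        return xs, y

    def test_first_weight_is_normalized_xty(self):
        xs, y = self._random_problem(5)
        model = clf.fit_plsda(xs, y, 1)
        w_expected = xs.T @ (y - y.mean())
        w_expected /= np.linalg.norm(w_expected)
        assert np.allclose(model.weights[:, 0], w_expected, atol=1e-12)

    def test_weights_unit_norm(self):
        xs, y = self._random_problem(6)
        model = clf.fit_plsda(xs, y, 3)
        assert np.allclose(np.linalg.norm(model.weights, axis=0), 1.0)

    def test_separable_centroids_classified_with_one_component(self):
        rng = np.random.default_rng(7)
        y = np.repeat([0.0, 1.0], 30)
        x = rng.normal(0, 0.5, (60, 5))
        x[y == 1, 0] += 6.0
        xs, _ = clf.autoscale(x)
        model = clf.fit_plsda(xs, y, 1)
        yhat = model.transform_predict(xs)
        assert np.all((yhat > 0.5) == (y == 1))

    def test_residual_orthogonal_to_scores(self):
        xs, y = self._random_problem(8)
        model = clf.fit_plsda(xs, y, 3)
        assert np.allclose(model.scores.T @ model.y_residual, 0.0, atol=1e-8)

    def test_matches_sklearn_pls1_reference(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        xs, y = self._random_problem(9)
        k = 3
        model = clf.fit_plsda(xs, y, k)
        ref = sklearn_pls.PLSRegression(n_components=k, scale=False).fit(xs, y)
        ref_pred = ref.predict(xs).ravel()
        # identical components; intercepts differ by (0.5 - y_mean)
        ours = model.transform_predict(xs) - 0.5 + y.mean()
        assert np.allclose(ours, ref_pred, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            clf.fit_plsda(np.zeros((4, 2)), np.ones(4), 1)

    def test_k_beyond_rank_rejected(self):
        x = np.outer(np.arange(10.0) - 4.5, [1.0, 2.0])  # rank 1
        y = (np.arange(10) >= 5).astype(float)
        with pytest.raises(ValueError, match="rank"):
            clf.fit_plsda(x, y, 2)


class TestClassifyAndCI:
    @pytest.mark.parametrize("value, cls", [(0.9, 1), (0.1, 0), (0.5, 0)])
    def test_threshold(self, value, cls):
        assert clf.classify(value) == cls

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            clf.classify(float("nan"))

    def test_identical_predictions_zero_width(self):
        lo, hi = clf.confidence_interval([0.7, 0.7, 0.7])
        assert lo == pytest.approx(0.7)
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_two_point_interval_closed_form(self):
        lo, hi = clf.confidence_interval([0.8, 0.9])
        half = stats.t.ppf(0.995, 1) * np.std([0.8, 0.9], ddof=1) / np.sqrt(2)
        assert hi - lo == pytest.approx(2 * half)
        assert (lo + hi) / 2 == pytest.approx(0.85)
        assert half == pytest.approx(3.1828, abs=1e-3)

    def test_single_prediction_rejected(self):
        with pytest.raises(ValueError):
            clf.confidence_interval([0.5])


class TestSelectComponents:
    def test_smallest_correct_k(self):
        path = np.array([0.4, 0.7, 0.9])
        k, fellback = clf.select_components(path, 1, k_max=3)
        assert (k, fellback) == (2, False)

    def test_fallback_max_margin_flagged(self):
        path = np.array([0.45, 0.30, 0.10])
        k, fellback = clf.select_components(path, 1, k_max=3)
        assert fellback and k == 1

    def test_kmax_one_forced(self):
        k, _ = clf.select_components(np.array([0.2, 0.9]), 1, k_max=1)
        assert k == 1


class TestDoubleCV:
    def test_fold_arithmetic_eight_elps(self, small_dataset):
        data, labels, _ = small_dataset
        res = clf.double_cross_validate(data, labels, k_max=3)
        n = len(labels)
        for e, p in res.per_elp.items():
            assert len(p.predictions) == n - 1
        assert sum(len(v) for v in res.chosen_components.values()) == n * (n - 1)

    def test_six_elps_five_predictions_each(self):
        spec = ClusterSpec(n_elps_per_class=3, n_replicas=1, n_timepoints=30, seed=3)
        data, labels, _ = gen_descriptor_dataset(spec)
        res = clf.double_cross_validate(data, labels, k_max=2)
        assert all(len(p.predictions) == 5 for p in res.per_elp.values())
        assert sum(len(v) for v in res.chosen_components.values()) == 6 * 5

    def test_fewer_than_three_elps_rejected(self):
        spec = ClusterSpec(n_elps_per_class=1, n_replicas=1, n_timepoints=10, seed=3)
        data, labels, _ = gen_descriptor_dataset(spec)
        with pytest.raises(ValueError, match="at least 3"):
            clf.double_cross_validate(data, labels)

    def test_no_test_rows_in_training(self, small_dataset, monkeypatch):
        """Leakage audit: every fit sees exactly total − test − val rows."""
        data, labels, _ = small_dataset
        rows_per_elp = data.groupby("elp").size().to_dict()
        total = len(data)
        seen_sizes = []
        original = clf.fit_plsda

        def spy(X, y, k):
            seen_sizes.append(len(X))
            return original(X, y, k)

        monkeypatch.setattr(clf, "fit_plsda", spy)
        clf.double_cross_validate(data, labels, k_max=2)
        n_rows = set(rows_per_elp.values())
        assert len(n_rows) == 1
        expected = total - 2 * n_rows.pop()
        assert seen_sizes and all(s == expected for s in seen_sizes)

    def test_metadata_travels_together(self, small_dataset):
        # grouping is by ELP: shuffling rows must not change the result
        data, labels, _ = small_dataset
        shuffled = data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = clf.double_cross_validate(data, labels, k_max=2)
        b = clf.double_cross_validate(shuffled, labels, k_max=2)
        for e in labels:
            assert a.per_elp[e].mean == pytest.approx(b.per_elp[e].mean)

    def test_single_class_fold_skipped_with_warning(self):
        spec = ClusterSpec(n_elps_per_class=2, n_replicas=1, n_timepoints=25, seed=4)
        data, labels, _ = gen_descriptor_dataset(spec)
        lopsided = dict(labels)
        # relabel so only one ELP carries class 1
        ones = [e for e, l in lopsided.items() if l == 1]
        for e in ones[1:]:
            lopsided[e] = 0
        with pytest.warns(UserWarning):
            res = clf.double_cross_validate(data, lopsided, k_max=2)
        assert res.per_elp  # still produced predictions for some ELPs

    def test_deterministic(self, small_dataset):
        data, labels, _ = small_dataset
        a = clf.double_cross_validate(data, labels, k_max=3)
        b = clf.double_cross_validate(data, labels, k_max=3)
        assert a.to_report() == b.to_report()

    def test_missing_elp_rows_rejected(self, small_dataset):
        data, labels, _ = small_dataset
        bad = dict(labels, ghost=1)
        with pytest.raises(ValueError, match="ghost"):
            clf.double_cross_validate(data, bad)


def test_predict_plsda_aggregates_per_elp(small_dataset):
    data, labels, _ = small_dataset
    feature_cols = [c for c in data.columns if c not in clf.META_COLUMNS]
    xs, scaler = clf.autoscale(data[feature_cols])
    y = data["elp"].map(labels).to_numpy(dtype=float)
    model = clf.fit_plsda(xs, y, 2)
    agg = clf.predict_plsda(model, scaler, data)
    assert set(agg.index) == set(labels)
    # identical rows aggregate to the single-row prediction
    one = data.iloc[[0]].copy()
    single = clf.predict_plsda(model, scaler, one)
    row_pred = model.transform_predict(scaler.apply(one[feature_cols]))
    assert single.iloc[0] == pytest.approx(row_pred[0])
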