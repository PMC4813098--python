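"""Maxent core: variable filter, convex fit, output transforms, AUC."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from richcompare import maxent_core as mx
from richcompare.raster import GridGeometry, RasterGrid


def make_layers(arrays):
    geom = GridGeometry(ncols=arrays[0].shape[1], nrows=arrays[0].shape[0])
    return {f"L{i}": RasterGrid(geom, a) for i, a in enumerate(arrays)}


def correlated(rng, base, rho, n):
    return rho * base + np.sqrt(1 - rho**2) * rng.standard_normal(n)


class TestSelectVariables:
    def _bg(self, n):
        return np.arange(n)

    def test_highly_correlated_pair_drops_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(400)
        b = correlated(rng, a, 0.97, 400)
        layers = make_layers([a.reshape(20, 20), b.reshape(20, 20)])
        retained, report = mx.select_variables(layers, self._bg(400))
        assert len(retained) == 1
        assert len(report) == 1

    def test_hub_layer_dropped_keeps_its_satellites(self):
        """A correlated with both B and C (B,C mutually uncorrelated):
        dropping A alone resolves every conflict."""
        rng = np.random.default_rng(1)
        cov = np.array([[1.0, 0.85, 0.85], [0.85, 1.0, 0.5], [0.85, 0.5, 1.0]])
        abc = rng.multivariate_normal(np.zeros(3), cov, size=2500)
        a, b, c = abc.T
        layers = make_layers([x.reshape(50, 50) for x in (a, b, c)])
        bg = self._bg(2500)
        r_ab = np.corrcoef(a, b)[0, 1]
        r_ac = np.corrcoef(a, c)[0, 1]
        assert min(abs(r_ab), abs(r_ac)) > 0.8  # fixture sanity
        retained, _ = mx.select_variables(layers, bg)
        assert retained == ["L1", "L2"]
        # brute-force all-pairs check of the retained set
        for n1, n2 in itertools.combinations(retained, 2):
            r = np.corrcoef(
                layers[n1].values.ravel()[bg], layers[n2].values.ravel()[bg]
            )[0, 1]
            assert abs(r) <= 0.8

    def test_uncorrelated_layers_all_retained(self):
        rng = np.random.default_rng(2)
        layers = make_layers([rng.standard_normal((20, 20)) for _ in range(4)])
        retained, report = mx.select_variables(layers, self._bg(400))
        assert len(retained) == 4
        assert report == []

    def test_constant_layer_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        layers = make_layers(
            [np.zeros((10, 10)), rng.standard_normal((10, 10))]
        )
        with pytest.warns(UserWarning, match="constant"):
            retained, report = mx.select_variables(layers, self._bg(100))
        assert retained == ["L1"]


def binary_feature_problem(p0=0.5, p1=0.8, n_bg=1000, m=20):
    """Single unstandardized binary feature with exact sample means."""
    col = np.zeros(n_bg)
    col[: int(p0 * n_bg)] = 1.0
    features = mx.FeatureSet(["f"], col[:, None], np.array([1.0]))
    presence = np.concatenate(
        [np.arange(int(p1 * m)), np.arange(int(p0 * n_bg), int(p0 * n_bg) + m - int(p1 * m))]
    )
    return features, presence, np.arange(n_bg)


class TestFitMaxent:
    def test_closed_form_log_odds_ratio(self):
        """With one binary feature and no penalty the moment condition has
        the closed form lambda = ln(p1 (1-p0) / (p0 (1-p1)))."""
        features, presence, bg = binary_feature_problem()
        # the default tol stops on objective change; pin it down for a
        # parameter-precision check
        model = mx.fit_maxent(presence, bg, features, beta=0.0, tol=1e-10)
        expected = np.log(0.8 * 0.5 / (0.5 * 0.2))  # ln 4
        assert abs(model.lam[0] - expected) < 1e-4

    def test_constant_features_give_uniform_model(self):
        n = 500
        features = mx.FeatureSet(["z"], np.zeros((n, 1)), np.array([1.0]))
        model = mx.fit_maxent(np.arange(10), np.arange(n), features)
        assert model.lam[0] == 0.0
        raw = mx.predict_raw(model, np.arange(n))
        np.testing.assert_allclose(raw, 1.0 / n)

    def test_huge_penalty_shrinks_to_zero(self):
        features, presence, bg = binary_feature_problem()
        model = mx.fit_maxent(presence, bg, features, beta=1e6)
        np.testing.assert_allclose(model.lam, 0.0)

    def test_l1_norm_monotone_in_beta(self):
        features, presence, bg = binary_feature_problem()
        norms = [
            np.abs(mx.fit_maxent(presence, bg, features, beta=b).lam).sum()
            for b in [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_zero_presences_rejected(self):
        features, _, bg = binary_feature_problem()
        with pytest.raises(ValueError):
            mx.fit_maxent(np.array([], dtype=int), bg, features)

    def test_non_finite_features_rejected(self):
        mat = np.ones((50, 1))
        mat[3, 0] = np.nan
        features = mx.FeatureSet(["f"], mat, np.array([1.0]))
        with pytest.raises(ValueError, match="finite"):
            mx.fit_maxent(np.array([0]), np.arange(50), features)

    def test_entropy_within_bounds(self, small_world):
        landscape = small_world["landscape"]
        bg = mx.sample_background(landscape.geometry.n_cells, 2000, seed=4)
        retained, _ = mx.select_variables(landscape.continuous_layers, bg)
        features = mx.build_features(landscape, retained, bg)
        occ = small_world["occupancies"][0]
        presence = np.flatnonzero(occ.values.ravel())[:150]
        model = mx.fit_maxent(presence, bg, features)
        assert 0.0 <= model.entropy <= np.log(bg.size)


class TestPredictions:
    def test_raw_sums_to_one_over_background(self, small_world):
        landscape = small_world["landscape"]
        bg = mx.sample_background(landscape.geometry.n_cells, 2000, seed=4)
        features = mx.build_features(landscape, landscape.layer_names[:3], bg)
        presence = np.flatnonzero(small_world["occupancies"][1].values.ravel())[:100]
        model = mx.fit_maxent(presence, bg, features)
        assert abs(mx.predict_raw(model, bg).sum() - 1.0) < 1e-9

    def test_raw_monotone_in_single_feature(self):
        grad = np.linspace(-2, 2, 200)[:, None]
        features = mx.FeatureSet(["g"], grad, np.array([1.0]))
        model = mx.fit_maxent(np.arange(150, 200), np.arange(200), features, beta=0.5)
        assert model.lam[0] > 0
        raw = mx.predict_raw(model)
        assert np.all(np.diff(raw) > 0)

    def test_uniform_model_logistic_half(self):
        n = 400
        features = mx.FeatureSet(["z"], np.zeros((n, 1)), np.array([1.0]))
        model = mx.fit_maxent(np.arange(5), np.arange(n), features)
        logistic = mx.predict_logistic(model, np.arange(n))
        np.testing.assert_allclose(logistic, 0.5, atol=1e-12)

    def test_logistic_vanishes_with_raw(self):
        features, presence, bg = binary_feature_problem()
        model = mx.fit_maxent(presence, bg, features)
        assert mx.raw_to_logistic(model, np.array([0.0]))[0] == 0.0
        tiny = mx.raw_to_logistic(model, np.array([1e-300]))[0]
        assert 0.0 < tiny < 1e-100

    def test_logistic_preserves_raw_ordering(self):
        rng = np.random.default_rng(5)
        features, presence, bg = binary_feature_problem()
        model = mx.fit_maxent(presence, bg, features)
        raw = rng.uniform(0, 1e-2, 50)
        logistic = mx.raw_to_logistic(model, raw)
        assert np.array_equal(np.argsort(raw), np.argsort(logistic))
        assert np.all((logistic > 0) & (logistic < 1))


def pairwise_auc_oracle(pos, neg):
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in pos
        for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_worked_example(self):
        assert mx.auc_score([0.9, 0.8], [0.7, 0.85]) == 0.75

    def test_perfect_separation(self):
        assert mx.auc_score([0.9, 0.95], [0.1, 0.2]) == 1.0

    def test_all_ties(self):
        assert mx.auc_score([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    @given(
        st.lists(st.integers(0, 9), min_size=1, max_size=30),
        st.lists(st.integers(0, 9), min_size=1, max_size=30),
    )
    def test_matches_pairwise_oracle(self, pos, neg):
        # coarse integer scores force plenty of ties
        assert mx.auc_score(pos, neg) == pytest.approx(
            pairwise_auc_oracle(pos, neg), abs=0
        )


class TestCvAuc:
    def _setup(self, small_world, sp=2, n_bg=2000):
        landscape = small_world["landscape"]
        bg = mx.sample_background(landscape.geometry.n_cells, n_bg, seed=4)
        retained, _ = mx.select_variables(landscape.continuous_layers, bg)
        features = mx.build_features(landscape, retained, bg)
        presence = np.flatnonzero(small_world["occupancies"][sp].values.ravel())
        return features, presence, bg

    def test_separable_species_scores_high(self, small_world):
        features, presence, bg = self._setup(small_world)
        rng = np.random.default_rng(0)
        presence = rng.choice(presence, 120, replace=False)
        cv = mx.cv_auc(presence, bg, features, k=5, seed=1)
        assert len(cv.fold_aucs) == 5
        assert cv.mean_auc > 0.6
        assert np.all((cv.mean_logistic >= 0) & (cv.mean_logistic <= 1))

    def test_folds_reduced_with_warning(self, small_world):
        features, presence, bg = self._setup(small_world)
        with pytest.warns(UserWarning, match="reducing folds"):
            cv = mx.cv_auc(presence[:6], bg, features, k=10, seed=1)
        assert cv.k == 6

    def test_too_few_presences_rejected(self, small_world):
        features, presence, bg = self._setup(small_world)
        with pytest.raises(ValueError):
            mx.cv_auc(presence[:1], bg, features, k=10, seed=1)
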