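"""Marker-effect extraction: linear effects, impurity importance, Shapley
scores (against exact enumeration), pairwise interactions, normalization,
ensembling and genome-track binning."""

import math

import numpy as np
import pytest
from _oracles import exact_shapley

from ensgp import effects as fx
from ensgp import models as md
from ensgp import simulate as sim

FAST = {"n_iter": 1_500, "burn_in": 300}


class _LinearModel:
    """Stand-in predictor f(x) = b0 + beta . x for closed-form checks."""

    model_id = "SVR"

    def __init__(self, beta, b0=0.0):
        self.beta = np.asarray(beta, float)
        self.b0 = b0

    def predict(self, X):
        return self.b0 + np.atleast_2d(X) @ self.beta


class TestLinearEffects:
    def test_constant_y_all_zero(self):
        X = np.random.default_rng(0).integers(0, 3, (20, 8)).astype(float)
        m = md.RRBlupModel(**FAST, seed=1).fit(X, np.full(20, 2.0))
        prof = fx.effects_linear(m)
        assert np.abs(prof.raw).max() < 1e-3

    def test_single_qtl_is_max_effect(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, (80, 20)).astype(float)
        y = 3.0 * X[:, 7] + rng.normal(0, 0.5, 80)
        m = md.BayesBModel(**FAST, seed=2).fit(X, y)
        prof = fx.effects_linear(m)
        assert np.argmax(np.abs(prof.raw)) == 7

    def test_marker_ids_trim_factor_columns(self):
        X = np.random.default_rng(2).normal(size=(30, 11))
        y = X[:, 0] + np.random.default_rng(3).normal(size=30)
        m = md.RRBlupModel(**FAST, seed=3).fit(X, y)
        prof = fx.effects_linear(m, marker_ids=[f"m{j}" for j in range(10)])
        assert len(prof.raw) == 10

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError):
            fx.effects_linear(md.RRBlupModel(**FAST))


class TestImpurityEffects:
    def test_unused_feature_zero_importance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        X[:, 2] = 1.0  # constant feature can never be split on
        y = X[:, 0] * 2
        m = md.RandomForestModel(n_trees=50, seed=1).fit(X, y)
        prof = fx.effects_impurity(m)
        assert prof.raw[2] == 0.0

    def test_importances_sum_to_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 5))
        y = X[:, 0] + 0.5 * X[:, 1]
        m = md.RandomForestModel(n_trees=50, seed=2).fit(X, y)
        assert fx.effects_impurity(m).raw.sum() == pytest.approx(1.0)

    def test_predictive_feature_dominates(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 2))
        y = 3.0 * X[:, 0] + rng.normal(0, 0.1, 80)
        m = md.RandomForestModel(n_trees=100, seed=3).fit(X, y)
        prof = fx.effects_impurity(m)
        assert prof.raw[0] > 3 * prof.raw[1]


class TestShapley:
    def test_linear_closed_form(self):
        # additive predictor with independent background:
        # phi_j = beta_j * (x_j - mean background_j)
        rng = np.random.default_rng(7)
        beta = np.array([2.0, -1.0, 0.5, 0.0])
        model = _LinearModel(beta, b0=1.0)
        background = rng.integers(0, 3, (40, 4)).astype(float)
        x = np.array([2.0, 0.0, 1.0, 2.0])
        phi, _ = fx.shapley_values(model.predict, x[None, :], background, 2_000, seed=1)
        expected = beta * (x - background.mean(axis=0))
        assert np.abs(phi[0] - expected).max() < 0.05

    def test_ignored_marker_gets_zero(self):
        model = _LinearModel([1.5, 0.0, -2.0])
        background = np.random.default_rng(8).integers(0, 3, (30, 3)).astype(float)
        x = np.array([1.0, 2.0, 0.0])
        phi, _ = fx.shapley_values(model.predict, x[None, :], background, 1_000, seed=2)
        assert abs(phi[0, 1]) < 0.05

    def test_matches_exact_enumeration_4_markers(self):
        # nonlinear 4-marker model vs exact subset enumeration
        rng = np.random.default_rng(9)

        class Interacting:
            def predict(self, X):
                X = np.atleast_2d(X)
                return X[:, 0] - 0.5 * X[:, 1] + 0.8 * X[:, 2] * X[:, 3]

        model = Interacting()
        background = rng.integers(0, 3, (5, 4)).astype(float)
        x = np.array([2.0, 1.0, 2.0, 1.0])
        phi, _ = fx.shapley_values(model.predict, x[None, :], background, 12_000, seed=3)
        exact = exact_shapley(model.predict, x, background)
        assert np.abs(phi[0] - exact).max() < 1e-2

    def test_efficiency_enforced(self):
        rng = np.random.default_rng(10)
        X = rng.integers(0, 3, (50, 6)).astype(float)
        y = X[:, 0] - X[:, 3] + rng.normal(0, 0.2, 50)
        m = md.SVRModel().fit(X, y)
        prof = fx.shapley_effects(
            m, X[:8], X, n_permutations=40, seed=4, y_spread=float(np.ptp(y))
        )
        assert prof.method == "shapley"
        assert (prof.raw >= 0).all()

    def test_empty_background_rejected(self):
        model = _LinearModel([1.0])
        with pytest.raises(ValueError):
            fx.shapley_values(model.predict, np.ones((1, 1)), np.empty((0, 1)), 10, 0)


@pytest.fixture(scope="module")
def epistatic_rf():
    rng = np.random.default_rng(11)
    X = rng.integers(0, 3, (300, 8)).astype(float)
    y = 3.0 * X[:, 1] * X[:, 5] + rng.normal(0, 0.2, 300)
    model = md.RandomForestModel(n_trees=200, seed=5, max_features=1.0).fit(X, y)
    return model, X


class TestPairwiseShapley:

    def test_epistatic_pair_ranks_first(self, epistatic_rf):
        model, X = epistatic_rf
        result = fx.pairwise_shapley_rf(model, X[:25], seed=6, n_samples=120)
        top = result.all_scores.iloc[0]
        assert {top["marker_i"], top["marker_j"]} == {"m1", "m5"}
        assert top["score"] > 5 * result.all_scores["score"].iloc[1]

    def test_additive_trait_indistinguishable_from_permuted_null(self, epistatic_rf):
        # a purely additive trait must not produce interaction scores beyond
        # what an RF fitted to permuted phenotypes produces
        _, X = epistatic_rf
        rng = np.random.default_rng(12)
        y_add = 3.0 * X[:, 1] + 2.0 * X[:, 5] + rng.normal(0, 0.2, X.shape[0])
        m_add = md.RandomForestModel(n_trees=200, seed=7, max_features=1.0).fit(X, y_add)
        s_add = fx.pairwise_shapley_rf(m_add, X[:25], seed=8, n_samples=120)
        y_perm = np.random.default_rng(13).permutation(y_add)
        m_null = md.RandomForestModel(n_trees=200, seed=9, max_features=1.0).fit(X, y_perm)
        s_null = fx.pairwise_shapley_rf(m_null, X[:25], seed=10, n_samples=120)
        assert s_add.all_scores["score"].max() <= 1.5 * s_null.all_scores["score"].max()

    def test_selection_size_and_symmetry(self, epistatic_rf):
        model, X = epistatic_rf
        result = fx.pairwise_shapley_rf(model, X[:10], seed=14, n_samples=10)
        p = 8
        expected = max(1, math.ceil(1e-4 * p * (p - 1) / 2))
        assert len(result.pairs) == expected
        # unordered pairs: every score is stored once with i < j
        pairs = list(zip(result.all_scores["marker_i"], result.all_scores["marker_j"]))
        assert all(int(a[1:]) < int(b[1:]) for a, b in pairs)
        assert len(pairs) == p * (p - 1) // 2

    def test_single_marker_rejected(self, epistatic_rf):
        model, X = epistatic_rf
        with pytest.raises(ValueError):
            fx.pairwise_shapley_rf(model, X[:5, :1], seed=0)


class TestNormalizeAndEnsemble:
    def test_max_scaling_arithmetic(self):
        prof = fx.MarkerEffectProfile("rrBLUP", "allele_substitution", ["a", "b", "c"],
                                      np.array([2.0, -1.0, 0.0]))
        out = fx.normalize_effects(prof)
        assert np.allclose(out.normalized, [1.0, 0.5, 0.0])

    def test_all_zero_profile(self):
        prof = fx.MarkerEffectProfile("RF", "impurity", ["a"], np.zeros(1))
        assert fx.normalize_effects(prof).normalized[0] == 0.0

    def test_scale_invariance(self, rng):
        raw = rng.normal(size=12)
        a = fx.normalize_effects(fx.MarkerEffectProfile("SVR", "shapley", list(range(12)), raw))
        b = fx.normalize_effects(fx.MarkerEffectProfile("SVR", "shapley", list(range(12)), -3.7 * raw))
        assert np.allclose(a.normalized, b.normalized)

    def test_ensemble_idempotent_on_identical_members(self, rng):
        raw = np.abs(rng.normal(size=6))
        profs = [
            fx.normalize_effects(fx.MarkerEffectProfile(m, "shapley", list("abcdef"), raw))
            for m in ("rrBLUP", "BayesB", "RKHS")
        ]
        ens = fx.ensemble_effects(profs)
        assert np.allclose(ens.normalized, profs[0].normalized)

    def test_ensemble_mean_and_bounds(self):
        p1 = fx.MarkerEffectProfile("rrBLUP", "allele_substitution", ["a"], np.array([1.0]),
                                    np.array([0.0]))
        p2 = fx.MarkerEffectProfile("RF", "impurity", ["a"], np.array([1.0]), np.array([1.0]))
        ens = fx.ensemble_effects([p1, p2])
        assert ens.normalized[0] == pytest.approx(0.5)

    def test_marker_mismatch_rejected(self):
        p1 = fx.MarkerEffectProfile("rrBLUP", "allele_substitution", ["a"], np.ones(1))
        p2 = fx.MarkerEffectProfile("RF", "impurity", ["b"], np.ones(1))
        with pytest.raises(ValueError):
            fx.ensemble_effects([p1, p2])


class TestQuantileBinTrack:
    @staticmethod
    def _map(n):
        return sim.simulate_map(1, n, 100, 1_000, seed=3)

    def test_ten_distinct_values_one_per_level(self):
        gmap = self._map(10)
        prof = fx.MarkerEffectProfile(
            "ensemble", "ensemble", list(gmap.marker_id),
            np.arange(10) / 9.0, np.arange(10) / 9.0,
        )
        track = fx.quantile_bin_track(prof, gmap)
        assert sorted(track["level"]) == list(range(1, 11))

    def test_constant_profile_all_level_one(self):
        gmap = self._map(7)
        vals = np.full(7, 0.4)
        prof = fx.MarkerEffectProfile("RF", "impurity", list(gmap.marker_id), vals, vals)
        assert (fx.quantile_bin_track(prof, gmap)["level"] == 1).all()

    def test_levels_match_sort_based_oracle(self, rng):
        gmap = self._map(40)
        vals = rng.random(40)
        prof = fx.MarkerEffectProfile("SVR", "shapley", list(gmap.marker_id), vals, vals)
        track = fx.quantile_bin_track(prof, gmap)
        cuts = np.quantile(np.sort(vals), np.arange(1, 10) / 10)  # independent decile calc
        expected = np.array([1 + int((cuts < v).sum()) for v in vals])
        assert np.array_equal(track["level"].to_numpy(), expected)

    def test_misaligned_profile_rejected(self):
        gmap = self._map(5)
        prof = fx.MarkerEffectProfile("RF", "impurity", ["x"], np.ones(1), np.ones(1))
        with pytest.raises(ValueError):
            fx.quantile_bin_track(prof, gmap)
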