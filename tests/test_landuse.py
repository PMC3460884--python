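import numpy as np
import pytest
from scipy.stats import spearmanr

from ensemblesdm.ensemble import ConsensusMap
from ensemblesdm.grid import Grid
from ensemblesdm.landuse import (
    FineLandscape,
    TransitionMatrix,
    estimate_transition,
    fit_conversion_suitability,
    habitat_filter,
    native_fraction,
    project_landuse,
)
from ensemblesdm.synthetic import ANTHROPIC, NATIVE, generate_landuse_pair


class TestEstimateTransition:
    def test_unchanged_map_gives_identity(self, rng):
        m = rng.integers(0, 2, size=(10, 10))
        t = estimate_transition(m, m)
        assert np.allclose(t.P, np.eye(2))

    def test_counted_example(self):
        t0 = np.array([NATIVE, NATIVE, NATIVE, ANTHROPIC])
        t1 = np.array([NATIVE, ANTHROPIC, NATIVE, ANTHROPIC])
        t = estimate_transition(t0, t1)
        assert np.allclose(t.P, [[2 / 3, 1 / 3], [0, 1]])

    def test_all_native_converted(self):
        t0 = np.full(10, NATIVE)
        t1 = np.full(10, ANTHROPIC)
        t = estimate_transition(t0, t1)
        assert t.prob(NATIVE, ANTHROPIC) == 1.0

    def test_absent_class_keeps_identity_row(self):
        t0 = np.full(6, NATIVE)
        t = estimate_transition(t0, t0)
        assert t.prob(ANTHROPIC, ANTHROPIC) == 1.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_transition(np.zeros(4), np.zeros(5))

    def test_row_stochastic_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TransitionMatrix((0, 1), np.array([[0.5, 0.4], [0, 1]]))


class TestProjectLanduse:
    def test_identity_matrix_leaves_map_unchanged(self, rng):
        m = rng.integers(0, 2, size=(12, 12))
        P = TransitionMatrix((NATIVE, ANTHROPIC), np.eye(2))
        out = project_landuse(m, P, n_steps=5, suitability=rng.random(m.shape))
        assert np.array_equal(out, m)

    def test_ten_percent_step_converts_top_100_by_score(self, rng):
        m = np.full(1000, NATIVE)
        P = TransitionMatrix((NATIVE, ANTHROPIC), [[0.9, 0.1], [0, 1]])
        suit = rng.permutation(np.linspace(0, 1, 1000))
        out = project_landuse(m, P, n_steps=1, suitability=suit)
        converted = np.flatnonzero(out == ANTHROPIC)
        assert len(converted) == 100
        assert set(converted) == set(np.argsort(-suit)[:100])

    def test_two_steps_geometric_decay(self, rng):
        m = np.full(1000, NATIVE)
        P = TransitionMatrix((NATIVE, ANTHROPIC), [[0.9, 0.1], [0, 1]])
        out = project_landuse(m, P, n_steps=2, suitability=rng.random(1000))
        assert (out == NATIVE).sum() == 810  # 1000 -> 900 -> 810

    def test_native_area_non_increasing(self, rng):
        m = rng.integers(0, 2, size=400)
        P = TransitionMatrix((NATIVE, ANTHROPIC), [[0.8, 0.2], [0, 1]])
        suit = rng.random(400)
        prev = (m == NATIVE).sum()
        for steps in (1, 2, 3):
            cur = (project_landuse(m, P, steps, suit) == NATIVE).sum()
            assert cur <= prev
            prev = cur

    def test_stochastic_mode_seeded_and_counts_match(self, rng):
        m = np.full(500, NATIVE)
        P = TransitionMatrix((NATIVE, ANTHROPIC), [[0.9, 0.1], [0, 1]])
        suit = rng.random(500)
        a = project_landuse(m, P, 1, suit, mode="stochastic", seed=4)
        b = project_landuse(m, P, 1, suit, mode="stochastic", seed=4)
        assert np.array_equal(a, b)
        assert (a == ANTHROPIC).sum() == 50

    def test_one_step_reproduces_observed_counts(self):
        # estimate from t0 -> t1, then one expected-quantity step from t0
        pair = generate_landuse_pair((30, 30), conversion_rate=0.15, seed=9)
        t = estimate_transition(pair.t0, pair.t1)
        out = project_landuse(pair.t0, t, 1, pair.truth_score)
        assert abs((out == NATIVE).sum() - (pair.t1 == NATIVE).sum()) <= 1


class TestConversionSuitability:
    def test_recovers_planted_logistic_ranking(self):
        pair = generate_landuse_pair((50, 50), conversion_rate=0.25, seed=5)
        landscape = FineLandscape(pair.t0, pair.covariates, block=5)
        converted = (pair.t0 == NATIVE) & (pair.t1 == ANTHROPIC)
        scores = fit_conversion_suitability(landscape, converted)
        native = pair.t0 == NATIVE
        rho = spearmanr(scores[native], pair.truth_score[native]).statistic
        assert rho > 0.9
        s = scores[native]
        assert (s >= 0).all() and (s <= 1).all()

    def test_pure_noise_covariates_give_no_skill(self, rng):
        from ensemblesdm.sdm import roc_threshold, evaluate_at_threshold

        pair = generate_landuse_pair((40, 40), conversion_rate=0.3, seed=6)
        noise_cov = {f"n{i}": rng.normal(size=(40, 40)) for i in range(3)}
        landscape = FineLandscape(pair.t0, noise_cov, block=5)
        converted = (pair.t0 == NATIVE) & (pair.t1 == ANTHROPIC)
        native = pair.t0 == NATIVE
        # split native cells into fit/validation halves
        idx = np.flatnonzero(native.ravel())
        half = len(idx) // 2
        X = landscape.covariate_matrix()
        y = converted.ravel().astype(int)
        from ensemblesdm.sdm import fit_model

        model = fit_model("GLM", X[idx[:half]], y[idx[:half]])
        res = roc_threshold(model.predict(X[idx[:half]]), y[idx[:half]])
        val = evaluate_at_threshold(
            model.predict(X[idx[half:]]), y[idx[half:]], res.threshold
        )
        assert abs(val.tss) < 0.2


class TestHabitatFilter:
    def _consensus(self, grid, freq):
        return ConsensusMap("sp", "current", grid, np.asarray(freq, dtype=float))

    def test_all_native_landscape_is_identity(self):
        g = Grid(2, 2, cell_size=1.0)
        fine = np.full((4, 4), NATIVE)
        landscape = FineLandscape(fine, {}, block=2)
        cm = self._consensus(g, [0.9, 0.6, 0.4, 0.8])
        out = habitat_filter(cm, fine, landscape, 0.5)
        assert np.allclose(out.frequency, cm.frequency)

    def test_low_native_fraction_removes_presence(self):
        g = Grid(1, 2, cell_size=1.0)
        fine = np.zeros((2, 4), dtype=int)
        fine[:, 2:] = ANTHROPIC  # right coarse cell fully anthropic
        fine[0, 0] = ANTHROPIC  # left cell native fraction 3/4
        landscape = FineLandscape(fine, {}, block=2)
        cm = self._consensus(g, [0.9, 0.9])
        out = habitat_filter(cm, fine, landscape, 0.5)
        assert out.presence.tolist() == [1, 0]

    def test_threshold_zero_is_identity(self):
        g = Grid(2, 2, cell_size=1.0)
        fine = np.full((4, 4), ANTHROPIC)
        landscape = FineLandscape(fine, {}, block=2)
        cm = self._consensus(g, [0.9, 0.6, 0.4, 0.8])
        out = habitat_filter(cm, fine, landscape, 0.0)
        assert np.allclose(out.frequency, cm.frequency)

    def test_filtered_richness_never_exceeds_unfiltered(self, rng):
        from ensemblesdm.metrics import richness

        g = Grid(5, 5, cell_size=1.0)
        fine = rng.integers(0, 2, size=(15, 15))
        landscape = FineLandscape(fine, {}, block=3)
        maps = [self._consensus(g, rng.random(25)) for _ in range(8)]
        filt = [habitat_filter(m, fine, landscape, 0.5) for m in maps]
        assert (richness(filt) <= richness(maps)).all()

    def test_native_fraction_block_aggregation(self):
        g = Grid(1, 2, cell_size=1.0)
        fine = np.array([[0, 1, 1, 1], [0, 0, 1, 1]])
        landscape = FineLandscape(fine, {}, block=2)
        frac = native_fraction(fine, landscape, g)
        assert np.allclose(frac, [0.75, 0.0])
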