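import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensemblesdm.sdm import (
    METHODS,
    evaluate_at_threshold,
    fit_model,
    make_partitions,
    roc_threshold,
    tss,
)


def brute_force_best_tss(scores, labels):
    """Independent confusion-matrix oracle: enumerate every candidate
    threshold and tally TP/FP/TN/FN by explicit loops."""
    scores = list(map(float, scores))
    cands = sorted(set(scores)) + [max(scores) + 1.0]
    best = None
    for t in cands:
        tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= t)
        fn = sum(1 for s, y in zip(scores, labels) if y == 1 and s < t)
        tn = sum(1 for s, y in zip(scores, labels) if y == 0 and s < t)
        fp = sum(1 for s, y in zip(scores, labels) if y == 0 and s >= t)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        if best is None or sens + spec > best[0] + 1e-12:
            best = (sens + spec, t, sens, spec)
    return best


class TestPartitions:
    def test_40_40_split_gives_30_30_calibration(self):
        labels = np.array([1] * 40 + [0] * 40)
        ps = make_partitions(labels, k=10, calib_frac=0.75, seed=0)
        assert ps.k == 10 and len(ps.repeats) == 10
        for cal, val in ps.repeats:
            assert labels[cal].sum() == 30
            assert (labels[cal] == 0).sum() == 30
            assert len(val) == 20
            # disjoint union of all cells
            assert sorted(np.concatenate([cal, val])) == list(range(80))

    def test_prevalence_maintained_within_one_record(self):
        labels = np.array([1] * 13 + [0] * 87)
        ps = make_partitions(labels, k=10, seed=1)
        prev = labels.mean()
        for cal, _ in ps.repeats:
            n_cal = len(cal)
            expected = prev * n_cal
            assert abs(labels[cal].sum() - expected) <= 1

    def test_degenerate_fraction_rejected(self):
        labels = np.array([1] * 10 + [0] * 10)
        for frac in (0.0, 1.0, 1.2):
            with pytest.raises(ValueError):
                make_partitions(labels, calib_frac=frac)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="need >= 2"):
            make_partitions(np.array([1, 0, 0, 0]))

    def test_deterministic_under_seed(self):
        labels = np.array([1] * 20 + [0] * 30)
        a = make_partitions(labels, seed=5)
        b = make_partitions(labels, seed=5)
        for (c1, v1), (c2, v2) in zip(a.repeats, b.repeats):
            assert np.array_equal(c1, c2) and np.array_equal(v1, v2)


@pytest.fixture(scope="module")
def separable_toy():
    rng = np.random.default_rng(0)
    n = 60
    X = rng.normal(size=(n, 4))
    y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
    # widen the margin so every model family can separate it
    X[y == 1, 0] += 2.0
    X[y == 0, 0] -= 2.0
    return X, y


class TestFitModel:
    @pytest.mark.parametrize("method", METHODS)
    def test_separable_toy_reaches_perfect_tss(self, separable_toy, method):
        X, y = separable_toy
        model = fit_model(method, X, y, random_state=1)
        scores = model.predict(X)
        assert scores.min() >= 0 and scores.max() <= 1
        res = roc_threshold(scores, y)
        assert res.tss == pytest.approx(1.0)

    def test_unknown_method_rejected(self, separable_toy):
        X, y = separable_toy
        with pytest.raises(ValueError, match="GLM, GAM, MARS, RF, ANN, GBM"):
            fit_model("MAXENT", X, y)

    def test_single_class_rejected(self, separable_toy):
        X, _ = separable_toy
        with pytest.raises(ValueError, match="single class"):
            fit_model("GLM", X, np.ones(len(X), dtype=int))

    def test_exactly_six_method_tags(self):
        assert len(METHODS) == 6
        assert set(METHODS) == {"GLM", "GAM", "MARS", "RF", "ANN", "GBM"}


class TestRocThreshold:
    def test_perfectly_separated_scores(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        res = roc_threshold(scores, labels)
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.tss == 1.0
        assert res.threshold == pytest.approx(0.8)  # smallest qualifying

    def test_uninformative_constant_scores(self):
        res = roc_threshold(np.full(10, 0.5), np.array([1, 0] * 5))
        assert res.tss == pytest.approx(0.0)

    def test_recovers_constructed_threshold(self):
        rng = np.random.default_rng(3)
        scores = rng.random(200)
        scores[np.argmin(np.abs(scores - 0.5))] = 0.5  # ensure 0.5 is a value
        labels = (scores >= 0.5).astype(int)
        res = roc_threshold(scores, labels)
        assert res.threshold == pytest.approx(0.5)
        assert res.tss == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_threshold(np.array([0.1, 0.9]), np.array([1, 1]))

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(6, 40))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        scores = data.draw(
            st.lists(
                st.floats(0, 1, allow_nan=False, width=32), min_size=n, max_size=n
            )
        )
        res = roc_threshold(np.array(scores), np.array(labels))
        best_sum, t, sens, spec = brute_force_best_tss(scores, labels)
        assert res.sensitivity + res.specificity == pytest.approx(best_sum)
        assert res.threshold == pytest.approx(t)

    def test_permuted_labels_give_near_zero_mean_tss(self):
        rng = np.random.default_rng(8)
        scores = rng.random(60)
        labels = np.array([1] * 20 + [0] * 40)
        vals = []
        for _ in range(150):
            perm = rng.permutation(labels)
            res = roc_threshold(scores, perm)
            # evaluate on an independent permutation at the chosen threshold
            vals.append(evaluate_at_threshold(scores, rng.permutation(labels),
                                              res.threshold).tss)
        assert abs(np.mean(vals)) < 0.05


class TestTss:
    @pytest.mark.parametrize(
        "sens,spec,expected", [(1, 1, 1.0), (0.5, 0.5, 0.0), (0.8, 0.7, 0.5)]
    )
    def test_values(self, sens, spec, expected):
        assert tss(sens, spec) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tss(1.2, 0.5)
        with pytest.raises(ValueError):
            tss(0.5, -0.1)
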