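"""The greedy MKMD ranking and its weight schedule."""

import numpy as np
import pytest

from mkmdigwo import (Dataset, DistanceCache, ab_weights, make_dataset,
                      md1, minmax_normalize, mkmd_rank, mkmd_score,
                      SyntheticSpec, tau_abs)


class TestABWeights:
    @pytest.mark.parametrize("t,T,a,b", [
        (0, 100, 1.0, 0.0),
        (100, 100, 0.0, 1.0),
        (70, 100, 0.51, 0.49),
        (50, 100, 0.75, 0.25),
    ])
    def test_quadratic_schedule(self, t, T, a, b):
        w = ab_weights(t, T)
        assert w.a == pytest.approx(a)
        assert w.b == pytest.approx(b)
        assert w.a + w.b == pytest.approx(1.0)

    def test_crossover_at_70_of_100(self):
        # the last integer iteration at which relevance still outweighs distance
        last = max(t for t in range(101) if ab_weights(t, 100).a >= ab_weights(t, 100).b)
        assert last == 70

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ab_weights(101, 100)
        with pytest.raises(ValueError):
            ab_weights(0, 0)


@pytest.fixture()
def toy():
    # feature 0 = labels, feature 1 = near-copy, feature 2 independent
    rng = np.random.default_rng(2)
    y = np.array([0, 1] * 10)
    X = np.column_stack([
        y.astype(float),
        y + rng.normal(0, 0.05, 20),
        rng.normal(0, 1, 20),
        rng.normal(0, 1, 20),
        y + rng.normal(0, 0.4, 20),
        rng.normal(0, 1, 20),
    ])
    return Dataset(X, y, list("abcdef"))


class TestScore:
    def test_pure_relevance_when_b_zero(self, toy):
        w = ab_weights(0, 100)
        s = mkmd_score(2, [0, 1], w, toy)
        assert s == pytest.approx(tau_abs(toy.X[:, 2], toy.y))

    def test_pure_distance_when_a_zero(self, toy):
        w = ab_weights(100, 100)
        cache = DistanceCache(minmax_normalize(toy))
        s = mkmd_score(2, [0, 1], w, toy)
        assert s == pytest.approx(md1(2, [0, 1], cache)[0])

    def test_half_half_hand_computed(self, toy):
        w = ab_weights(50, 100)  # a = 0.75, b = 0.25
        cache = DistanceCache(minmax_normalize(toy))
        expected = 0.75 * tau_abs(toy.X[:, 3], toy.y) + 0.25 * md1(3, [0], cache)[0]
        assert mkmd_score(3, [0], w, toy) == pytest.approx(expected)

    def test_rejects_already_selected(self, toy):
        with pytest.raises(ValueError):
            mkmd_score(0, [0, 1], ab_weights(0, 100), toy)


class TestRank:
    def test_k1_reduces_to_max_kendall(self, toy):
        r = mkmd_rank(toy, ab_weights(30, 100), K=1)
        taus = [tau_abs(toy.X[:, j], toy.y) for j in range(toy.n_features)]
        assert r.order == [int(np.argmax(taus))]

    def test_b_zero_is_tau_descending(self, toy):
        r = mkmd_rank(toy, ab_weights(0, 100), K=toy.n_features)
        taus = np.array([tau_abs(toy.X[:, j], toy.y) for j in range(toy.n_features)])
        expected = sorted(range(toy.n_features), key=lambda j: (-taus[j], j))
        assert r.order == expected

    def test_matches_exhaustive_greedy(self, toy):
        w = ab_weights(50, 100)
        r = mkmd_rank(toy, w, K=4)
        # independent greedy recomputation
        taus = [tau_abs(toy.X[:, j], toy.y) for j in range(toy.n_features)]
        cache = DistanceCache(minmax_normalize(toy))
        order, remaining = [], list(range(toy.n_features))
        for _ in range(4):
            def score(j):
                if not order:
                    return w.a * taus[j]
                return w.a * taus[j] + w.b * md1(j, order, cache)[0]
            best = max(remaining, key=lambda j: (score(j), -j))
            order.append(best)
            remaining.remove(best)
        assert r.order == order

    def test_deterministic(self, toy):
        w = ab_weights(20, 100)
        assert mkmd_rank(toy, w, 5).order == mkmd_rank(toy, w, 5).order

    def test_no_duplicates_and_budget(self, toy):
        r = mkmd_rank(toy, ab_weights(80, 100), K=5)
        assert len(r.order) == len(set(r.order)) == 5

    def test_export_frame(self, toy, tmp_path):
        r = mkmd_rank(toy, ab_weights(10, 100), K=3)
        df = r.to_frame()
        assert list(df.columns) == ["rank", "feature_index", "feature_name",
                                    "score", "a", "b"]
        r.to_csv(tmp_path / "ranking.csv")
        assert (tmp_path / "ranking.csv").exists()

    def test_informative_dominate_top_ranks(self):
        """Pure-relevance ranking puts the 5 informative features in the
        top 10 of 50 in nearly every draw."""
        hits = 0
        for seed in range(20):
            data, truth = make_dataset(SyntheticSpec(
                n_informative=5, n_redundant=0, n_noise=45, seed=seed))
            r = mkmd_rank(data, ab_weights(0, 100), K=10)
            if set(truth.informative) <= set(r.order):
                hits += 1
        assert hits >= 18
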