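"""Maxent SDM: fitting, prediction, validation, importance, aggregation."""

import numpy as np
import pytest

from priormap.geodata import ContinuousLayer, Grid
from priormap.maxent import (
    FeatureExpansion,
    aggregate_richness,
    auc_rank,
    evaluate,
    fit_maxent,
    predict,
    variable_importance,
)


def linear_expansion(bg, names=None):
    names = names or [f"c{i}" for i in range(bg.shape[1])]
    return FeatureExpansion.from_background(names, bg, ("linear",))


def gibbs_presences(rng, bg, weights, n):
    """Sample presence rows from the Gibbs density over background rows."""
    eta = bg @ np.asarray(weights)
    p = np.exp(eta - eta.max())
    p /= p.sum()
    idx = rng.choice(len(bg), size=n, replace=True, p=p)
    return bg[idx]


class TestFit:
    def test_no_signal_strong_penalty_shrinks_all_weights_to_zero(self):
        rng = np.random.default_rng(0)
        bg = rng.standard_normal((2000, 3))
        pres = bg[rng.choice(2000, size=200, replace=False)]
        model = fit_maxent(pres, bg, linear_expansion(bg), rm=5.0)
        assert np.all(np.abs(model.weights) <= 1e-6)

    def test_recovers_single_covariate_weight(self):
        rng = np.random.default_rng(1)
        bg = rng.standard_normal((5000, 1))
        pres = gibbs_presences(rng, bg, [2.0], 500)
        model = fit_maxent(pres, bg, linear_expansion(bg), rm=1.1)
        assert model.weights[0] == pytest.approx(2.0, abs=0.3)

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(2)
        bg = rng.standard_normal((1000, 2))
        pres = gibbs_presences(rng, bg, [1.5, -1.0], 300)
        model = fit_maxent(pres, bg, linear_expansion(bg))
        trace = np.asarray(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_deterministic_given_data(self):
        rng = np.random.default_rng(3)
        bg = rng.standard_normal((800, 2))
        pres = gibbs_presences(rng, bg, [1.0, 0.5], 200)
        m1 = fit_maxent(pres, bg, linear_expansion(bg))
        m2 = fit_maxent(pres, bg, linear_expansion(bg))
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_too_few_presences_rejected(self):
        rng = np.random.default_rng(4)
        bg = rng.standard_normal((100, 2))
        with pytest.raises(ValueError):
            fit_maxent(bg[:3], bg, linear_expansion(bg))

    def test_increasing_rm_shrinks_weight_norm(self):
        rng = np.random.default_rng(5)
        bg = rng.standard_normal((2000, 3))
        pres = gibbs_presences(rng, bg, [2.0, 1.0, 0.0], 400)
        norms = []
        for rm in (0.5, 1.1, 2.0, 4.0, 8.0):
            m = fit_maxent(pres, bg, linear_expansion(bg), rm=rm)
            norms.append(np.abs(m.weights).sum())
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))


class TestPredict:
    def grid_layers(self, rng, n=3):
        grid = Grid(20, 20, 100.0, origin_y=2000.0)
        return [ContinuousLayer(grid, rng.standard_normal((20, 20))) for _ in range(n)]

    def test_all_zero_weights_give_constant_map(self):
        rng = np.random.default_rng(6)
        layers = self.grid_layers(rng)
        bg = np.column_stack([l.values.ravel() for l in layers])
        exp = linear_expansion(bg)
        model = fit_maxent(bg[:50], bg, exp, rm=50.0)  # shrinks to zero
        smap = predict(model, layers)
        assert np.allclose(smap.values, smap.values[0, 0])
        assert np.all((smap.values >= 0) & (smap.values <= 1))

    def test_output_monotone_in_linear_predictor(self):
        rng = np.random.default_rng(7)
        layers = self.grid_layers(rng)
        bg = np.column_stack([l.values.ravel() for l in layers])
        pres = gibbs_presences(rng, bg, [2.0, 0.0, 0.0], 200)
        model = fit_maxent(pres, bg, linear_expansion(bg))
        smap = predict(model, layers)
        eta = model.eta(bg).reshape(20, 20)
        order = np.argsort(eta.ravel())
        s = smap.values.ravel()[order]
        assert np.all(np.diff(s) >= -1e-12)

    def test_missing_covariate_errors(self):
        rng = np.random.default_rng(8)
        layers = self.grid_layers(rng)
        bg = np.column_stack([l.values.ravel() for l in layers])
        model = fit_maxent(bg[:50], bg, linear_expansion(bg), rm=50.0)
        with pytest.raises(ValueError):
            predict(model, layers[:2])

    def test_training_landscape_auc_high_under_strong_signal(self):
        rng = np.random.default_rng(9)
        grid = Grid(50, 50, 100.0, origin_y=5000.0)
        layers = [ContinuousLayer(grid, rng.standard_normal((50, 50)))]
        bg = np.column_stack([l.values.ravel() for l in layers])
        pres = gibbs_presences(rng, bg, [2.5], 500)
        model = fit_maxent(pres, bg, linear_expansion(bg))
        assert auc_rank(model.eta(pres), model.eta(bg)) >= 0.85


class TestAUC:
    def test_perfect_separation_gives_one(self):
        assert auc_rank([3, 4, 5], [0, 1, 2]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_rank([1.0, 1.0], [1.0, 1.0, 1.0]) == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_equals_pairwise_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 10, size=rng.integers(5, 100)).astype(float)
        neg = rng.integers(0, 10, size=rng.integers(5, 100)).astype(float)
        oracle = np.mean(
            [
                1.0 if p > n else (0.5 if p == n else 0.0)
                for p in pos
                for n in neg
            ]
        )
        assert auc_rank(pos, neg) == pytest.approx(oracle, abs=0)

    def test_agrees_with_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(11)
        pos = rng.normal(1, 1, 80)
        neg = rng.normal(0, 1, 120)
        y = np.r_[np.ones(80), np.zeros(120)]
        s = np.r_[pos, neg]
        assert auc_rank(pos, neg) == pytest.approx(
            sklearn_metrics.roc_auc_score(y, s), abs=1e-12
        )


class TestEvaluate:
    def test_replicate_split_validation_reports_aucs(self):
        rng = np.random.default_rng(12)
        bg = rng.standard_normal((3000, 2))
        pres = gibbs_presences(rng, bg, [2.0, 0.5], 200)
        rep = evaluate(pres, bg, linear_expansion(bg), replicates=4, seed=0)
        assert len(rep.train_auc) == 4 and len(rep.test_auc) == 4
        assert 0.7 <= rep.mean_test_auc <= 1.0

    def test_degenerate_split_rejected(self):
        rng = np.random.default_rng(13)
        bg = rng.standard_normal((100, 1))
        with pytest.raises(ValueError):
            evaluate(bg[:6], bg, linear_expansion(bg), split=0.99)


class TestVariableImportance:
    def test_signal_covariate_ranks_first_and_constant_is_zero(self):
        rng = np.random.default_rng(14)
        raw = np.column_stack(
            [
                rng.standard_normal(3000),  # signal
                rng.standard_normal(3000),  # noise
                np.full(3000, 2.5),         # constant
            ]
        )
        exp = FeatureExpansion.from_background(["sig", "noise", "const"], raw)
        eta = 2.0 * (raw[:, 0] - raw[:, 0].mean()) / raw[:, 0].std()
        p = np.exp(eta - eta.max())
        p /= p.sum()
        pres = raw[rng.choice(3000, size=400, replace=True, p=p)]
        model = fit_maxent(pres, raw, exp)
        rep = variable_importance(model, pres, raw, seed=0)
        pi = rep.permutation_importance
        assert max(pi, key=pi.get) == "sig"
        assert pi["const"] == 0.0
        assert sum(pi.values()) == pytest.approx(100.0, abs=0.1)
        assert sum(rep.percent_contribution.values()) == pytest.approx(100.0, abs=0.1)

    def test_jackknife_without_absent_for_single_covariate(self):
        rng = np.random.default_rng(15)
        bg = rng.standard_normal((1000, 1))
        pres = gibbs_presences(rng, bg, [1.5], 200)
        model = fit_maxent(pres, bg, linear_expansion(bg))
        rep = variable_importance(model, pres, bg, seed=0)
        assert rep.jackknife_without == {}
        assert rep.jackknife_only["c0"] > 0


class TestAggregateRichness:
    def grid(self):
        return Grid(3, 3, 100.0, origin_y=300.0)

    def test_single_map_equals_its_normalized_self(self):
        g = self.grid()
        vals = np.arange(9, dtype=float).reshape(3, 3)
        out = aggregate_richness([ContinuousLayer(g, vals)])
        np.testing.assert_allclose(out.values, vals / 8.0)

    def test_two_identical_maps_equal_either_normalized(self):
        g = self.grid()
        vals = np.arange(9, dtype=float).reshape(3, 3)
        maps = [ContinuousLayer(g, vals), ContinuousLayer(g, vals.copy())]
        np.testing.assert_allclose(aggregate_richness(maps).values, vals / 8.0)

    def test_disjoint_hotspots_peak_at_half(self):
        g = self.grid()
        a = np.zeros((3, 3)); a[0, 0] = 1.0
        b = np.zeros((3, 3)); b[2, 2] = 1.0
        out = aggregate_richness([ContinuousLayer(g, a), ContinuousLayer(g, b)])
        assert out.values[0, 0] == pytest.approx(0.5)
        assert out.values[2, 2] == pytest.approx(0.5)
        assert out.values[1, 1] == 0.0
        assert out.values.max() == pytest.approx(0.5)

    def test_constant_map_warns_and_zeroes(self):
        g = self.grid()
        with pytest.warns(UserWarning):
            out = aggregate_richness([ContinuousLayer(g, np.full((3, 3), 0.7))])
        assert (out.values == 0).all()
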