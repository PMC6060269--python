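"""Fold plans, cross-validated scoring, stacking, and the leakage audit."""

import numpy as np
import pytest

import spikebench as sb
from spikebench.crossval import LeakageError, StackedPredictions


class TestFoldPlans:
    def test_random_fold_sizes_balanced(self):
        folds = sb.make_folds(16, 8, "random", seed=0)
        sizes = [folds.test_indices(j).size for j in range(8)]
        assert sizes == [2] * 8
        folds = sb.make_folds(103, 8, "random", seed=0)
        sizes = [folds.test_indices(j).size for j in range(8)]
        assert max(sizes) - min(sizes) <= 1
        all_bins = np.sort(np.concatenate([folds.test_indices(j) for j in range(8)]))
        assert np.array_equal(all_bins, np.arange(103))

    def test_contiguous_folds_are_intervals(self):
        folds = sb.make_folds(100, 8, "contiguous", seed=0)
        for j in range(8):
            te = folds.test_indices(j)
            assert np.array_equal(te, np.arange(te.min(), te.max() + 1))

    def test_determinism(self):
        a = sb.make_folds(50, 5, "random", seed=3)
        b = sb.make_folds(50, 5, "random", seed=3)
        assert np.array_equal(a.assignment, b.assignment)

    def test_guard_margin_blocks_history_leakage(self):
        """No training row's causal history window may overlap test bins."""
        L = 50
        folds = sb.make_folds(2000, 8, "contiguous", seed=0, history_span_bins=L)
        for j in range(8):
            te = set(folds.test_indices(j).tolist())
            for r in folds.train_indices(j):
                window = set(range(r - L, r))
                assert not window & te

    def test_validation(self):
        with pytest.raises(ValueError):
            sb.make_folds(4, 8)
        with pytest.raises(ValueError):
            sb.make_folds(100, 1)
        with pytest.raises(ValueError):
            sb.make_folds(100, 8, mode="blocked")


class TestCrossValidatedScores:
    def test_null_adapter_scores_zero(self):
        rng = np.random.default_rng(0)
        n = 50_000
        y = rng.poisson(0.8, size=n)
        X = rng.normal(size=(n, 2))
        folds = sb.make_folds(n, 8, "random", seed=1)
        scores = sb.cross_validated_scores(X, y, sb.NullAdapter(), folds)
        assert len(scores) == 8
        assert abs(np.mean(scores)) < 0.01

    def test_oracle_self_consistency(self, cosine_sim, trig_design):
        """The oracle's CV score matches its score on an independent
        simulation of the same neuron, up to sampling error."""
        b0, m, tp = cosine_sim["b0"], cosine_sim["m"], cosine_sim["theta_pref"]

        def rate_fn(X):
            return np.exp(b0 + m * (np.cos(tp) * X[:, 0] + np.sin(tp) * X[:, 1]))

        X = trig_design.to_numpy()
        y = cosine_sim["y"]
        folds = sb.make_folds(y.size, 8, "random", seed=2)
        cv = np.mean(sb.cross_validated_scores(X, y, sb.OracleAdapter(rate_fn), folds))
        rng = np.random.default_rng(77)
        theta2 = rng.uniform(-np.pi, np.pi, y.size)
        lam2 = np.exp(b0 + m * np.cos(theta2 - tp))
        y2 = rng.poisson(lam2)
        independent = sb.pseudo_r2(y2, lam2, mu_null=float(y2.mean()))
        assert cv == pytest.approx(independent, abs=0.02)

    def test_oracle_score_stable_when_data_doubles(self, cosine_sim):
        b0, m, tp = cosine_sim["b0"], cosine_sim["m"], cosine_sim["theta_pref"]
        rng = np.random.default_rng(8)

        def simulate(n):
            theta = rng.uniform(-np.pi, np.pi, n)
            lam = np.exp(b0 + m * np.cos(theta - tp))
            return theta[:, None], rng.poisson(lam), lam

        def rate_fn_factory(thetas, lams):
            def rate_fn(X):
                return np.exp(b0 + m * np.cos(X[:, 0] - tp))
            return rate_fn

        for n in (8000,):
            X1, y1, lam1 = simulate(n)
            X2, y2, lam2 = simulate(2 * n)
            f1 = sb.make_folds(n, 8, "random", seed=0)
            f2 = sb.make_folds(2 * n, 8, "random", seed=0)
            s1 = np.mean(sb.cross_validated_scores(X1, y1, sb.OracleAdapter(rate_fn_factory(X1, lam1)), f1))
            s2 = np.mean(sb.cross_validated_scores(X2, y2, sb.OracleAdapter(rate_fn_factory(X2, lam2)), f2))
            assert s2 >= s1 - 0.01

    def test_scores_independent_of_neuron_order(self, m1_small):
        from spikebench.benchmark import build_features

        X = build_features(m1_small, "trig_direction")
        folds = sb.make_folds(m1_small.n_bins, 4, "random", seed=0)
        s_fwd = [
            sb.cross_validated_scores(X, m1_small.counts(i), sb.GLMAdapter(), folds)
            for i in range(m1_small.n_neurons)
        ]
        order = list(reversed(range(m1_small.n_neurons)))
        s_rev = [
            sb.cross_validated_scores(X, m1_small.counts(i), sb.GLMAdapter(), folds)
            for i in order
        ]
        for i, j in enumerate(order):
            assert np.allclose(s_fwd[j], s_rev[i])


class TestStackedEnsemble:
    def test_audit_clean_on_both_fold_modes(self):
        rng = np.random.default_rng(0)
        n = 800
        y = rng.poisson(0.5, size=n)
        X = rng.normal(size=(n, 2))
        first = {"null": sb.NullAdapter(), "noise": sb.NoiseAdapter(seed=1)}
        second = sb.BoostedTreesAdapter(n_trees=10, seed=0)
        for mode, span in (("random", 0), ("contiguous", 20)):
            folds = sb.make_folds(n, 4, mode, seed=0, history_span_bins=span)
            scores, stacked = sb.run_stacked_ensemble(
                X, y, first, second, folds, inner_k=3, seed=0
            )
            assert len(scores) == 4
            assert stacked.audit() == []

    def test_audit_detects_injected_leak(self):
        rng = np.random.default_rng(0)
        n = 400
        y = rng.poisson(0.5, size=n)
        X = rng.normal(size=(n, 2))
        folds = sb.make_folds(n, 4, "random", seed=0)
        first = {"null": sb.NullAdapter()}
        second = sb.BoostedTreesAdapter(n_trees=5, seed=0)
        _, stacked = sb.run_stacked_ensemble(X, y, first, second, folds, inner_k=2, seed=0)
        bad = dict(stacked.records[0])
        bad["train_bins"] = np.union1d(bad["train_bins"], bad["predicted_bins"][:2])
        stacked.records.append(bad)
        assert len(stacked.audit()) >= 1

    def test_single_oracle_first_stage_not_degraded(self, cosine_sim, trig_design):
        """Stacking on one model's predictions loses almost nothing."""
        b0, m, tp = cosine_sim["b0"], cosine_sim["m"], cosine_sim["theta_pref"]

        def rate_fn(X):
            return np.exp(b0 + m * (np.cos(tp) * X[:, 0] + np.sin(tp) * X[:, 1]))

        X, y = trig_design.to_numpy(), cosine_sim["y"]
        folds = sb.make_folds(y.size, 8, "random", seed=1)
        oracle = sb.OracleAdapter(rate_fn)
        base = np.mean(sb.cross_validated_scores(X, y, oracle, folds))
        scores, _ = sb.run_stacked_ensemble(
            X, y, {"oracle": oracle}, sb.BoostedTreesAdapter(n_trees=100, seed=0),
            folds, inner_k=5, seed=0,
        )
        assert np.mean(scores) >= base - 0.02

    def test_headline_ordering_on_misspecified_features(self):
        """ensemble >= boosted trees >= GLM on raw-direction input."""
        rng = np.random.default_rng(10)
        n = 4000
        glm_s, xgb_s, ens_s = [], [], []
        for neuron in range(4):
            theta = rng.uniform(-np.pi, np.pi, n)
            tp = rng.uniform(-np.pi, np.pi)
            lam = np.exp(np.log(0.5) + 1.2 * np.cos(theta - tp))
            y = rng.poisson(lam)
            X = theta[:, None]
            folds = sb.make_folds(n, 8, "random", seed=neuron)
            glm = sb.GLMAdapter(penalty=1e-4)
            xgb = sb.BoostedTreesAdapter(n_trees=100, seed=0)
            glm_s.append(np.mean(sb.cross_validated_scores(X, y, glm, folds)))
            xgb_s.append(np.mean(sb.cross_validated_scores(X, y, xgb, folds)))
            scores, _ = sb.run_stacked_ensemble(
                X, y, {"glm": glm, "xgboost": xgb},
                sb.BoostedTreesAdapter(n_trees=50, max_depth=2, seed=0),
                folds, inner_k=3, seed=0,
            )
            ens_s.append(np.mean(scores))
        assert np.mean(xgb_s) > np.mean(glm_s)
        assert np.mean(ens_s) >= np.mean(xgb_s) - 0.02

    def test_validation(self):
        folds = sb.make_folds(100, 4, "random", seed=0)
        with pytest.raises(ValueError):
            sb.run_stacked_ensemble(
                np.ones((100, 1)), np.ones(100), {}, sb.NullAdapter(), folds
            )
        with pytest.raises(ValueError):
            sb.run_stacked_ensemble(
                np.ones((100, 1)), np.ones(100), {"null": sb.NullAdapter()},
                sb.NullAdapter(), folds, inner_k=1,
            )

    def test_provenance_frame_schema(self):
        rng = np.random.default_rng(0)
        n = 200
        y = rng.poisson(0.5, size=n)
        X = rng.normal(size=(n, 1))
        folds = sb.make_folds(n, 2, "random", seed=0)
        _, stacked = sb.run_stacked_ensemble(
            X, y, {"null": sb.NullAdapter()}, sb.BoostedTreesAdapter(n_trees=5, seed=0),
            folds, inner_k=2, seed=0,
        )
        df = stacked.provenance_frame()
        assert set(df.columns) == {"outer_fold", "inner_fold", "stage", "model", "kind", "bin"}
        assert set(df["stage"]) == {"inner", "full", "second"}
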