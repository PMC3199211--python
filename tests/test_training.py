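"""Weight learning: likelihood, exact and SPA gradients, gradient ascent."""

import math

import numpy as np
import pytest

from dermcrf import (
    CrfFeatures,
    LabelField,
    WeightVector,
    build_grid,
    map_inference,
)
from dermcrf.training import (
    EDGE_WEIGHT_FLOOR,
    CrfInstance,
    TrainingConfig,
    exact_gradient,
    regularized_log_likelihood,
    spa_gradient,
    train_weights,
)
from tests.conftest import random_instance


def _single_pixel_instance(a=0.4, b=1.3, truth=0):
    g = build_grid(1, 1)
    feats = CrfFeatures((np.array([[a, b]]),), ())
    return CrfInstance(feats, LabelField(np.array([truth]), 1, 1), g)


def _fd_gradient(w, instances, sigma2, h=1e-5):
    grad = np.zeros_like(w.w)
    for i in range(w.w.size):
        for sign in (+1, -1):
            wp = w.w.copy()
            wp[i] += sign * h
            l = regularized_log_likelihood(
                WeightVector(wp, w.edge_indices), instances, sigma2, method="exact"
            )
            grad[i] += sign * l
    return grad / (2 * h)


class TestRegularizedLogLikelihood:
    def test_single_pixel_closed_form(self):
        inst = _single_pixel_instance(a=0.4, b=1.3, truth=0)
        w = WeightVector(np.array([2.0]), ())
        sigma2 = 5.0
        want = (
            -2.0 * 0.4
            - np.log(np.exp(-2.0 * 0.4) + np.exp(-2.0 * 1.3))
            - 2.0**2 / (2 * sigma2)
        )
        got = regularized_log_likelihood(w, [inst], sigma2)
        assert got == pytest.approx(want)

    def test_infinite_sigma2_drops_penalty(self, tiny_instances, w_standard):
        with_pen = regularized_log_likelihood(w_standard, tiny_instances, 2.0)
        without = regularized_log_likelihood(w_standard, tiny_instances, math.inf)
        pen = float(w_standard.w @ w_standard.w) / 4.0
        assert with_pen == pytest.approx(without - pen)

    def test_penalty_scales_quadratically(self, tiny_instances):
        sigma2 = 3.0
        c = 2.5
        w1 = WeightVector(np.array([1.0, 0.5]), (1,))
        wc = WeightVector(c * w1.w, (1,))
        l1 = regularized_log_likelihood(w1, tiny_instances, sigma2)
        l1_inf = regularized_log_likelihood(w1, tiny_instances, math.inf)
        lc = regularized_log_likelihood(wc, tiny_instances, sigma2)
        lc_inf = regularized_log_likelihood(wc, tiny_instances, math.inf)
        pen_diff = (l1_inf - l1) - (lc_inf - lc)
        want = (1 - c**2) * float(w1.w @ w1.w) / (2 * sigma2)
        assert pen_diff == pytest.approx(want)

    def test_nonpositive_sigma2_rejected(self, tiny_instances, w_standard):
        with pytest.raises(ValueError):
            regularized_log_likelihood(w_standard, tiny_instances, 0.0)


class TestExactGradient:
    def test_matches_central_finite_differences(self, tiny_instances, w_standard):
        for sigma2 in (2.0, math.inf):
            g = exact_gradient(w_standard, tiny_instances, sigma2)
            fd = _fd_gradient(w_standard, tiny_instances, sigma2)
            assert np.allclose(g, fd, rtol=1e-6, atol=1e-8)

    def test_regularization_shifts_stationary_point(self):
        inst = _single_pixel_instance()
        w = WeightVector(np.array([1.5]), ())
        g_unreg = exact_gradient(w, [inst], math.inf)
        g_reg = exact_gradient(w, [inst], 2.0)
        assert g_reg[0] == pytest.approx(g_unreg[0] - 1.5 / 2.0)

    def test_zero_weights_give_uniform_expectation(self, rng):
        """At w = 0 the model is uniform: expectation = mean feature total."""
        from dermcrf.crf import enumerate_labelings, feature_totals

        inst = random_instance(rng, 2, 2)
        w = WeightVector(np.array([0.0, 0.0]), (1,))
        g = exact_gradient(w, [inst], math.inf)
        totals = np.mean(
            [
                feature_totals(LabelField(y, 2, 2), inst.feats, inst.graph)
                for y in enumerate_labelings(4, 2)
            ],
            axis=0,
        )
        truth_tot = feature_totals(inst.truth, inst.feats, inst.graph)
        assert np.allclose(g, totals - truth_tot)

    def test_refuses_large_instances(self, rng, w_standard):
        inst = random_instance(rng, 5, 5)
        with pytest.raises(ValueError, match="tiny"):
            exact_gradient(w_standard, [inst], 2.0)


class TestSpaGradient:
    def test_truth_at_map_gives_pure_shrinkage(self, rng, w_standard):
        inst = random_instance(rng, 3, 3)
        y_star = map_inference(inst.feats, w_standard, inst.graph)
        inst = CrfInstance(inst.feats, y_star, inst.graph)
        g = spa_gradient(w_standard, [inst], 4.0)
        assert np.allclose(g, -w_standard.w / 4.0)

    def test_zero_gradient_at_convergence(self, rng, w_standard):
        inst = random_instance(rng, 3, 3)
        y_star = map_inference(inst.feats, w_standard, inst.graph)
        inst = CrfInstance(inst.feats, y_star, inst.graph)
        g = spa_gradient(w_standard, [inst], math.inf)
        assert np.allclose(g, 0.0)

    def test_agrees_with_exact_when_peaked(self, rng):
        """When one labeling carries > 0.999 mass, SPA is within 1% of exact."""
        from dermcrf.crf import _all_energies

        w = WeightVector(np.array([1.0, 0.5]), (1,))
        insts = []
        while len(insts) < 5:
            cand = random_instance(rng, 2, 3, node_scale=30.0, edge_scale=30.0)
            _, E = _all_energies(cand.feats, w, cand.graph)
            p = np.exp(-(E - E.min()))
            if p.max() / p.sum() > 0.999:
                insts.append(cand)
        ge = exact_gradient(w, insts, math.inf)
        gs = spa_gradient(w, insts, math.inf)
        assert np.linalg.norm(gs - ge) <= 0.01 * np.linalg.norm(ge)

    def test_low_temperature_limit(self, rng):
        """SPA error vanishes as all potentials are scaled up (no near-ties)."""
        from dermcrf.crf import _all_energies

        w = WeightVector(np.array([1.0, 0.5]), (1,))
        base = []
        while len(base) < 3:
            cand = random_instance(rng, 2, 3)
            _, E = _all_energies(cand.feats, w, cand.graph)
            gap = np.diff(np.sort(E)[:2])[0]
            if gap > 0.1:  # exclude near-degenerate optima
                base.append(cand)
        errs = []
        for scale in (1.0, 10.0, 100.0):
            insts = [
                CrfInstance(
                    CrfFeatures(
                        (scale * i.feats.node_features[0],),
                        (scale * i.feats.edge_features[0],),
                    ),
                    i.truth,
                    i.graph,
                )
                for i in base
            ]
            ge = exact_gradient(w, insts, math.inf)
            gs = spa_gradient(w, insts, math.inf)
            errs.append(np.linalg.norm(gs - ge) / max(np.linalg.norm(ge), 1e-12))
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 0.01 * errs[0]


class TestTrainWeights:
    def test_zero_gradient_start_does_not_move(self, rng):
        w0 = WeightVector(np.array([1.0, 0.5]), (1,))
        inst = random_instance(rng, 3, 3)
        y_star = map_inference(inst.feats, w0, inst.graph)
        inst = CrfInstance(inst.feats, y_star, inst.graph)
        cfg = TrainingConfig(w0=w0, sigma2=math.inf, n_itr=10, gradient="spa")
        trace = train_weights([inst], cfg)
        assert trace.converged
        assert trace.n_iterations == 1
        assert np.allclose(trace.best_w.w, w0.w)

    def test_edge_weight_clipped_to_floor(self, rng):
        """A step that would push the edge weight negative is projected."""
        g = build_grid(2, 2)
        # ground truth with many label changes but huge edge costs:
        # the gradient on the edge weight is strongly negative
        feats = CrfFeatures((np.zeros((4, 2)),), (np.full(4, 50.0),))
        truth = LabelField(np.array([0, 1, 1, 0]), 2, 2)
        inst = CrfInstance(feats, truth, g)
        cfg = TrainingConfig(
            w0=WeightVector(np.array([1.0, 0.05]), (1,)),
            sigma2=math.inf,
            gamma=1.0,
            n_itr=5,
            gradient="exact",
        )
        trace = train_weights([inst], cfg)
        for wv in trace.weights:
            assert wv.w[1] >= EDGE_WEIGHT_FLOOR

    def test_best_iterate_scores_maximum(self, tiny_instances):
        cfg = TrainingConfig(
            w0=WeightVector(np.array([0.5, 0.5]), (1,)),
            sigma2=5.0,
            gamma=0.3,
            n_itr=30,
            gradient="spa",
        )
        trace = train_weights(tiny_instances, cfg)
        assert trace.scores[trace.best_index] == max(trace.scores)
        re_scored = regularized_log_likelihood(
            trace.best_w, tiny_instances, 5.0, method="exact"
        )
        assert re_scored == pytest.approx(max(trace.scores))

    def test_exact_ascent_is_monotone(self, tiny_instances):
        cfg = TrainingConfig(
            w0=WeightVector(np.array([0.2, 0.2]), (1,)),
            sigma2=5.0,
            gamma=0.05,
            epsilon=1e-6,
            n_itr=200,
            gradient="exact",
        )
        trace = train_weights(tiny_instances, cfg)
        diffs = np.diff(trace.scores)
        assert np.all(diffs > -1e-10)

    def test_trace_respects_iteration_cap(self, tiny_instances):
        cfg = TrainingConfig(
            w0=WeightVector(np.array([0.5, 0.5]), (1,)),
            gamma=0.5,
            n_itr=7,
            gradient="spa",
        )
        trace = train_weights(tiny_instances, cfg)
        assert trace.n_iterations <= 7
        df = trace.to_dataframe()
        assert len(df) == trace.n_iterations
        assert set(df.columns) == {"w0", "w1", "grad0", "grad1", "score"}

    def test_parameter_recovery_from_known_weights(self, rng):
        """MLE on data sampled from a known CRF recovers the weight direction."""
        from dermcrf.crf import _all_energies

        w_true = np.array([1.0, 2.0])
        instances = []
        for _ in range(50):
            g = build_grid(3, 3)
            feats = CrfFeatures((rng.random((9, 2)),), (rng.random(g.n_edges),))
            Y, E = _all_energies(feats, WeightVector(w_true, (1,)), g)
            p = np.exp(-(E - E.min()))
            p /= p.sum()
            y = Y[rng.choice(len(Y), p=p)]
            instances.append(CrfInstance(feats, LabelField(y, 3, 3), g))
        cfg = TrainingConfig(
            w0=WeightVector(np.array([0.5, 0.5]), (1,)),
            sigma2=math.inf,
            gamma=0.05,
            epsilon=1e-5,
            n_itr=2000,
            gradient="exact",
        )
        trace = train_weights(instances, cfg)
        w_hat = trace.best_w.w
        d = w_hat / np.linalg.norm(w_hat) - w_true / np.linalg.norm(w_true)
        assert np.linalg.norm(d) <= 0.1
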