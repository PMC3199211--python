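"""Per-pixel model: LDA, class-conditionals, prior, MAP and thresholds."""

import warnings

import numpy as np
import pytest

from dermcrf import (
    FeatureStack,
    LabelField,
    LabelSet,
    LikelihoodMap,
    PriorDistribution,
    fit_class_conditionals,
    fit_lda,
    fit_prior,
    likelihood_map,
    map_label,
    threshold_labeling,
)
from dermcrf.pp import LdaProjection, ClassConditionalSet


def _stack(values, h, w):
    return FeatureStack(np.asarray(values, dtype=float), h, w)


def _field(labels, h, w):
    return LabelField(np.asarray(labels), h, w)


def _two_class_2d(rng, n=400, sep=5.0):
    """Two Gaussian classes separated along feature axis 1 only."""
    x0 = rng.normal([0.0, 0.0], 1.0, (n, 2))
    x1 = rng.normal([0.0, sep], 1.0, (n, 2))
    X = np.vstack([x0, x1])
    y = np.repeat([0, 1], n)
    return X, y


class TestFitLda:
    def test_separation_axis_recovered(self, rng):
        X, y = _two_class_2d(rng)
        stack = _stack(X, X.shape[0], 1)
        truth = _field(y, X.shape[0], 1)
        proj = fit_lda([stack], [truth], LabelSet((0, 1)))
        q = proj.Q[:, 0] / np.linalg.norm(proj.Q[:, 0])
        assert abs(q[1]) > 0.99  # parallel to axis 1 up to sign

    def test_projection_shape_30_to_1(self, rng):
        n = 40
        X = rng.normal(0, 1, (2 * n, 30))
        X[n:, 0] += 4.0
        y = np.repeat([0, 1], n)
        proj = fit_lda(
            [_stack(X, 2 * n, 1)], [_field(y, 2 * n, 1)], LabelSet((0, 1))
        )
        assert proj.Q.shape == (30, 1)

    def test_fisher_criterion_beats_random_directions(self, rng):
        """Brute-force oracle: the LDA direction maximizes the scatter ratio."""
        n = 300
        X = rng.normal(0, 1, (3 * n, 5))
        X[n : 2 * n, 1] += 3.0
        X[2 * n :, 3] -= 2.5
        y = np.repeat([0, 1, 2], n)
        labels = LabelSet((0, 1, 2))
        proj = fit_lda([_stack(X, 3 * n, 1)], [_field(y, 3 * n, 1)], labels)

        def fisher(direction):
            mu = X.mean(axis=0)
            sw = sb = 0.0
            for l in (0, 1, 2):
                Xl = X[y == l] @ direction
                sw += Xl.var()
                sb += (Xl.mean() - mu @ direction) ** 2
            return sb / sw

        best_lda = fisher(proj.Q[:, 0] / np.linalg.norm(proj.Q[:, 0]))
        dirs = rng.normal(0, 1, (200, 5))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        assert best_lda >= max(fisher(d) for d in dirs) - 1e-12

    def test_absent_label_errors(self, rng):
        X = rng.normal(0, 1, (50, 2))
        y = np.zeros(50, dtype=int)
        with pytest.raises(ValueError, match="absent|samples"):
            fit_lda([_stack(X, 50, 1)], [_field(y, 50, 1)], LabelSet((0, 1)))

    def test_channel_permutation_equivariance(self, rng):
        X, y = _two_class_2d(rng)
        X = np.hstack([X, rng.normal(0, 1, (X.shape[0], 2))])
        labels = LabelSet((0, 1))
        perm = np.array([2, 0, 3, 1])
        p1 = fit_lda([_stack(X, X.shape[0], 1)], [_field(y, X.shape[0], 1)], labels)
        p2 = fit_lda(
            [_stack(X[:, perm], X.shape[0], 1)], [_field(y, X.shape[0], 1)], labels
        )
        q1, q2 = p1.Q[:, 0], p2.Q[:, 0]
        if np.sign(q1[perm][np.argmax(np.abs(q2))]) != np.sign(q2[np.argmax(np.abs(q2))]):
            q2 = -q2
        assert np.allclose(q1[perm], q2, atol=1e-8)


class TestFitClassConditionals:
    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(7)
        n = 10**5
        mu_true = {0: -1.0, 1: 2.0}
        sd_true = {0: 0.5, 1: 1.5}
        X = np.concatenate(
            [rng.normal(mu_true[l], sd_true[l], n) for l in (0, 1)]
        )[:, None]
        y = np.repeat([0, 1], n)
        cc = fit_class_conditionals(
            [X], [_field(y, 2 * n, 1)], LabelSet((0, 1))
        )
        for j in (0, 1):
            se_mean = sd_true[j] / np.sqrt(n)
            assert abs(cc.means[j, 0] - mu_true[j]) < 3 * se_mean
            se_var = sd_true[j] ** 2 * np.sqrt(2.0 / n)
            assert abs(cc.covariances[j, 0, 0] - sd_true[j] ** 2) < 3 * se_var

    def test_degenerate_single_value(self):
        X = np.full((10, 1), 3.0)
        y = np.array([0] * 5 + [1] * 5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cc = fit_class_conditionals([X], [_field(y, 10, 1)], LabelSet((0, 1)))
        assert cc.means[0, 0] == pytest.approx(3.0)
        assert cc.covariances[0, 0, 0] > 0  # regularization floor applied

    def test_duplication_invariance(self, rng):
        X = rng.normal(0, 1, (60, 1))
        y = rng.integers(0, 2, 60)
        one = fit_class_conditionals([X], [_field(y, 60, 1)], LabelSet((0, 1)))
        two = fit_class_conditionals(
            [X, X], [_field(y, 60, 1), _field(y, 60, 1)], LabelSet((0, 1))
        )
        assert np.allclose(one.means, two.means)
        assert np.allclose(one.covariances, two.covariances)

    def test_too_few_samples_errors(self):
        X = np.array([[1.0], [2.0]])
        y = np.array([0, 1])
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_class_conditionals([X], [_field(y, 2, 1)], LabelSet((0, 1)))


class TestFitPrior:
    def test_direct_ratio(self):
        y = np.array([0] * 40 + [1] * 60)
        prior = fit_prior([_field(y, 100, 1)], LabelSet((0, 1)))
        assert np.allclose(prior.p, [0.4, 0.6])

    def test_pooling_across_image_sizes(self, rng):
        fields = [
            _field(rng.integers(0, 2, n), n, 1) for n in (13, 29, 58)
        ]
        prior = fit_prior(fields, LabelSet((0, 1)))
        manual = np.concatenate([f.labels for f in fields])
        assert prior.p[1] == pytest.approx((manual == 1).mean())

    def test_uniform_truth_gives_uniform_prior(self):
        y = np.tile([0, 1], 50)
        prior = fit_prior([_field(y, 100, 1)], LabelSet((0, 1)))
        assert np.allclose(prior.p, 0.5)


def _toy_model(mu0=-2.0, mu1=2.0, var=1.0):
    proj = LdaProjection(Q=np.eye(1), mu_global=np.zeros(1))
    cc = ClassConditionalSet(
        means=np.array([[mu0], [mu1]]),
        covariances=np.array([[[var]], [[var]]]),
    )
    return proj, cc


class TestLikelihoodAndMap:
    def test_rows_sum_to_one(self, rng):
        proj, cc = _toy_model()
        stack = _stack(rng.normal(0, 3, (50, 1)), 50, 1)
        lmap = likelihood_map(stack, proj, cc)
        assert np.allclose(lmap.L_mat.sum(axis=1), 1.0, atol=1e-9)

    def test_equidistant_pixel_is_half_half(self):
        proj, cc = _toy_model()
        lmap = likelihood_map(_stack([[0.0]], 1, 1), proj, cc)
        assert np.allclose(lmap.L_mat[0], [0.5, 0.5])

    def test_pixel_at_class_mean_prefers_that_class(self):
        proj, cc = _toy_model()
        lmap = likelihood_map(_stack([[-2.0]], 1, 1), proj, cc)
        assert lmap.L_mat[0, 0] > 0.5

    def test_underflow_is_handled_in_log_space(self):
        proj, cc = _toy_model(var=1e-4)
        lmap = likelihood_map(_stack([[1000.0]], 1, 1), proj, cc)
        assert np.all(np.isfinite(lmap.L_mat))
        assert np.allclose(lmap.L_mat.sum(axis=1), 1.0)

    def test_uniform_prior_map_equals_likelihood_argmax(self, rng):
        proj, cc = _toy_model()
        stack = _stack(rng.normal(0, 3, (40, 1)), 40, 1)
        lmap = likelihood_map(stack, proj, cc)
        y_map = map_label(stack, proj, cc, PriorDistribution.uniform(2))
        assert np.array_equal(y_map.labels, np.argmax(lmap.L_mat, axis=1))

    def test_degenerate_prior_forces_label(self, rng):
        proj, cc = _toy_model()
        stack = _stack(rng.normal(0, 3, (40, 1)), 40, 1)
        y = map_label(stack, proj, cc, PriorDistribution(np.array([1.0, 0.0])))
        assert np.all(y.labels == 0)

    def test_map_matches_direct_evaluation(self):
        """Four pixels scored by hand against density x prior."""
        from scipy.stats import norm

        proj, cc = _toy_model(mu0=-1.0, mu1=3.0, var=2.0)
        prior = PriorDistribution(np.array([0.7, 0.3]))
        xs = np.array([[-3.0], [0.5], [1.2], [4.0]])
        stack = _stack(xs, 2, 2)
        got = map_label(stack, proj, cc, prior)
        sd = np.sqrt(2.0)
        want = [
            int(
                norm.pdf(x, 3.0, sd) * 0.3 > norm.pdf(x, -1.0, sd) * 0.7
            )
            for x in xs[:, 0]
        ]
        assert np.array_equal(got.labels, want)


class TestThresholdLabeling:
    def _lmap(self, rng, n=30):
        p = rng.random(n)
        return LikelihoodMap(np.column_stack([1 - p, p]), n, 1)

    def test_zero_threshold_labels_everything(self, rng):
        lmap = self._lmap(rng)
        y = threshold_labeling(lmap, 1, 0.0)
        assert np.all(y.labels == 1)

    def test_boundary_threshold_one(self):
        lmap = LikelihoodMap(np.array([[0.0, 1.0], [0.5, 0.5]]), 2, 1)
        y = threshold_labeling(lmap, 1, 1.0)
        assert np.array_equal(y.labels, [1, 0])
        with pytest.raises(ValueError):
            threshold_labeling(lmap, 1, 1.0 + 1e-9)

    def test_half_threshold_equals_uniform_prior_map(self, rng):
        proj, cc = _toy_model()
        stack = _stack(rng.normal(0, 3, (40, 1)), 40, 1)
        lmap = likelihood_map(stack, proj, cc)
        th = threshold_labeling(lmap, 1, 0.5)
        mp = map_label(stack, proj, cc, PriorDistribution.uniform(2))
        assert np.array_equal(th.labels, mp.labels)

    def test_sweep_is_monotone(self, rng):
        lmap = self._lmap(rng, 100)
        counts = [
            int((threshold_labeling(lmap, 1, t).labels == 1).sum())
            for t in np.linspace(0, 1, 21)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
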