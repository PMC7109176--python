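"""EM mixture fitting, k-means++ seeding, class assignment and the
unknown/tumor intersection threshold."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from petgmm.segmentation import (
    DegenerateFitError,
    MixtureFit,
    class_assign,
    fit_gmm,
    kmeanspp_init,
    tumor_threshold,
)


def _sample_mixture(rng, n, weights, means, sds):
    comps = rng.choice(len(weights), size=n, p=weights)
    return rng.normal(np.asarray(means)[comps], np.asarray(sds)[comps])


def _make_fit(weights, means, variances):
    w = np.asarray(weights, float)
    return MixtureFit(
        weights=w / w.sum(),
        means=np.asarray(means, float),
        variances=np.asarray(variances, float),
        log_likelihood=0.0,
        n_iter=1,
        converged=True,
    )


class TestKmeansppInit:
    def test_three_plateaus_always_yield_one_center_each(self):
        values = np.array([0, 0, 0, 10, 10, 10, 20, 20, 20], dtype=float)
        for seed in range(200):
            centers = kmeanspp_init(values, k=3, seed=seed)
            assert sorted(centers) == [0.0, 10.0, 20.0]

    def test_k1_returns_a_data_value(self, rng):
        values = rng.normal(size=50)
        c = kmeanspp_init(values, k=1, seed=3)
        assert c[0] in values

    def test_too_few_distinct_values_raise(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeanspp_init(np.array([1.0, 1.0, 2.0, 3.0, 3.0]), k=4, seed=0)

    def test_deterministic_given_seed(self, rng):
        values = rng.normal(size=200)
        a = kmeanspp_init(values, 3, seed=11)
        b = kmeanspp_init(values, 3, seed=11)
        np.testing.assert_array_equal(a, b)


class TestFitGmm:
    def test_parameter_recovery_on_reference_mixture(self, rng):
        x = _sample_mixture(rng, 3000, [0.5, 0.3, 0.2], [1, 3, 8], [0.3, 0.5, 1.0])
        fit = fit_gmm(x, seed=1)
        assert np.max(np.abs(fit.means - [1, 3, 8])) < 0.1
        assert np.max(np.abs(fit.weights - [0.5, 0.3, 0.2])) < 0.05
        assert fit.converged

    def test_log_likelihood_monotone_every_iteration(self, rng):
        x = _sample_mixture(rng, 2000, [0.5, 0.3, 0.2], [1, 3, 8], [0.3, 0.5, 1.0])
        fit = fit_gmm(x, seed=2)
        hist = np.array(fit.log_likelihood_history)
        assert np.all(np.diff(hist) >= -1e-9 * np.abs(hist[:-1]))

    def test_tight_separated_clusters(self, rng):
        x = np.concatenate(
            [rng.normal(m, 0.01, 100) for m in (0.0, 5.0, 10.0)]
        )
        fit = fit_gmm(x, seed=3)
        np.testing.assert_allclose(fit.means, [0, 5, 10], atol=0.01)
        np.testing.assert_allclose(fit.weights, [1 / 3] * 3, atol=0.01)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_gmm(np.full(100, 3.7))

    def test_components_ordered_by_ascending_mean(self, rng):
        x = _sample_mixture(rng, 1500, [0.2, 0.5, 0.3], [8, 1, 3], [1.0, 0.3, 0.5])
        fit = fit_gmm(x, seed=4)
        assert np.all(np.diff(fit.means) >= 0)

    def test_agrees_with_sklearn_reference(self, rng):
        """Independent EM implementation recovers the same solution."""
        sklearn = pytest.importorskip("sklearn.mixture")
        x = _sample_mixture(rng, 3000, [0.5, 0.3, 0.2], [1, 3, 8], [0.3, 0.5, 1.0])
        ours = fit_gmm(x, seed=5)
        ref = sklearn.GaussianMixture(
            n_components=3, n_init=5, random_state=0, tol=1e-6, max_iter=500
        ).fit(x[:, None])
        order = np.argsort(ref.means_.ravel())
        np.testing.assert_allclose(ours.means, ref.means_.ravel()[order], atol=0.05)
        np.testing.assert_allclose(ours.weights, ref.weights_[order], atol=0.02)

    def test_recovery_over_many_seeds(self):
        """Well-separated mixtures are recovered across 20 replicate draws."""
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = _sample_mixture(rng, 2500, [0.4, 0.35, 0.25], [0, 4, 9], [0.5, 0.6, 0.9])
            fit = fit_gmm(x, seed=seed)
            assert np.max(np.abs(fit.means - [0, 4, 9])) < 0.15


class TestClassAssign:
    def test_component_means_map_to_their_class(self):
        fit = _make_fit([1, 1, 1], [1.0, 4.0, 8.0], [0.1, 0.1, 0.1])
        assert list(class_assign(fit, [1.0, 4.0, 8.0])) == [0, 1, 2]

    def test_midpoint_tie_goes_to_lower_class(self):
        fit = _make_fit([1, 1, 1], [0.0, 4.0, 8.0], [0.25, 1.0, 1.0])
        # unknown/tumor symmetric about 6: tie resolves to unknown (index 1)
        assert class_assign(fit, [6.0])[0] == 1

    def test_matches_direct_density_argmax(self, rng):
        for _ in range(50):
            means = np.sort(rng.uniform(0, 10, 3))
            fit = _make_fit(rng.uniform(0.1, 1, 3), means, rng.uniform(0.05, 2, 3))
            x = rng.uniform(-2, 12, 20)
            expected = np.argmax(
                fit.weights * norm.pdf(x[:, None], fit.means, np.sqrt(fit.variances)),
                axis=1,
            )
            np.testing.assert_array_equal(class_assign(fit, x), expected)


def _grid_crossing(fit, step=1e-5):
    """Oracle: dense scan for the first weighted-density crossing between means."""
    w_u, w_t = fit.weights[1], fit.weights[2]
    mu_u, mu_t = fit.means[1], fit.means[2]
    s_u, s_t = np.sqrt(fit.variances[1]), np.sqrt(fit.variances[2])
    x = np.arange(mu_u, mu_t, step)
    diff = w_u * norm.pdf(x, mu_u, s_u) - w_t * norm.pdf(x, mu_t, s_t)
    sign = np.sign(diff)
    idx = np.where(sign[:-1] != sign[1:])[0]
    if len(idx) == 0:
        return None
    return 0.5 * (x[idx[0]] + x[idx[0] + 1])


class TestTumorThreshold:
    def test_symmetric_components_cross_at_midpoint(self):
        fit = _make_fit([1, 1, 1], [0.0, 3.0, 8.0], [1.0, 0.5**2, 0.5**2])
        thr, flags = tumor_threshold(fit)
        assert thr == pytest.approx(5.5, abs=1e-12)
        assert flags == ()

    def test_matches_grid_scan_oracle(self):
        fit = _make_fit(
            [0.5, 0.3, 0.2], [0.0, 3.0, 8.0], [1.0, 0.5**2, 1.0**2]
        )
        thr, _ = tumor_threshold(fit)
        assert thr == pytest.approx(_grid_crossing(fit), abs=1e-4)

    def test_threshold_monotone_in_tumor_log_weight(self):
        prev = None
        for w_t in (0.3, 0.1, 0.03, 0.01):
            fit = _make_fit([1 - 0.3 - w_t, 0.3, w_t], [0, 3, 8], [1, 0.8, 0.8])
            thr, _ = tumor_threshold(fit)
            if prev is not None:
                assert thr > prev  # vanishing tumor weight pushes toward mu_t
            prev = thr

    def test_between_means_or_midpoint(self, rng):
        for _ in range(100):
            means = np.sort(rng.uniform(0, 10, 3))
            if means[2] - means[1] < 1e-3:
                continue
            fit = _make_fit(
                rng.dirichlet([1, 1, 1]), means, rng.uniform(0.05, 2.0, 3) ** 2
            )
            thr, flags = tumor_threshold(fit)
            if "midpoint_fallback" in flags:
                assert thr == pytest.approx(0.5 * (means[1] + means[2]))
            else:
                assert means[1] < thr < means[2]

    def test_degenerate_equal_means_raise(self):
        fit = _make_fit([1, 1, 1], [1.0, 5.0, 5.0], [0.5, 0.5, 0.5])
        with pytest.raises(DegenerateFitError):
            tumor_threshold(fit)
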