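"""Quasi-Monte Carlo sampling, Sobol total-effect indices, CDF area metric
and density summaries against analytic oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.stats import qmc

from aortauq import (
    area_metric,
    association_signs,
    density_mode,
    prob_leq,
    sobol_sample,
    total_effect_indices,
)
from aortauq.doe import INPUT_NAMES

UNIT = (np.zeros(3), np.ones(3))

#: closed-form Sobol total-effect indices of the Ishigami function
#: (a=7, b=0.1) on [-pi, pi]^3.
ISHIGAMI_ST = np.array([0.5576, 0.4424, 0.2437])


def ishigami(X, a=7.0, b=0.1):
    return np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2 + b * X[:, 2] ** 4 * np.sin(X[:, 0])


class TestSobolSample:
    def test_row_count_and_bounds(self, bounds):
        X = sobol_sample(bounds, 10_000, seed=0)
        assert X.shape == (10_000, 9)
        assert list(X.columns) == list(INPUT_NAMES)
        assert np.all(X.to_numpy() >= bounds.lb) and np.all(X.to_numpy() <= bounds.ub)

    def test_deterministic_under_seed(self, bounds):
        a = sobol_sample(bounds, 256, seed=7)
        b = sobol_sample(bounds, 256, seed=7)
        assert a.equals(b)

    def test_lower_discrepancy_than_pseudorandom(self):
        lo, hi = np.zeros(5), np.ones(5)
        sob, rnd = [], []
        for seed in range(10):
            s = sobol_sample((lo, hi), 1024, seed=seed).to_numpy()
            r = np.random.default_rng(seed).uniform(size=(1024, 5))
            sob.append(qmc.discrepancy(s))
            rnd.append(qmc.discrepancy(r))
        assert np.median(sob) < np.median(rnd)


class TestTotalEffectIndices:
    def test_single_active_input(self):
        res = total_effect_indices(lambda X: X[:, 0], (np.zeros(4), np.ones(4)),
                                   base_n=1024, seed=0)
        assert res.tei[0] == pytest.approx(1.0, abs=0.02)
        assert np.all(np.abs(res.tei[1:]) < 0.02)
        assert res.ranking[0] == "x1"

    def test_additive_two_input_oracle(self):
        # Y = X1 + 2*X2 on the unit square: ST = (0.2, 0.8)
        res = total_effect_indices(lambda X: X[:, 0] + 2 * X[:, 1],
                                   (np.zeros(2), np.ones(2)), base_n=1024, seed=0)
        assert res.tei[0] == pytest.approx(0.2, abs=0.02)
        assert res.tei[1] == pytest.approx(0.8, abs=0.02)

    def test_ishigami_oracle(self):
        res = total_effect_indices(ishigami, (-np.pi * np.ones(3), np.pi * np.ones(3)),
                                   base_n=1024, seed=0)
        assert np.allclose(res.tei, ISHIGAMI_ST, atol=0.03)

    def test_estimator_converges_with_base_n(self):
        truth = np.array([0.2, 0.8])
        f = lambda X: X[:, 0] + 2 * X[:, 1]
        err_small, err_big = [], []
        for seed in range(10):
            small = total_effect_indices(f, (np.zeros(2), np.ones(2)), 256, seed=seed)
            big = total_effect_indices(f, (np.zeros(2), np.ones(2)), 4096, seed=seed)
            err_small.append(np.abs(small.tei - truth).max())
            err_big.append(np.abs(big.tei - truth).max())
        assert np.median(err_big) < np.median(err_small)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            total_effect_indices(lambda X: np.ones(len(X)), UNIT, base_n=64)

    def test_ranks_are_permutation(self):
        res = total_effect_indices(ishigami, (-np.pi * np.ones(3), np.pi * np.ones(3)),
                                   base_n=256, seed=1)
        assert sorted(res.ranking) == ["x1", "x2", "x3"]
        assert sorted(res.as_frame()["rank"]) == [1, 2, 3]


class TestAssociationSigns:
    def test_trivial_directions(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(500, 3))
        signs = association_signs(X, X[:, 0], names=["s", "HR", "V"])
        assert signs["s"] == "+"
        signs = association_signs(X, -X[:, 0], names=["s", "HR", "V"])
        assert signs["s"] == "-"
        # output independent of the third input
        assert association_signs(X, X[:, 0], names=["s", "HR", "V"])["V"] == "indeterminate"


class TestAreaMetric:
    def test_pure_location_shift(self):
        # model Normal(mu + delta, sigma) vs comparator Normal(mu, sigma):
        # the area metric is exactly |delta| for location families
        rng = np.random.default_rng(0)
        delta, sigma = 2.0, 0.625
        sample = rng.normal(46.0 + delta, sigma, size=10_000)
        res = area_metric(sample, 46.0, sigma)
        assert res.area_mm == pytest.approx(delta, rel=0.01)

    def test_point_mass_vs_normal(self):
        # degenerate model at the comparator mean: d = sigma*sqrt(2/pi)
        sigma = 0.625
        res = area_metric(np.full(5000, 46.0), 46.0, sigma)
        assert res.area_mm == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.01)

    def test_matching_distributions_vanish(self):
        # ideal (quantile) sample from the comparator itself
        n = 20_000
        q = stats.norm.ppf((np.arange(n) + 0.5) / n, loc=46.0, scale=0.625)
        res = area_metric(q, 46.0, 0.625)
        assert res.area_mm < 5e-4

    def test_percentage_and_pass_flag(self):
        rng = np.random.default_rng(1)
        sample = rng.normal(47.0, 0.6, size=2000)
        res = area_metric(sample, 46.0, 0.625, threshold=5.0)
        assert res.area_percent == pytest.approx(100 * res.area_mm / 46.0, rel=1e-12)
        assert res.passed == (res.area_percent <= 5.0)

    def test_custom_normalization(self):
        sample = np.full(200, 50.0)
        res = area_metric(sample, 50.0, 1.0, normalization=10.0)
        assert res.area_percent == pytest.approx(100 * res.area_mm / 10.0, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            area_metric([], 46.0, 0.625)
        with pytest.raises(ValueError):
            area_metric([46.0], 46.0, -1.0)


class TestProbLeq:
    def test_examples(self):
        sample = [50.0, 54.0, 56.0]
        assert prob_leq(sample, 54.6) == pytest.approx(2 / 3)
        assert prob_leq(sample, 100.0) == 1.0
        assert prob_leq(sample, 10.0) == 0.0


class TestDensityMode:
    def test_normal_mode(self):
        rng = np.random.default_rng(0)
        res = density_mode(rng.normal(0.2, 0.05, size=10_000))
        assert res.mode == pytest.approx(0.2, abs=0.01)
        assert res.interval95[0] < 0.2 < res.interval95[1]
        assert res.sample.min() <= res.mode <= res.sample.max()

    def test_constant_sample(self):
        res = density_mode(np.full(200, 0.3))
        assert res.mode == 0.3
        assert res.interval95 == (0.3, 0.3)

    def test_bimodal_mixture_prefers_taller_component(self):
        rng = np.random.default_rng(2)
        tall = rng.normal(0.3, 0.02, size=7000)
        short = rng.normal(0.1, 0.02, size=3000)
        res = density_mode(np.concatenate([tall, short]))
        assert res.mode == pytest.approx(0.3, abs=0.02)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            density_mode(np.ones(50))
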