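"""Likelihood machinery versus independent oracles.

The enumeration oracle and the complete-data kernel are checked against
term-by-term recomputation with scipy's distributions, forward Monte-Carlo
simulation, closed-form special cases, and an exhaustive normalization sum.
"""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import mastmix as mm
from mastmix.likelihood import ModelData, binom_logpmf, poisson_logpmf


def _random_instance(rng, n_sessions=3, max_nights=3):
    """A small random model instance with coherent shapes."""
    nights = rng.integers(1, max_nights + 1, n_sessions)
    night_session = np.repeat(np.arange(n_sessions), nights)
    p_a, p_d = 2, 2
    X = np.column_stack([np.ones(n_sessions), rng.normal(0, 1, n_sessions)])
    Z = np.column_stack([np.ones(len(night_session)), rng.normal(0, 1, len(night_session))])
    offset = np.log(rng.uniform(0.3, 1.2, n_sessions))
    beta = rng.normal(0, 0.5, p_a)
    alpha = rng.normal(0, 0.5, p_d)
    eps = rng.normal(0, 0.4, n_sessions)
    tau = rng.uniform(0.5, 4.0)
    mu = np.exp(offset + X @ beta + eps)
    N = rng.poisson(mu)
    p = expit(Z @ alpha)
    counts = rng.binomial(N[night_session], p)
    data = ModelData(counts=counts, X=X, offset_log_area=offset, Z=Z,
                     night_session=night_session)
    abund = mm.AbundanceParams(beta=beta, eps=eps, tau=tau)
    det = mm.DetectionParams(alpha=alpha)
    return data, abund, det, N


class TestExpectedAbundance:
    def test_all_zero_coefficients(self):
        params = mm.AbundanceParams(beta=[0.0], eps=[0.0], tau=1.0)
        lam, mu = mm.expected_abundance(np.array([1.0]), 0.0, params, eps=0.0)
        assert (lam, mu) == (1.0, 1.0)

    def test_intercept_only_density(self):
        # a typical vole abundance intercept on a 0.5625 ha grid
        params = mm.AbundanceParams(beta=[3.73], eps=[0.0], tau=1.0)
        lam, mu = mm.expected_abundance(
            np.array([1.0]), np.log(0.5625), params, eps=0.0
        )
        assert lam == pytest.approx(np.exp(3.73))
        assert lam == pytest.approx(41.7, abs=0.05)
        assert mu == pytest.approx(0.5625 * np.exp(3.73))

    def test_offset_linearity(self):
        params = mm.AbundanceParams(beta=[1.2, -0.3], eps=[0.0], tau=1.0)
        x = np.array([1.0, 0.7])
        lam1, mu1 = mm.expected_abundance(x, np.log(0.5), params, eps=0.0)
        lam2, mu2 = mm.expected_abundance(x, np.log(1.0), params, eps=0.0)
        assert lam1 == pytest.approx(lam2)
        assert mu2 == pytest.approx(2 * mu1)

    def test_dimension_mismatch(self):
        params = mm.AbundanceParams(beta=[1.0, 2.0], eps=[0.0], tau=1.0)
        with pytest.raises(ValueError):
            mm.expected_abundance(np.array([1.0]), 0.0, params, eps=0.0)


class TestDetectionProb:
    def test_zero_coefficients_give_half(self):
        assert mm.detection_prob(np.zeros(3), mm.DetectionParams(np.zeros(3))) == 0.5

    def test_intercept_value(self):
        # a typical nightly capture probability around 0.25
        p = mm.detection_prob(np.array([1.0, 0, 0]),
                              mm.DetectionParams([-1.08, 0.3, 0.1]))
        assert p == pytest.approx(expit(-1.08))
        assert p == pytest.approx(0.2536, abs=2e-4)

    def test_negative_quadratic_dominates(self):
        params = mm.DetectionParams([0.0, 1.0, -0.5])  # intercept, t, t^2
        grid = np.linspace(3, 8, 10)
        rows = np.column_stack([np.ones(10), grid, grid**2])
        p = mm.detection_prob(rows, params)
        assert (np.diff(p) < 0).all()


class TestCompleteDataLogpost:
    def test_closed_form_binomial_factor(self):
        """1 session, N=2, p=0.5 both nights, C=(1,2): the binomial part is
        C(2,1)(.5)^2 * C(2,2)(.5)^2 = 0.5 * 0.25."""
        data = ModelData(
            counts=[1, 2], X=[[1.0]], offset_log_area=[0.0], Z=[[0.0], [0.0]],
            night_session=[0, 0],
        )
        abund = mm.AbundanceParams(beta=[0.5], eps=[0.0], tau=1.0)
        det = mm.DetectionParams(alpha=[1.0])  # z=0 -> p=0.5
        lp = mm.complete_data_logpost(data, np.array([2]), abund, det)
        binom_part = np.log(0.5) + np.log(0.25)
        pois_part = stats.poisson.logpmf(2, np.exp(0.5))
        # remainder: eps and coefficient priors, tau prior
        assert np.isfinite(lp)
        resid = lp - binom_part - pois_part
        lp_shift = mm.complete_data_logpost(
            ModelData(counts=[0, 0], X=[[1.0]], offset_log_area=[0.0],
                      Z=[[0.0], [0.0]], night_session=[0, 0]),
            np.array([2]), abund, det,
        )
        # same parameters: prior terms cancel in the difference
        assert lp - lp_shift == pytest.approx(
            binom_part - (np.log(0.25) + np.log(0.25))
        )
        assert resid == pytest.approx(lp_shift - pois_part - 2 * np.log(0.25))

    def test_support_violation_is_minus_inf(self):
        data = ModelData(counts=[3], X=[[1.0]], offset_log_area=[0.0],
                         Z=[[0.0]], night_session=[0])
        abund = mm.AbundanceParams(beta=[0.0], eps=[0.0], tau=1.0)
        det = mm.DetectionParams(alpha=[0.0])
        assert mm.complete_data_logpost(data, np.array([2]), abund, det) == -np.inf

    def test_term_by_term_oracle(self, rng):
        """Random tiny instances versus independent scipy summation."""
        priors = mm.Priors()
        for _ in range(30):
            data, abund, det, N = _random_instance(rng)
            N = np.maximum(N, data.max_counts())
            got = mm.complete_data_logpost(data, N, abund, det, priors)
            # independent recomputation, term by term
            mu = np.exp(data.offset_log_area + data.X @ abund.beta + abund.eps)
            p = expit(data.Z @ det.alpha)
            want = stats.poisson.logpmf(N, mu).sum()
            want += stats.binom.logpmf(
                data.counts, N[data.night_session], p
            ).sum()
            want += stats.norm.logpdf(abund.eps, 0, abund.sigma_eps).sum()
            coef = np.concatenate([abund.beta, det.alpha])
            want += stats.norm.logpdf(coef, 0, priors.coef_sd).sum()
            want += stats.gamma.logpdf(
                abund.tau, priors.tau_shape, scale=1 / priors.tau_rate
            )
            assert got == pytest.approx(want, rel=1e-10)

    def test_session_order_invariance(self, rng):
        data, abund, det, N = _random_instance(rng, n_sessions=4)
        N = np.maximum(N, data.max_counts())
        perm = rng.permutation(4)
        # permute sessions consistently
        order = np.argsort(np.argsort(perm))
        remap = {old: new for new, old in enumerate(perm)}
        ns_new = np.array([remap[s] for s in data.night_session])
        sort_idx = np.argsort(ns_new, kind="stable")
        data2 = ModelData(
            counts=data.counts[sort_idx],
            X=data.X[perm],
            offset_log_area=data.offset_log_area[perm],
            Z=data.Z[sort_idx],
            night_session=ns_new[sort_idx],
        )
        abund2 = mm.AbundanceParams(beta=abund.beta, eps=abund.eps[perm],
                                    tau=abund.tau)
        a = mm.complete_data_logpost(data, N, abund, det)
        b = mm.complete_data_logpost(data2, N[perm], abund2, det)
        assert a == pytest.approx(b, rel=1e-12)


class TestMarginalLoglikEnum:
    def test_certain_detection_collapses_to_poisson(self):
        """p=1 forces N=C, so the marginal is the Poisson pmf at the count."""
        ll = mm.marginal_loglik_enum(np.array([2]), 1.0, np.array([1.0]), N_max=60)
        assert ll == pytest.approx(stats.poisson.logpmf(2, 1.0))
        assert ll == pytest.approx(np.log(np.exp(-1) / 2))

    def test_zero_detection_with_positive_count(self):
        ll = mm.marginal_loglik_enum(np.array([1]), 2.0, np.array([0.0]), N_max=50)
        assert ll == -np.inf

    def test_nmax_below_count_rejected(self):
        with pytest.raises(ValueError):
            mm.marginal_loglik_enum(np.array([5]), 1.0, np.array([0.5]), N_max=3)

    def test_forward_simulation_oracle(self, rng):
        """Enumeration matches Monte-Carlo forward simulation within 3 MCSE."""
        mu, p = 4.0, np.array([0.6, 0.3])
        n_mc = 10**6
        N = rng.poisson(mu, n_mc)
        c1 = rng.binomial(N, p[0])
        c2 = rng.binomial(N, p[1])
        target = (2, 1)
        hits = (c1 == target[0]) & (c2 == target[1])
        phat = hits.mean()
        mcse = np.sqrt(phat * (1 - phat) / n_mc)
        ll = mm.marginal_loglik_enum(np.array(target), mu, p, N_max=80)
        assert abs(np.exp(ll) - phat) < 3 * mcse

    def test_normalization_sums_to_one(self):
        """Summing the marginal over every possible count vector is 1."""
        mu, p = 2.5, np.array([0.4, 0.7])
        n_cap = 15  # Poisson(>15 | 2.5) < 1e-9: truncation negligible
        total = 0.0
        for c1, c2 in itertools.product(range(n_cap + 1), repeat=2):
            ll = mm.marginal_loglik_enum(np.array([c1, c2]), mu, p, N_max=60)
            total += np.exp(ll)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_p_near_one_limit(self):
        """As p -> 1 on all nights the marginal tends to Poisson at max count."""
        C = np.array([3, 3])
        for p in (0.999, 0.99999):
            ll = mm.marginal_loglik_enum(C, 3.0, np.array([p, p]), N_max=80)
            want = stats.poisson.logpmf(3, 3.0)
            assert ll == pytest.approx(want, abs=3 * (1 - p) * 10)


class TestPmfHelpers:
    def test_binom_logpmf_against_scipy(self, rng):
        n = rng.integers(0, 20, 50)
        c = rng.integers(0, 21, 50)
        p = rng.uniform(0, 1, 50)
        got = binom_logpmf(c, n, p)
        want = stats.binom.logpmf(c, n, p)
        np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-10)

    def test_poisson_logpmf_against_scipy(self, rng):
        n = rng.integers(0, 30, 50)
        mu = rng.uniform(0.01, 20, 50)
        np.testing.assert_allclose(
            poisson_logpmf(n, mu), stats.poisson.logpmf(n, mu), rtol=1e-10
        )

    def test_edge_cases(self):
        assert binom_logpmf(0, 0, 0.3) == pytest.approx(0.0)
        assert binom_logpmf(1, 0, 0.3) == -np.inf
        assert binom_logpmf(2, 5, 0.0) == -np.inf
        assert binom_logpmf(5, 5, 1.0) == pytest.approx(0.0)
        assert poisson_logpmf(0, 0.0) == pytest.approx(0.0)
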