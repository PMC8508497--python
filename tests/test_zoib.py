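import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from deazoib import (
    HierarchicalDesign,
    PriorConfig,
    ResponseVector,
    ZOIBParams,
    beta_shapes,
    inv_logit,
    log_prior,
    loglik,
    logit,
    mei,
    mu_linpred,
    omega_linpred,
    ratio_from_coefficient,
    zoib_logpdf,
)


def make_params(J=2, l1=0, l2=0, **kw):
    defaults = dict(
        beta0=0.0, beta1=np.zeros(l1), beta2=np.zeros(l2), u=np.zeros(J),
        sigma_u0=1.0, gamma0=0.0, gamma1=np.zeros(l1), gamma2=np.zeros(l2),
        theta=0.5, precision=2.0,
    )
    defaults.update(kw)
    return ZOIBParams(**defaults)


def make_design(group_of, X1=None, X2=None, J=None):
    n = len(group_of)
    J = J if J is not None else max(group_of) + 1
    return HierarchicalDesign(
        group_of=np.asarray(group_of),
        X1=np.zeros((n, 0)) if X1 is None else np.asarray(X1, float),
        X2=np.zeros((J, 0)) if X2 is None else np.asarray(X2, float),
        n_groups=J,
    )


class TestLinkFunctions:
    def test_logit_examples(self):
        assert logit(0.5) == pytest.approx(0.0, abs=1e-12)
        assert inv_logit(0.0) == pytest.approx(0.5, abs=1e-12)
        assert logit(0.78) == pytest.approx(np.log(0.78 / 0.22), abs=1e-12)

    def test_logit_domain_error(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                logit(bad)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=1e-9, max_value=1 - 1e-9))
    def test_round_trip(self, p):
        assert inv_logit(logit(p)) == pytest.approx(p, abs=1e-12)

    def test_monotone(self):
        x = np.linspace(-8, 8, 100)
        assert np.all(np.diff(inv_logit(x)) > 0)


class TestLinearPredictors:
    def test_null_model_gives_half(self):
        d = make_design([0, 0, 1, 1])
        p = make_params(J=2)
        assert mu_linpred(p, d) == pytest.approx([0.5] * 4)
        assert omega_linpred(p, d) == pytest.approx([0.5] * 4)

    def test_intercept_only(self):
        d = make_design([0, 1])
        p = make_params(J=2, beta0=1.0)
        assert mu_linpred(p, d) == pytest.approx([inv_logit(1.0)] * 2)

    def test_group_random_intercepts(self):
        d = make_design([0, 0, 1, 1])
        p = make_params(J=2, u=np.array([1.0, -1.0]))
        mu = mu_linpred(p, d)
        assert mu[:2] == pytest.approx([inv_logit(1.0)] * 2)
        assert mu[2:] == pytest.approx([inv_logit(-1.0)] * 2)
        # the omega01 submodel carries no random effect
        assert omega_linpred(p, d) == pytest.approx([0.5] * 4)

    def test_omega_intercept_matches_logistic(self):
        d = make_design([0])
        p = make_params(J=1, gamma0=-3.0)
        assert omega_linpred(p, d)[0] == pytest.approx(inv_logit(-3.0), abs=1e-12)
        # adding c to gamma0 multiplies the endpoint odds by exp(c)
        p2 = make_params(J=1, gamma0=-3.0 + 0.7)
        om, om2 = omega_linpred(p, d)[0], omega_linpred(p2, d)[0]
        assert om2 / (1 - om2) == pytest.approx(np.exp(0.7) * om / (1 - om), rel=1e-10)

    def test_level2_broadcasting(self):
        d = make_design([0, 0, 1], X2=[[1.0], [-2.0]])
        p = make_params(J=2, l2=1, beta2=np.array([0.5]))
        assert mu_linpred(p, d) == pytest.approx(
            [inv_logit(0.5), inv_logit(0.5), inv_logit(-1.0)]
        )

    def test_dimension_mismatch(self):
        d = make_design([0], X1=[[1.0, 2.0]])
        with pytest.raises(ValueError):
            mu_linpred(make_params(J=1, l1=1), d)


class TestBetaShapes:
    def test_uniform_case(self):
        assert beta_shapes(0.5, 2.0) == pytest.approx((1.0, 1.0))

    def test_regime_values(self):
        a1, a2 = beta_shapes(0.78, 14.27)
        assert (a1, a2) == pytest.approx((11.1306, 3.1394), abs=1e-10)

    @settings(max_examples=30, derandomize=True)
    @given(
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.1, max_value=100.0),
    )
    def test_mean_and_concentration_recovered(self, mu, prec):
        a1, a2 = beta_shapes(mu, prec)
        assert a1 + a2 == pytest.approx(prec, rel=1e-12)
        assert a1 / (a1 + a2) == pytest.approx(mu, rel=1e-9)


class TestDensity:
    def test_point_masses(self):
        assert zoib_logpdf(1.0, 0.2, 1.0, 0.5, 2.0) == pytest.approx(np.log(0.2))
        assert zoib_logpdf(0.0, 0.2, 1.0, 0.5, 2.0) == -np.inf
        # Beta(1,1) density is 1, so the interior term is log(1 - omega01)
        assert zoib_logpdf(0.5, 0.2, 1.0, 0.5, 2.0) == pytest.approx(np.log(0.8))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            zoib_logpdf(1.5, 0.2, 0.5, 0.5, 2.0)

    def test_total_mass_is_one(self, rng):
        """Two point masses plus the quadrature of the continuous part."""
        for _ in range(20):
            om = rng.uniform(0.05, 0.6)
            th = rng.uniform(0.1, 0.95)
            mu = rng.uniform(0.2, 0.8)
            prec = rng.uniform(4.0, 40.0)
            cont, _ = integrate.quad(
                lambda t: np.exp(zoib_logpdf(t, om, th, mu, prec)), 0.0, 1.0
            )
            total = om * (1 - th) + om * th + cont
            assert total == pytest.approx(1.0, abs=1e-6)


class TestLogLikelihood:
    def test_empty_dataset(self):
        d = make_design([], J=1)
        y = ResponseVector(y=np.array([]))
        assert loglik(make_params(J=1), d, y) == 0.0

    def test_single_frontier_unit(self):
        d = make_design([0])
        y = ResponseVector(y=np.array([1.0]))
        # all-zero coefficients: omega01 = 0.5; theta = 0.5
        assert loglik(make_params(J=1), d, y) == pytest.approx(np.log(0.25))

    def test_matches_per_unit_hand_sum(self):
        d = make_design([0, 0, 1], X1=[[1.0], [0.0], [-1.0]])
        p = make_params(
            J=2, l1=1, beta0=0.5, beta1=np.array([0.3]), u=np.array([0.2, -0.2]),
            gamma0=-2.0, gamma1=np.array([1.0]), theta=0.9, precision=8.0,
        )
        y = ResponseVector(y=np.array([0.7, 1.0, 0.4]))
        terms = []
        for i, (x, g) in enumerate(zip([1.0, 0.0, -1.0], [0, 0, 1])):
            mu_i = inv_logit(0.5 + p.u[g] + 0.3 * x)
            om_i = inv_logit(-2.0 + 1.0 * x)
            if y.y[i] == 1.0:
                terms.append(np.log(om_i * 0.9))
            else:
                terms.append(
                    np.log(1 - om_i) + stats.beta.logpdf(y.y[i], mu_i * 8.0, (1 - mu_i) * 8.0)
                )
        assert loglik(p, d, y) == pytest.approx(sum(terms), abs=1e-10)

    def test_permutation_invariance(self, rng):
        n = 12
        X1 = rng.standard_normal((n, 1))
        g = rng.integers(0, 2, n)
        yv = np.concatenate([rng.uniform(0.1, 0.9, n - 2), [1.0, 1.0]])
        p = make_params(J=2, l1=1, beta1=np.array([0.4]), theta=0.8)
        perm = rng.permutation(n)
        ll1 = loglik(p, make_design(g, X1=X1), ResponseVector(y=yv))
        ll2 = loglik(p, make_design(g[perm], X1=X1[perm]), ResponseVector(y=yv[perm]))
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_degenerates_to_beta_regression(self, rng):
        """theta -> 1 and omega01 -> 0 leave the plain beta likelihood."""
        n = 20
        yv = rng.uniform(0.05, 0.95, n)
        d = make_design(np.zeros(n, dtype=int))
        p = make_params(J=1, beta0=0.9, theta=1.0, gamma0=-40.0, precision=6.0)
        mu = inv_logit(0.9)
        expected = stats.beta.logpdf(yv, mu * 6.0, (1 - mu) * 6.0).sum()
        assert loglik(p, d, ResponseVector(y=yv)) == pytest.approx(expected, abs=1e-9)

    def test_endpoint_tolerance_snaps_lp_noise(self):
        d = make_design([0, 0])
        y = ResponseVector(y=np.array([1.0 - 1e-9, 0.5]))
        assert y.is_one.tolist() == [True, False]


class TestPriors:
    def test_flat_on_fixed_effects(self):
        a = make_params(beta0=0.0)
        b = make_params(beta0=123.4)
        assert log_prior(a) == pytest.approx(log_prior(b), abs=1e-12)

    def test_halfnormal_difference_on_sigma(self):
        scale = PriorConfig().sigma_u0_scale
        a = make_params(sigma_u0=0.5)
        b = make_params(sigma_u0=1.0)
        # closed form: half-normal log-density difference on sigma plus the
        # J = 2 random-intercept increments N(0, sigma^2) evaluated at u = 0
        halfnorm_diff = -(0.5**2 - 1.0**2) / (2 * scale**2)
        u_increment_diff = -2 * (np.log(0.5) - np.log(1.0))
        assert log_prior(a) - log_prior(b) == pytest.approx(
            halfnorm_diff + u_increment_diff, abs=1e-10
        )

    def test_zero_random_intercepts_maximise_increment(self, rng):
        base = make_params(u=np.zeros(2))
        for _ in range(5):
            other = make_params(u=rng.standard_normal(2))
            assert log_prior(base) >= log_prior(other)

    def test_unknown_config_rejected(self):
        with pytest.raises(ValueError, match="unknown prior"):
            PriorConfig(name="banana")

    def test_sensitivity_configs_are_proper(self):
        p = make_params()
        for name in ("gamma_sensitivity", "normal_sensitivity"):
            assert np.isfinite(log_prior(p, name))
            assert log_prior(p, name) != log_prior(p, "default")


class TestEffectMeasures:
    def test_mei_examples(self):
        assert mei(0.5) == pytest.approx(1.0)
        assert ratio_from_coefficient(0.0) == pytest.approx(1.0)
        # a 1.45 coefficient corresponds to a 4.26-fold mean efficiency index
        assert ratio_from_coefficient(1.45) == pytest.approx(4.2631, abs=1e-4)

    def test_mei_strictly_increasing_and_reciprocal(self):
        mus = np.linspace(0.01, 0.99, 50)
        vals = mei(mus)
        assert np.all(np.diff(vals) > 0)
        assert mei(mus) * mei(1 - mus) == pytest.approx(np.ones(50), rel=1e-10)

    def test_mei_domain(self):
        with pytest.raises(ValueError):
            mei(1.0)
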