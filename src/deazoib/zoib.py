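"""Multilevel zero-one inflated beta (ZOIB) model for efficiency scores.

Pure technical efficiency lives on (0, 1] with a point mass at 1 (frontier
units), so it is modelled as a three-part mixture: with probability
``omega01`` the response is an endpoint (1 with conditional probability
``theta``, else 0), otherwise it follows a Beta distribution parameterised
by its mean ``mu`` and precision ``alpha1 + alpha2``:

    f(y) = omega01 * (1 - theta)          if y = 0
           omega01 * theta                if y = 1
           (1 - omega01) * Beta(y; a1,a2) if 0 < y < 1,

with a1 = mu * precision, a2 = (1 - mu) * precision.

Units (hospitals, level 1) are nested in groups (regions, level 2).  The
beta mean carries a group random intercept on the logit scale,

    logit(mu_ij) = beta0 + u_0j + X1 beta1 + X2 beta2,   u_0j ~ N(0, sigma_u0^2)

while the endpoint probability is modelled with fixed effects only,

    logit(omega01_ij) = gamma0 + X1 gamma1 + X2 gamma2.

``theta`` and the precision are constant across units.  exp(beta) is a
ratio of mean efficiency indices (RMEI, with MEI = mu/(1-mu)); exp(gamma)
is an odds ratio for frontier membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "HierarchicalDesign",
    "ResponseVector",
    "ZOIBParams",
    "PriorConfig",
    "logit",
    "inv_logit",
    "mu_linpred",
    "omega_linpred",
    "beta_shapes",
    "zoib_logpdf",
    "loglik",
    "log_prior",
    "mei",
    "ratio_from_coefficient",
]

#: observed responses within this distance of 0 or 1 are treated as exact
#: endpoints — the discrete mass lives on the endpoints and LP rounding
#: noise from the DEA stage must not leak into the continuous component.
ENDPOINT_TOL = 1e-6


def logit(p):
    """log(p / (1-p)); domain error on the endpoints."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("logit requires p strictly inside (0, 1)")
    out = special.logit(p)
    return float(out) if out.ndim == 0 else out


def inv_logit(x):
    """Logistic function 1 / (1 + exp(-x)), the inverse of :func:`logit`."""
    out = special.expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class HierarchicalDesign:
    """Two-level covariate design: units (level 1) nested in groups (level 2).

    Parameters
    ----------
    group_of
        Integer array of length ``n_units`` mapping each unit to a group
        index in ``[0, n_groups)``.
    X1
        (n_units, l1) matrix of unit-level covariates (standardized
        quantitative columns and 0/1 factor dummies).
    X2
        (n_groups, l2) matrix of group-level covariates; each group's row
        is broadcast to all of its units.
    """

    group_of: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    x1_names: tuple = ()
    x2_names: tuple = ()
    n_groups: int | None = None

    def __post_init__(self):
        g = np.asarray(self.group_of, dtype=int)
        X1 = np.asarray(self.X1, dtype=float)
        if X1.ndim != 2:
            X1 = X1.reshape(len(g), -1) if X1.size else np.zeros((len(g), 0))
        J = self.n_groups if self.n_groups is not None else (int(g.max()) + 1 if len(g) else 0)
        X2 = np.asarray(self.X2, dtype=float)
        if X2.ndim != 2:
            X2 = X2.reshape(J, -1) if X2.size else np.zeros((J, 0))
        object.__setattr__(self, "group_of", g)
        object.__setattr__(self, "X1", X1)
        object.__setattr__(self, "X2", X2)
        object.__setattr__(self, "n_groups", J)
        if len(g) and (g.min() < 0 or g.max() >= J):
            raise ValueError("every unit must map to a group in [0, n_groups)")
        if not self.x1_names:
            object.__setattr__(self, "x1_names", tuple(f"x1_{i}" for i in range(X1.shape[1])))
        if not self.x2_names:
            object.__setattr__(self, "x2_names", tuple(f"x2_{i}" for i in range(X2.shape[1])))
        if len(self.x1_names) != X1.shape[1] or len(self.x2_names) != X2.shape[1]:
            raise ValueError("covariate names do not match matrix dimensions")

    @property
    def n_units(self) -> int:
        return len(self.group_of)

    @property
    def l1(self) -> int:
        return self.X1.shape[1]

    @property
    def l2(self) -> int:
        return self.X2.shape[1]

    def x2_broadcast(self) -> np.ndarray:
        """Group-level covariates expanded to one row per unit."""
        return self.X2[self.group_of]

    def fixed_effects_matrix(self) -> np.ndarray:
        """[1 | X1 | broadcast X2], the design of either submodel's fixed part."""
        return np.column_stack([np.ones(self.n_units), self.X1, self.x2_broadcast()])


@dataclass(frozen=True)
class ResponseVector:
    """Responses in [0, 1] with endpoint classification.

    Values within ``endpoint_tol`` of an endpoint are snapped to it; the
    remainder must be strictly interior.
    """

    y: np.ndarray
    endpoint_tol: float = ENDPOINT_TOL

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        if np.any(y < 0) or np.any(y > 1) or not np.all(np.isfinite(y)):
            raise ValueError("responses must lie in [0, 1]")
        y = y.copy()
        y[y >= 1.0 - self.endpoint_tol] = 1.0
        y[y <= self.endpoint_tol] = 0.0
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def is_zero(self) -> np.ndarray:
        return self.y == 0.0

    @property
    def is_one(self) -> np.ndarray:
        return self.y == 1.0

    @property
    def is_interior(self) -> np.ndarray:
        return (self.y > 0.0) & (self.y < 1.0)


@dataclass(frozen=True)
class ZOIBParams:
    """Complete parameter vector of the multilevel ZOIB model.

    ``precision`` is the beta concentration alpha1 + alpha2 (often written
    phi_B), distinct from the DEA expansion factor.
    """

    beta0: float
    beta1: np.ndarray
    beta2: np.ndarray
    u: np.ndarray
    sigma_u0: float
    gamma0: float
    gamma1: np.ndarray
    gamma2: np.ndarray
    theta: float
    precision: float

    def __post_init__(self):
        for name in ("beta1", "beta2", "gamma1", "gamma2", "u"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if self.sigma_u0 <= 0:
            raise ValueError("sigma_u0 must be > 0")
        if self.precision <= 0:
            raise ValueError("precision must be > 0")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")


def _check_dims(params: ZOIBParams, design: HierarchicalDesign) -> None:
    if len(params.beta1) != design.l1 or len(params.gamma1) != design.l1:
        raise ValueError("level-1 coefficient length does not match design")
    if len(params.beta2) != design.l2 or len(params.gamma2) != design.l2:
        raise ValueError("level-2 coefficient length does not match design")
    if len(params.u) != design.n_groups:
        raise ValueError("random-intercept length does not match n_groups")


def mu_linpred(params: ZOIBParams, design: HierarchicalDesign) -> np.ndarray:
    """Per-unit beta mean mu_ij = inv_logit(beta0 + u_0j + X1 b1 + X2 b2)."""
    _check_dims(params, design)
    eta = (
        params.beta0
        + params.u[design.group_of]
        + design.X1 @ params.beta1
        + design.x2_broadcast() @ params.beta2
    )
    return inv_logit(eta)


def omega_linpred(params: ZOIBParams, design: HierarchicalDesign) -> np.ndarray:
    """Per-unit endpoint probability omega01_ij; fixed effects only (no
    random intercept in this submodel)."""
    _check_dims(params, design)
    eta = (
        params.gamma0
        + design.X1 @ params.gamma1
        + design.x2_broadcast() @ params.gamma2
    )
    return inv_logit(eta)


def beta_shapes(mu, precision):
    """(alpha1, alpha2) = (mu * precision, (1-mu) * precision)."""
    mu = np.asarray(mu, dtype=float)
    precision = np.asarray(precision, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if np.any(precision <= 0):
        raise ValueError("precision must be > 0")
    return mu * precision, (1.0 - mu) * precision


def zoib_logpdf(y, omega01, theta, mu, precision):
    """Log-density of the zero-one inflated beta mixture.

    Vectorised over ``y`` (with scalar or matching-shape parameters).
    Zero-probability endpoint observations yield ``-inf`` rather than an
    exception.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("y must lie in [0, 1]")
    omega01, theta, mu, precision = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (omega01, theta, mu, precision)),
        np.empty(y.shape),
    )[:4]
    a1, a2 = beta_shapes(mu, precision)
    with np.errstate(divide="ignore"):
        lp_zero = np.log(omega01) + np.log1p(-theta)
        lp_one = np.log(omega01) + np.log(theta)
        lp_mid = np.log1p(-omega01) + stats.beta.logpdf(np.clip(y, 1e-12, 1 - 1e-12), a1, a2)
    out = np.where(y == 0.0, lp_zero, np.where(y == 1.0, lp_one, lp_mid))
    return float(out) if out.ndim == 0 else out


def loglik(params: ZOIBParams, design: HierarchicalDesign, y: ResponseVector) -> float:
    """Joint log-likelihood: sum of :func:`zoib_logpdf` over units with
    unit-specific mu_ij and omega01_ij."""
    if design.n_units != y.n:
        raise ValueError("design and response lengths differ")
    if y.n == 0:
        return 0.0
    mu = mu_linpred(params, design)
    om = omega_linpred(params, design)
    return float(np.sum(zoib_logpdf(y.y, om, params.theta, mu, params.precision)))


@dataclass(frozen=True)
class PriorConfig:
    """Prior specification for the Bayesian fit.

    ``default`` uses improper flat priors on all fixed effects, a
    half-normal prior on the random-intercept scale sigma_u0, a uniform(0,1)
    prior on theta, and a half-normal prior on the precision.  The
    ``gamma_sensitivity`` and ``normal_sensitivity`` configurations swap the
    sigma_u0/precision priors for gamma and (positive-truncated) normal
    forms, for sensitivity analysis.
    """

    name: str = "default"
    sigma_u0_scale: float = 2.5
    precision_scale: float = 50.0
    # gamma sensitivity: Gamma(shape, rate) on sigma_u0 and precision
    gamma_shape: float = 2.0
    sigma_u0_gamma_rate: float = 2.0
    precision_gamma_rate: float = 0.1
    # normal sensitivity: N(loc, scale) truncated to (0, inf)
    sigma_u0_normal_loc: float = 1.0
    precision_normal_loc: float = 10.0

    KNOWN = ("default", "gamma_sensitivity", "normal_sensitivity")

    def __post_init__(self):
        if self.name not in self.KNOWN:
            raise ValueError(f"unknown prior config {self.name!r}; choose from {self.KNOWN}")

    def logp_sigma_u0(self, sigma: float) -> float:
        if sigma <= 0:
            return -np.inf
        if self.name == "gamma_sensitivity":
            return float(stats.gamma.logpdf(sigma, self.gamma_shape, scale=1.0 / self.sigma_u0_gamma_rate))
        if self.name == "normal_sensitivity":
            return float(stats.truncnorm.logpdf(
                sigma, -self.sigma_u0_normal_loc / self.sigma_u0_scale, np.inf,
                loc=self.sigma_u0_normal_loc, scale=self.sigma_u0_scale))
        return float(stats.halfnorm.logpdf(sigma, scale=self.sigma_u0_scale))

    def logp_precision(self, precision: float) -> float:
        if precision <= 0:
            return -np.inf
        if self.name == "gamma_sensitivity":
            return float(stats.gamma.logpdf(precision, self.gamma_shape, scale=1.0 / self.precision_gamma_rate))
        if self.name == "normal_sensitivity":
            return float(stats.truncnorm.logpdf(
                precision, -self.precision_normal_loc / self.precision_scale, np.inf,
                loc=self.precision_normal_loc, scale=self.precision_scale))
        return float(stats.halfnorm.logpdf(precision, scale=self.precision_scale))

    def logp_theta(self, theta: float) -> float:
        return 0.0 if 0.0 <= theta <= 1.0 else -np.inf


def log_prior(params: ZOIBParams, prior_config: PriorConfig | str = "default") -> float:
    """Joint log-prior.  Fixed effects contribute zero (flat); the random
    intercepts contribute their N(0, sigma_u0^2) increments."""
    if isinstance(prior_config, str):
        prior_config = PriorConfig(name=prior_config)
    lp = prior_config.logp_sigma_u0(params.sigma_u0)
    lp += prior_config.logp_precision(params.precision)
    lp += prior_config.logp_theta(params.theta)
    lp += float(np.sum(stats.norm.logpdf(params.u, scale=params.sigma_u0)))
    return lp


def mei(mu):
    """Mean efficiency index mu / (1 - mu); > 1 when mean efficiency
    exceeds mean inefficiency."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mei requires mu strictly inside (0, 1)")
    out = mu / (1.0 - mu)
    return float(out) if out.ndim == 0 else out


def ratio_from_coefficient(coef):
    """exp(coef): RMEI for a mu-submodel coefficient, odds ratio of frontier
    membership for an omega01-submodel coefficient.  Applying it to the CI
    bounds of the coefficient gives the CI of the ratio."""
    out = np.exp(np.asarray(coef, dtype=float))
    return float(out) if out.ndim == 0 else out
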