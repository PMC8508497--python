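"""Posterior sampling and MCMC summarisation for the multilevel ZOIB model.

The default sampler is an adaptive random-walk Metropolis-within-Gibbs
scheme over parameter blocks:

* the mu-submodel fixed effects (beta0, beta1, beta2) as one block with a
  covariance-adapted multivariate normal proposal,
* the omega01-submodel fixed effects (gamma0, gamma1, gamma2) likewise,
* the group random intercepts u_j, updated jointly but accepted per group
  (groups are conditionally independent given the fixed effects),
* scalar blocks for logit(theta), log(precision) and log(sigma_u0).

Proposal scales and covariances adapt only during warmup (Robbins-Monro on
the log step size toward standard acceptance targets; Haario-style
empirical covariance for the two fixed-effect blocks) and are frozen
afterwards, so retained draws come from a fixed-kernel Markov chain.

Diagnostics (rank-normalised split R-hat, bulk and tail effective sample
size) follow the modern formulation and are computed with ``arviz``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .zoib import (
    HierarchicalDesign,
    PriorConfig,
    ResponseVector,
    ZOIBParams,
)

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

__all__ = [
    "MCMCConfig",
    "ChainSet",
    "sample_posterior",
    "rhat",
    "bulk_ess",
    "tail_ess",
    "summarize",
    "convergence_check",
]


@dataclass(frozen=True)
class MCMCConfig:
    """MCMC settings: 4 chains, 1000 warmup iterations and 5000 retained
    updates per chain by default."""

    chains: int = 4
    warmup: int = 1000
    iters: int = 5000
    seed: int = 0
    thin: int = 1  # keep every thin-th post-warmup iteration
    jitter: float = 0.1  # sd of the per-chain initialisation jitter


@dataclass(frozen=True)
class ChainSet:
    """Retained posterior draws: (chains, iterations, parameters)."""

    draws: np.ndarray
    names: tuple
    seed: int
    warmup: int
    accept_rates: dict = field(default_factory=dict)

    def __post_init__(self):
        draws = np.asarray(self.draws, dtype=float)
        if draws.ndim != 3:
            raise ValueError("draws must have shape (chains, iters, params)")
        if draws.shape[2] != len(self.names):
            raise ValueError("parameter names do not match draw dimension")
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")
        if np.isnan(draws).any():
            raise ValueError("NaN draws after warmup")
        object.__setattr__(self, "draws", draws)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def param(self, name: str) -> np.ndarray:
        """Draws for one parameter as a (chains, iters) array."""
        return self.draws[:, :, self.names.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.param(name).ravel()

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draws table (chain, iteration, parameter, value)."""
        C, S, P = self.draws.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(C), S * P),
                "iteration": np.tile(np.repeat(np.arange(S), P), C),
                "parameter": np.tile(np.array(self.names), C * S),
                "value": self.draws.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# diagnostics


def _as_chain_array(draws) -> np.ndarray:
    a = np.asarray(draws, dtype=float)
    if a.ndim != 2:
        raise ValueError("diagnostics expect draws of shape (chains, iterations)")
    if a.shape[0] < 2 or a.shape[1] < 4:
        raise ValueError("diagnostics need >= 2 chains and >= 4 iterations")
    return a


def _is_constant(a: np.ndarray) -> bool:
    return bool(np.all(a == a.flat[0]))


def rhat(draws) -> float:
    """Rank-normalised split-chain R-hat; NaN (with a warning) for
    constant draws."""
    a = _as_chain_array(draws)
    if _is_constant(a):
        warnings.warn("constant draws: R-hat is undefined", RuntimeWarning)
        return float("nan")
    return float(az.rhat(a, method="rank"))


def bulk_ess(draws) -> float:
    """Bulk effective sample size from rank-normalised draws."""
    a = _as_chain_array(draws)
    if _is_constant(a):
        warnings.warn("constant draws: ESS is undefined", RuntimeWarning)
        return float("nan")
    return float(az.ess(a, method="bulk"))


def tail_ess(draws) -> float:
    """Tail effective sample size (minimum over the 5% and 95% quantile
    indicator series)."""
    a = _as_chain_array(draws)
    if _is_constant(a):
        warnings.warn("constant draws: ESS is undefined", RuntimeWarning)
        return float("nan")
    return float(az.ess(a, method="tail"))


# ---------------------------------------------------------------------------
# posterior


class _ZOIBPosterior:
    """Pre-computed log-posterior pieces for block updates.

    The likelihood factorises as an interior beta part (depends on the
    mu-submodel and the precision), an endpoint-membership part (depends on
    the gamma block) and a 1-vs-0 part (depends on theta only), so each
    block update only re-evaluates its own piece.
    """

    def __init__(self, design: HierarchicalDesign, y: ResponseVector, prior: PriorConfig):
        self.design = design
        self.prior = prior
        self.J = design.n_groups
        X = design.fixed_effects_matrix()
        interior = y.is_interior
        self.n0 = int(y.is_zero.sum())
        self.n1 = int(y.is_one.sum())
        self.endpoint = ~interior
        self.X_all = X
        # interior rows sorted by group so per-group sums are reduceat slices
        idx = np.nonzero(interior)[0]
        order = np.argsort(design.group_of[idx], kind="stable")
        self.int_idx = idx[order]
        self.g_int = design.group_of[self.int_idx]
        self.X_int = X[self.int_idx]
        yi = y.y[self.int_idx]
        self.log_y = np.log(yi)
        self.log_1my = np.log1p(-yi)
        # groups that own at least one interior unit, and reduceat offsets
        self.groups_present, starts = np.unique(self.g_int, return_index=True)
        self.reduce_starts = starts
        self.p_beta = X.shape[1]
        self.p_gamma = X.shape[1]

    # interior beta log-density per interior unit
    def interior_terms(self, beta_vec: np.ndarray, u: np.ndarray, log_prec: float) -> np.ndarray:
        eta = self.X_int @ beta_vec + u[self.g_int]
        mu = special.expit(eta)
        np.clip(mu, 1e-12, 1.0 - 1e-12, out=mu)
        prec = np.exp(log_prec)
        a1 = mu * prec
        a2 = prec - a1
        return (
            (a1 - 1.0) * self.log_y
            + (a2 - 1.0) * self.log_1my
            - special.betaln(a1, a2)
        )

    def group_sums(self, terms: np.ndarray) -> np.ndarray:
        """Sum interior terms per group, zero-filled for empty groups."""
        out = np.zeros(self.J)
        if len(terms):
            out[self.groups_present] = np.add.reduceat(terms, self.reduce_starts)
        return out

    def ll_omega(self, gamma_vec: np.ndarray) -> float:
        eta = self.X_all @ gamma_vec
        # endpoint rows contribute log(omega) = eta - softplus(eta);
        # interior rows contribute log(1-omega) = -softplus(eta)
        return float(eta[self.endpoint].sum() - np.logaddexp(0.0, eta).sum())

    def ll_theta(self, logit_theta: float) -> float:
        # n1*log(theta) + n0*log(1-theta) in terms of the unconstrained scale
        return -self.n1 * np.logaddexp(0.0, -logit_theta) - self.n0 * np.logaddexp(0.0, logit_theta)

    # log-priors on the sampling (unconstrained) scale, Jacobians included
    def lp_sigma(self, log_sigma: float) -> float:
        return self.prior.logp_sigma_u0(np.exp(log_sigma)) + log_sigma

    def lp_prec(self, log_prec: float) -> float:
        return self.prior.logp_precision(np.exp(log_prec)) + log_prec

    def lp_theta(self, logit_theta: float) -> float:
        # uniform(0,1) on theta; Jacobian of the logistic transform
        return -np.logaddexp(0.0, logit_theta) - np.logaddexp(0.0, -logit_theta)

    def lp_u(self, u: np.ndarray, log_sigma: float) -> np.ndarray:
        sig2 = np.exp(2.0 * log_sigma)
        return -0.5 * u * u / sig2 - log_sigma - 0.5 * np.log(2.0 * np.pi)


class _BlockAdapter:
    """Haario-style covariance adaptation with Robbins-Monro step scaling."""

    def __init__(self, dim: int, target: float, init_scale: float = 0.1):
        self.dim = dim
        self.target = target
        self.log_s = 0.0
        self.mean = np.zeros(dim)
        self.m2 = np.eye(dim) * init_scale**2
        self.count = 0
        self.chol = np.eye(dim) * init_scale
        self._base = np.eye(dim) * init_scale

    def propose(self, rng: np.random.Generator, x: np.ndarray) -> np.ndarray:
        return x + np.exp(self.log_s) * (self.chol @ rng.standard_normal(self.dim))

    def update(self, x: np.ndarray, accepted: bool, t: int) -> None:
        self.count += 1
        d = x - self.mean
        self.mean += d / self.count
        self.m2 += np.outer(d, x - self.mean)
        self.log_s += (float(accepted) - self.target) / max(t, 1) ** 0.6
        self.log_s = min(max(self.log_s, -10.0), 4.0)
        if self.count >= 100 and self.count % 25 == 0:
            cov = self.m2 / (self.count - 1)
            cov = (2.38**2 / self.dim) * cov + 1e-10 * np.eye(self.dim)
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:  # pragma: no cover
                pass


#: Metropolis sweeps of each fixed-effect block per Gibbs iteration
SWEEPS = 3


def _run_chain(post: _ZOIBPosterior, cfg: MCMCConfig, rng: np.random.Generator):
    J = post.J
    pb, pg = post.p_beta, post.p_gamma
    # initialisation: fixed effects at 0, sigma_u0=1, theta=0.9, precision=10,
    # u=0, all jittered per chain (values sit in the plausible regime)
    for _ in range(100):
        beta = rng.normal(0.0, cfg.jitter, pb)
        gamma = rng.normal(0.0, cfg.jitter, pg)
        u = rng.normal(0.0, cfg.jitter, J)
        log_sigma = np.log(1.0) + rng.normal(0.0, cfg.jitter)
        logit_theta = special.logit(0.9) + rng.normal(0.0, cfg.jitter)
        log_prec = np.log(10.0) + rng.normal(0.0, cfg.jitter)
        int_terms = post.interior_terms(beta, u, log_prec)
        ll0 = (
            int_terms.sum()
            + post.ll_omega(gamma)
            + post.ll_theta(logit_theta)
            + post.lp_u(u, log_sigma).sum()
            + post.lp_sigma(log_sigma)
            + post.lp_prec(log_prec)
            + post.lp_theta(logit_theta)
        )
        if np.isfinite(ll0):
            break
    else:
        raise RuntimeError("could not find a finite log-posterior initial state")

    cur_int = int_terms  # per-interior-unit beta log-density
    cur_omega = post.ll_omega(gamma)

    ad_beta = _BlockAdapter(pb, 0.234)
    ad_gamma = _BlockAdapter(pg, 0.234)
    step_u = np.full(J, 0.5)
    step_sigma, step_theta, step_prec, step_c = 0.5, 0.5, 0.3, 0.3
    acc = {"beta": 0, "gamma": 0, "u": 0, "theta": 0, "precision": 0, "sigma": 0}

    total = cfg.warmup + cfg.iters * cfg.thin
    out = np.empty((cfg.iters, pb + pg + 3 + J))

    for t in range(total):
        warm = t < cfg.warmup

        # --- beta block (interior likelihood only; flat prior); several
        # sweeps per iteration because the correlated fixed-effect block
        # is the mixing bottleneck ---
        for _ in range(SWEEPS):
            prop = ad_beta.propose(rng, beta)
            prop_terms = post.interior_terms(prop, u, log_prec)
            a = prop_terms.sum() - cur_int.sum()
            ok = np.log(rng.random()) < a
            if ok:
                beta, cur_int = prop, prop_terms
                acc["beta"] += (not warm) / SWEEPS
            if warm:
                ad_beta.update(beta, ok, t + 1)

        # --- gamma block (endpoint-membership likelihood; flat prior) ---
        for _ in range(SWEEPS):
            prop = ad_gamma.propose(rng, gamma)
            prop_omega = post.ll_omega(prop)
            ok = np.log(rng.random()) < prop_omega - cur_omega
            if ok:
                gamma, cur_omega = prop, prop_omega
                acc["gamma"] += (not warm) / SWEEPS
            if warm:
                ad_gamma.update(gamma, ok, t + 1)

        # --- random intercepts: joint proposal, per-group accept ---
        prop_u = u + step_u * rng.standard_normal(J)
        prop_terms = post.interior_terms(beta, prop_u, log_prec)
        d_ll = post.group_sums(prop_terms) - post.group_sums(cur_int)
        d_lp = post.lp_u(prop_u, log_sigma) - post.lp_u(u, log_sigma)
        ok_g = np.log(rng.random(J)) < d_ll + d_lp
        if ok_g.any():
            u = np.where(ok_g, prop_u, u)
            take = ok_g[post.g_int]
            cur_int = np.where(take, prop_terms, cur_int)
        acc["u"] += (not warm) * float(ok_g.mean())
        if warm:
            step_u = np.clip(step_u * np.exp((ok_g.astype(float) - 0.44) / (t + 1) ** 0.6), 1e-6, 50.0)

        # --- recentering move: beta0 += c, u -= c leaves the likelihood
        # unchanged and walks along the intercept/random-effect ridge;
        # only the u prior enters the acceptance ratio ---
        c = step_c * rng.standard_normal()
        a = post.lp_u(u - c, log_sigma).sum() - post.lp_u(u, log_sigma).sum()
        ok = np.log(rng.random()) < a
        if ok:
            beta = beta.copy()
            beta[0] += c
            u = u - c
        if warm:
            step_c = min(step_c * np.exp((float(ok) - 0.44) / (t + 1) ** 0.6), 50.0)

        # --- theta (endpoint 1-vs-0 counts only) ---
        prop = logit_theta + step_theta * rng.standard_normal()
        a = (post.ll_theta(prop) + post.lp_theta(prop)) - (
            post.ll_theta(logit_theta) + post.lp_theta(logit_theta)
        )
        ok = np.log(rng.random()) < a
        if ok:
            logit_theta = prop
            acc["theta"] += not warm
        if warm:
            step_theta = min(step_theta * np.exp((float(ok) - 0.44) / (t + 1) ** 0.6), 50.0)

        # --- precision (interior likelihood) ---
        prop = log_prec + step_prec * rng.standard_normal()
        prop_terms = post.interior_terms(beta, u, prop)
        a = (prop_terms.sum() + post.lp_prec(prop)) - (cur_int.sum() + post.lp_prec(log_prec))
        ok = np.log(rng.random()) < a
        if ok:
            log_prec, cur_int = prop, prop_terms
            acc["precision"] += not warm
        if warm:
            step_prec = min(step_prec * np.exp((float(ok) - 0.44) / (t + 1) ** 0.6), 50.0)

        # --- sigma_u0 (random-intercept prior + hyperprior) ---
        prop = log_sigma + step_sigma * rng.standard_normal()
        a = (post.lp_u(u, prop).sum() + post.lp_sigma(prop)) - (
            post.lp_u(u, log_sigma).sum() + post.lp_sigma(log_sigma)
        )
        ok = np.log(rng.random()) < a
        if ok:
            log_sigma = prop
            acc["sigma"] += not warm
        if warm:
            step_sigma = min(step_sigma * np.exp((float(ok) - 0.44) / (t + 1) ** 0.6), 50.0)

        if not warm and (t - cfg.warmup) % cfg.thin == cfg.thin - 1:
            s = (t - cfg.warmup) // cfg.thin
            out[s, :pb] = beta
            out[s, pb : pb + pg] = gamma
            out[s, pb + pg] = special.expit(logit_theta)
            out[s, pb + pg + 1] = np.exp(log_prec)
            out[s, pb + pg + 2] = np.exp(log_sigma)
            out[s, pb + pg + 3 :] = u

    rates = {k: v / (cfg.iters * cfg.thin) for k, v in acc.items()}
    return out, rates


def parameter_names(design: HierarchicalDesign) -> tuple:
    """Canonical parameter ordering of the sampled posterior."""
    fixed = ["0"] + [f"[{c}]" for c in design.x1_names] + [f"[{c}]" for c in design.x2_names]
    names = [f"beta{s}" for s in fixed] + [f"gamma{s}" for s in fixed]
    names += ["theta", "precision", "sigma_u0"]
    names += [f"u[{j}]" for j in range(design.n_groups)]
    return tuple(names)


def sample_posterior(
    design: HierarchicalDesign,
    y: ResponseVector,
    prior_config: PriorConfig | str = "default",
    mcmc_config: MCMCConfig | None = None,
) -> ChainSet:
    """Draw from the posterior of the multilevel ZOIB model.

    Chains run sequentially with per-chain generators spawned from the
    master seed, so results are exactly reproducible for a given
    (seed, config) pair.
    """
    if isinstance(prior_config, str):
        prior_config = PriorConfig(name=prior_config)
    cfg = mcmc_config or MCMCConfig()
    post = _ZOIBPosterior(design, y, prior_config)
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    draws, rate_list = [], []
    for ss in seqs:
        d, rates = _run_chain(post, cfg, np.random.default_rng(ss))
        draws.append(d)
        rate_list.append(rates)
    mean_rates = {k: float(np.mean([r[k] for r in rate_list])) for k in rate_list[0]}
    return ChainSet(
        draws=np.stack(draws),
        names=parameter_names(design),
        seed=cfg.seed,
        warmup=cfg.warmup,
        accept_rates=mean_rates,
    )


# ---------------------------------------------------------------------------
# summaries


def _is_coefficient(name: str) -> bool:
    """Regression coefficients (not intercepts or nuisance parameters) get
    an exp-transformed ratio column."""
    return name.startswith(("beta[", "gamma["))


def summarize(chains: ChainSet, ratio_for=None) -> pd.DataFrame:
    """Posterior summary table, one row per parameter.

    Columns: mean, sd, 2.5/97.5 percentiles of the pooled post-warmup
    draws (linear interpolation), PCP (fraction of draws strictly > 0,
    draws exactly at 0 count as negative so PCP + NCP = 1 exactly), NCP,
    rank-normalised R-hat, bulk and tail ESS, and ratio = exp(mean) for
    regression coefficients (RMEI in the mu-submodel, OR in the omega01
    submodel).
    """
    rows = []
    for i, name in enumerate(chains.names):
        d = chains.draws[:, :, i]
        pooled = d.ravel()
        p2_5, p97_5 = np.percentile(pooled, [2.5, 97.5])
        pcp = float(np.mean(pooled > 0))
        is_coef = _is_coefficient(name) if ratio_for is None else (name in ratio_for)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r, be, te = rhat(d), bulk_ess(d), tail_ess(d)
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)),
                "p2_5": float(p2_5),
                "p97_5": float(p97_5),
                "pcp": pcp,
                "ncp": 1.0 - pcp,
                "rhat": r,
                "bulk_ess": be,
                "tail_ess": te,
                "ratio": float(np.exp(pooled.mean())) if is_coef else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def convergence_check(
    summary: pd.DataFrame, rhat_max: float = 1.01, ess_min: float = 400.0
) -> pd.DataFrame:
    """Per-parameter convergence verdicts at the standard thresholds
    (R-hat < 1.01, bulk and tail ESS > 400)."""
    ok = (
        (summary["rhat"] < rhat_max)
        & (summary["bulk_ess"] > ess_min)
        & (summary["tail_ess"] > ess_min)
    )
    return pd.DataFrame({"converged": ok})
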