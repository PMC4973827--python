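"""Fitting the cumulative link model: Bayesian MCMC and a maximum-likelihood oracle.

The posterior over ``(theta, beta)`` under the categorical likelihood is
sampled with adaptive random-walk Metropolis-within-Gibbs on an unconstrained
parameterization: ``z1 = theta_1``, log-increments ``w_j = log(theta_{j+1} -
theta_j)`` and the raw weights ``beta``.  Step sizes adapt toward a ~44%
acceptance rate during burn-in only, so the post-burn-in chain is a valid
Markov chain.  Convergence is assessed with the potential scale reduction
factor (split-R-hat, rank-normalized by default).

Priors (vague but proper): ``beta_k ~ Normal(0, prior_sd)``, ``theta_1 ~
Normal(0, prior_sd)``, increments ``theta_{j+1} - theta_j ~
HalfNormal(prior_sd)``.  They are placed on the internally standardized score
scale (scores are centered/scaled for mixing; draws are reported
back-transformed to the original scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtri
from scipy.stats import rankdata

from .io import Dataset
from .model import CLMParameters, log_class_prob_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "fit_bayes",
    "fit_ml",
    "psrf",
    "summarize",
]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings; ``seed`` is mandatory for reproducibility."""

    seed: int
    n_chains: int = 4
    n_iter: int = 5000
    n_burnin: int = 2500
    prior_sd: float = 10.0
    psrf_threshold: float = 1.05

    def __post_init__(self):
        if self.n_iter <= self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class PosteriorDraws:
    """Post-burn-in posterior draws of (theta, beta) on the original score scale.

    ``theta`` has shape (n_chains, n_kept, J-1), ``beta`` (n_chains, n_kept, k).
    """

    theta: np.ndarray
    beta: np.ndarray
    config: SamplerConfig
    converged: bool = True
    psrf_values: np.ndarray | None = None
    param_names: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_kept(self) -> int:
        return self.theta.shape[1]

    @property
    def n_classes(self) -> int:
        return self.theta.shape[2] + 1

    def stacked(self) -> np.ndarray:
        """All draws pooled across chains, shape (n_chains * n_kept, n_params)."""
        flat = np.concatenate([self.theta, self.beta], axis=2)
        return flat.reshape(-1, flat.shape[2])

    def posterior_mean(self) -> CLMParameters:
        """Posterior-mean parameters (the mean of ordered draws stays ordered)."""
        return CLMParameters(
            theta=self.theta.reshape(-1, self.theta.shape[2]).mean(axis=0),
            beta=self.beta.reshape(-1, self.beta.shape[2]).mean(axis=0),
        )


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean/sd/95% credible interval and PSRF."""

    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4f}")


def _unconstrained_to_theta(z: np.ndarray, J: int) -> np.ndarray:
    theta = np.empty(J - 1)
    theta[0] = z[0]
    if J > 2:
        theta[1:] = z[0] + np.cumsum(np.exp(z[1 : J - 1]))
    return theta


def _log_posterior(z: np.ndarray, X: np.ndarray, y: np.ndarray, J: int, prior_sd: float) -> float:
    theta = _unconstrained_to_theta(z, J)
    beta = z[J - 1 :]
    logp = log_class_prob_matrix(theta, beta, X)
    ll = logp[np.arange(len(y)), y - 1].sum()
    # theta_1 and beta: Normal(0, prior_sd); increments HalfNormal(prior_sd)
    # with the log|d incr/d w| = w Jacobian of the log transform.
    lp = -0.5 * (z[0] / prior_sd) ** 2 - 0.5 * np.sum((beta / prior_sd) ** 2)
    if J > 2:
        w = z[1 : J - 1]
        incr = np.exp(w)
        lp += np.sum(-0.5 * (incr / prior_sd) ** 2 + w)
    return float(ll + lp)


def _init_unconstrained(y: np.ndarray, J: int, k: int, rng: np.random.Generator) -> np.ndarray:
    # cut-offs at the logits of the empirical cumulative class frequencies,
    # jittered so chains start overdispersed
    freq = np.bincount(y, minlength=J + 1)[1:] / len(y)
    cum = np.clip(np.cumsum(freq)[:-1], 1e-3, 1 - 1e-3)
    theta0 = np.log(cum / (1 - cum))
    theta0 = np.sort(theta0 + rng.normal(0, 0.5, J - 1))
    theta0 += np.arange(J - 1) * 1e-3  # break exact ties
    z = np.empty(J - 1 + k)
    z[0] = theta0[0]
    if J > 2:
        z[1 : J - 1] = np.log(np.maximum(np.diff(theta0), 1e-3))
    z[J - 1 :] = rng.normal(0, 0.5, k)
    return z


def fit_bayes(
    ds: Dataset | None,
    config: SamplerConfig,
    prior_only: bool = False,
    n_classes: int | None = None,
) -> PosteriorDraws:
    """Sample the posterior of the cumulative link model parameters.

    Parameters
    ----------
    ds
        Fit-ready dataset (every record has a class and a score).  May be
        ``None`` together with ``prior_only=True`` to sample the prior — a
        debug mode for prior-recovery checks (``n_classes`` then required).
    config
        Chains, iterations, burn-in, seed, prior scale and PSRF threshold.

    Returns post-burn-in draws back-transformed to the original score scale.
    Identical (data, config) inputs give bit-identical draws.  If any
    parameter's PSRF exceeds the threshold the draws are still returned with
    ``converged=False`` and a prominent warning.
    """
    if prior_only:
        if n_classes is None:
            raise ValueError("prior_only sampling needs n_classes")
        J = n_classes
        X = np.zeros((0, 1))
        y = np.zeros(0, dtype=int)
        xm, xs = 0.0, 1.0
    else:
        if ds is None or len(ds) == 0:
            raise ValueError("cannot fit an empty dataset")
        y = ds.classes
        if np.any(y < 1):
            raise ValueError("fit requires expert classes on every record")
        J = ds.n_classes
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate data: all records in a single class")
        if len(ds) < J:
            raise ValueError(f"need at least J={J} records")
        x = ds.scores
        xm = float(x.mean())
        xs = float(x.std())
        if xs == 0:
            raise ValueError("scores have zero variance")
        X = ((x - xm) / xs)[:, None]
    k = X.shape[1]
    dim = J - 1 + k

    def logpost(z):
        if prior_only:
            return _log_posterior(z, X, y, J, config.prior_sd)
        return _log_posterior(z, X, y, J, config.prior_sd)

    n_kept = config.n_iter - config.n_burnin
    theta_out = np.empty((config.n_chains, n_kept, J - 1))
    beta_out = np.empty((config.n_chains, n_kept, k))
    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(config.n_chains)

    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        z = _init_unconstrained(y, J, k, rng) if not prior_only else rng.normal(0, 1, dim)
        lp = logpost(z)
        step = np.full(dim, 0.1)
        accepted = np.zeros(dim)
        proposed = np.zeros(dim)
        # joint proposal: empirical covariance of burn-in draws (Haario-style),
        # adapted during burn-in only and frozen afterwards
        joint_scale = 2.38 / np.sqrt(dim)
        chol = None
        hist = np.empty((config.n_burnin, dim))
        joint_acc = joint_prop = 0
        for it in range(config.n_iter):
            for d in range(dim):
                z_prop = z.copy()
                z_prop[d] += step[d] * rng.standard_normal()
                lp_prop = logpost(z_prop)
                proposed[d] += 1
                if np.log(rng.random()) < lp_prop - lp:
                    z, lp = z_prop, lp_prop
                    accepted[d] += 1
            if chol is not None:
                z_prop = z + joint_scale * (chol @ rng.standard_normal(dim))
                lp_prop = logpost(z_prop)
                joint_prop += 1
                if np.log(rng.random()) < lp_prop - lp:
                    z, lp = z_prop, lp_prop
                    joint_acc += 1
            if it < config.n_burnin:
                hist[it] = z
                if (it + 1) % 50 == 0:
                    # Robbins–Monro style scale adaptation toward ~44% acceptance
                    rate = accepted / np.maximum(proposed, 1)
                    step *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
                    accepted[:] = 0
                    proposed[:] = 0
                    if it + 1 >= 200:
                        cov = np.cov(hist[(it + 1) // 2 : it + 1].T)
                        try:
                            chol = np.linalg.cholesky(cov + 1e-8 * np.eye(dim))
                        except np.linalg.LinAlgError:
                            chol = None
                        if joint_prop > 0:
                            joint_scale *= np.exp(
                                np.clip(joint_acc / joint_prop - 0.23, -0.5, 0.5)
                            )
                            joint_acc = joint_prop = 0
            if it >= config.n_burnin:
                j = it - config.n_burnin
                theta_z = _unconstrained_to_theta(z, J)
                beta_z = z[J - 1 :]
                # back-transform from standardized to raw score scale
                theta_out[c, j] = theta_z + beta_z[0] * xm / xs if not prior_only else theta_z
                beta_out[c, j] = beta_z / xs
        logger.info(
            "chain %d: final acceptance ~%.2f", c, float(np.mean(accepted / np.maximum(proposed, 1)))
        )

    names = [f"theta_{j + 1}" for j in range(J - 1)] + [f"beta_{i + 1}" for i in range(k)]
    draws = PosteriorDraws(
        theta=theta_out, beta=beta_out, config=config, param_names=names
    )
    if config.n_chains >= 2:
        draws.psrf_values = psrf(draws)
        draws.converged = bool(np.all(draws.psrf_values < config.psrf_threshold))
        if not draws.converged:
            logger.warning(
                "MCMC NOT CONVERGED: max PSRF %.3f exceeds threshold %.3f; "
                "treat all downstream results with suspicion",
                float(np.max(draws.psrf_values)),
                config.psrf_threshold,
            )
    return draws


def _split_chains(x: np.ndarray) -> np.ndarray:
    """Split each chain in half: (m, n) -> (2m, n//2)."""
    m, n = x.shape
    half = n // 2
    return np.concatenate([x[:, :half], x[:, n - half :]], axis=0)


def _rhat_basic(x: np.ndarray) -> float:
    """Gelman–Rubin statistic on an (m, n) array of chains."""
    m, n = x.shape
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    B = n * chain_means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def psrf(draws: PosteriorDraws, rank_normalized: bool = True) -> np.ndarray:
    """Split potential scale reduction factor per parameter.

    With ``rank_normalized=True`` (default) draws are rank-transformed and
    mapped through the normal quantile function before the between/within
    variance comparison, which is robust to heavy tails; the plain estimator
    returns exactly 1 for identical chains.
    """
    if draws.n_chains < 2:
        raise ValueError("PSRF needs at least two chains")
    if draws.n_kept < 10:
        raise ValueError("PSRF needs at least 10 post-burn-in iterations")
    flat = np.concatenate([draws.theta, draws.beta], axis=2)
    out = np.empty(flat.shape[2])
    for p in range(flat.shape[2]):
        chains = flat[:, :, p]
        if np.all(chains == chains[0]):
            # zero between-chain variance (e.g. chains run from identical
            # seeds and inits): converged by definition
            out[p] = 1.0
            continue
        x = _split_chains(chains)
        if rank_normalized and not np.allclose(x, x.ravel()[0]):
            r = rankdata(x.ravel()).reshape(x.shape)
            x = ndtri((r - 0.375) / (x.size + 0.25))
        out[p] = _rhat_basic(x)
    return out


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Posterior mean, sd, central 95% credible interval and PSRF per parameter."""
    flat = draws.stacked()
    if flat.shape[0] == 0:
        raise ValueError("no draws to summarize")
    rhat = (
        psrf(draws)
        if draws.n_chains >= 2 and draws.n_kept >= 10
        else np.full(flat.shape[1], np.nan)
    )
    table = pd.DataFrame(
        {
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else 0.0,
            "q2.5": np.quantile(flat, 0.025, axis=0),
            "q97.5": np.quantile(flat, 0.975, axis=0),
            "psrf": rhat,
        },
        index=draws.param_names or None,
    )
    return PosteriorSummary(table=table)


def fit_ml(
    ds: Dataset, return_se: bool = False
) -> CLMParameters | tuple[CLMParameters, np.ndarray]:
    """Maximum-likelihood fit by BFGS on the unconstrained parameterization.

    Serves as an independent check on the Bayesian fit (with vague priors and
    enough data the two agree).  Optionally returns asymptotic standard
    errors for ``(theta, beta)`` from the inverse observed information.
    Complete separation (the score perfectly splitting the classes) shows up
    as a diverging ``beta`` and is reported as an error.
    """
    y = ds.classes
    if len(ds) == 0 or np.any(y < 1):
        raise ValueError("fit requires a non-empty dataset with expert classes")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate data: all records in a single class")
    J = ds.n_classes
    x = ds.scores
    xm, xs = float(x.mean()), float(x.std())
    X = ((x - xm) / xs)[:, None]

    def nll(z):
        theta = _unconstrained_to_theta(z, J)
        beta = z[J - 1 :]
        logp = log_class_prob_matrix(theta, beta, X)
        return -float(logp[np.arange(len(y)), y - 1].sum())

    rng = np.random.default_rng(0)
    z0 = _init_unconstrained(y, J, 1, rng)
    res = minimize(nll, z0, method="BFGS", options={"maxiter": 2000, "gtol": 1e-6})
    if not res.success and res.status != 2:  # status 2: precision loss at optimum
        raise RuntimeError(f"ML optimization failed: {res.message}")
    theta_z = _unconstrained_to_theta(res.x, J)
    beta_z = res.x[J - 1 :]
    # Separation check: under complete separation the likelihood keeps
    # improving as (theta, beta) are jointly scaled up, so the MLE does not
    # exist.  Doubling the fitted parameters must strictly hurt the fit.
    z2 = res.x.copy()
    z2[0] *= 2.0
    if J > 2:
        z2[1 : J - 1] += np.log(2.0)
    z2[J - 1 :] *= 2.0
    if nll(z2) <= nll(res.x) + 1e-6 or np.abs(beta_z[0]) > 50:
        raise RuntimeError(
            "beta diverged: the score separates the classes perfectly; "
            "the ML estimate does not exist (complete separation)"
        )
    params = CLMParameters(theta=theta_z + beta_z[0] * xm / xs, beta=beta_z / xs)
    if not return_se:
        return params

    # delta-free SEs: numerical Hessian of the NLL directly in (theta, beta)
    # on the raw scale, inverted to the asymptotic covariance
    def nll_raw(p):
        logp = log_class_prob_matrix(p[: J - 1], p[J - 1 :], x[:, None])
        return -float(logp[np.arange(len(y)), y - 1].sum())

    p_hat = np.concatenate([params.theta, params.beta])
    h = np.maximum(1e-5, 1e-4 * np.abs(p_hat))
    dim = len(p_hat)
    H = np.empty((dim, dim))
    for i in range(dim):
        for j in range(i, dim):
            pp = p_hat.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = p_hat.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = p_hat.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = p_hat.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            H[i, j] = H[j, i] = (nll_raw(pp) - nll_raw(pm) - nll_raw(mp) + nll_raw(mm)) / (
                4 * h[i] * h[j]
            )
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return params, se
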