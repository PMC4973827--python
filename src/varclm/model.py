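"""Cumulative link (proportional-odds) model for an ordinal response.

The response :math:`Y_i` falls in one of :math:`J` ordered classes.  With a
logit link, the cumulative probabilities are

.. math::

    \\gamma_{ij} = P(Y_i \\le j) = \\mathrm{logit}^{-1}(\\theta_j - x_i^\\top\\beta),
    \\qquad j = 1, \\dots, J-1,

with ordered cut-offs :math:`-\\infty < \\theta_1 < \\dots < \\theta_{J-1} <
\\infty` and regression weights :math:`\\beta` (no intercept).  Class
probabilities are first differences of the :math:`\\gamma`; the observation
model is :math:`Y_i \\sim \\mathrm{Categorical}(\\pi_i)`.

Sign convention: positive :math:`\\beta` moves probability mass toward higher
classes as the covariate (here, the scaled deleteriousness score) rises.

Probabilities are evaluated through log-sigmoid differences,

``log(sigmoid(a) - sigmoid(b)) = logsig(a) + logsig(-b) + log1p(-exp(b - a))``,

so that extreme scores (structural variants reach scaled scores far outside
the typical −4..14 range) do not suffer catastrophic cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Dataset, VariantRecord

__all__ = [
    "CLMParameters",
    "ClassProbabilityProfile",
    "cumulative_probs",
    "class_probs",
    "log_likelihood",
    "deviance",
    "assign_class",
]


@dataclass(frozen=True)
class CLMParameters:
    """Ordered cut-offs ``theta`` (length J-1) and regression weights ``beta``."""

    theta: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, dtype=float)))
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        if not np.all(np.isfinite(self.theta)) or not np.all(np.isfinite(self.beta)):
            raise ValueError("CLM parameters must be finite")
        if np.any(np.diff(self.theta) <= 0):
            raise ValueError("theta must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.theta) + 1


@dataclass(frozen=True)
class ClassProbabilityProfile:
    """Per-class probabilities and the cumulative probabilities they sum to."""

    probs: np.ndarray
    cumulative: np.ndarray


def _logsigmoid(z: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -z)


def _eta(params: CLMParameters, x: np.ndarray) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates must be finite")
    if x.shape[-1] != len(params.beta):
        raise ValueError(
            f"covariate length {x.shape[-1]} != number of weights {len(params.beta)}"
        )
    return params.theta - float(x @ params.beta)


def log_class_prob_matrix(
    theta: np.ndarray, beta: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Log class probabilities, shape (n, J), for covariate rows ``X`` (n, k).

    Numerically stable for linear predictors of any magnitude.
    """
    theta = np.atleast_1d(theta)
    beta = np.atleast_1d(beta)
    X = np.atleast_2d(X)
    eta = theta[None, :] - (X @ beta)[:, None]  # (n, J-1)
    J = len(theta) + 1
    n = eta.shape[0]
    out = np.empty((n, J))
    out[:, 0] = _logsigmoid(eta[:, 0])
    out[:, J - 1] = _logsigmoid(-eta[:, J - 2])
    if J > 2:
        a = eta[:, 1:]
        b = eta[:, :-1]
        with np.errstate(divide="ignore"):
            out[:, 1 : J - 1] = (
                _logsigmoid(a) + _logsigmoid(-b) + np.log1p(-np.exp(b - a))
            )
    return out


def cumulative_probs(params: CLMParameters, x) -> np.ndarray:
    """Cumulative class probabilities ``gamma_j = P(Y <= j)``; ``gamma_J = 1``."""
    from scipy.special import expit

    eta = _eta(params, x)
    gamma = np.append(expit(eta), 1.0)
    return gamma


def class_probs(params: CLMParameters, x) -> ClassProbabilityProfile:
    """Per-class probabilities as first differences of the cumulative ones."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    _ = _eta(params, x)  # validates
    logp = log_class_prob_matrix(params.theta, params.beta, x[None, :])[0]
    probs = np.exp(logp)
    probs /= probs.sum()  # removes residual rounding at the 1e-16 level
    return ClassProbabilityProfile(probs=probs, cumulative=np.cumsum(probs))


def log_likelihood(params: CLMParameters, ds: Dataset) -> float:
    """Sum of log class probabilities of the observed classes; ``-inf`` if any is 0."""
    import logging

    if len(ds) == 0:
        logging.getLogger(__name__).warning("log-likelihood of an empty dataset is 0")
        return 0.0
    y = ds.classes
    if np.any(y < 1):
        raise ValueError("all records must carry an expert class")
    logp = log_class_prob_matrix(params.theta, params.beta, ds.scores[:, None])
    return float(logp[np.arange(len(ds)), y - 1].sum())


def deviance(params: CLMParameters, record: VariantRecord) -> float:
    """Deviance ``-2 log P(Y_i)`` of one observation — a measure of surprise.

    Zero iff the observed class has probability one; ``+inf`` when the
    observed class has probability zero (flagged downstream, never raised).
    """
    if record.expert_class is None:
        raise ValueError("record has no expert class")
    logp = log_class_prob_matrix(
        params.theta, params.beta, np.array([[record.score]])
    )[0, record.expert_class - 1]
    return float(-2.0 * logp)


def assign_class(params: CLMParameters, x) -> int:
    """Most probable class (1-based); exact ties break toward the lower class."""
    profile = class_probs(params, x)
    return int(np.argmax(profile.probs)) + 1
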