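"""Deviance-based discrepancy flagging and class reassignment.

For each observation the deviance ``-2 log P(Y_i)`` is averaged over the
posterior draws; observations above the empirical 95th percentile of these
mean deviances are the ones the fitted model finds most surprising and are
flagged for re-examination.  Flagged observations are reassigned to the
model-preferred class (argmax of the class probabilities at the
posterior-mean parameters); unflagged observations keep their expert class.
The observed-vs-model contingency matrix, with the extreme disagreements
(expert class 1 assigned class J = "false positives", expert class J assigned
class 1 = "false negatives"), is the reassignment report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset
from .inference import PosteriorDraws
from .model import CLMParameters, log_class_prob_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "DevianceProfile",
    "ReassignmentReport",
    "mean_deviances",
    "reassign",
    "spearman_class_score",
]

FLAG_QUANTILE = 0.95


@dataclass
class DevianceProfile:
    """Per-variant posterior mean deviance with the 95th-percentile flag."""

    table: pd.DataFrame  # variant_id, mean_deviance, flagged
    threshold: float

    @property
    def n_flagged(self) -> int:
        return int(self.table["flagged"].sum())

    @property
    def flagged_ids(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "variant_id"].tolist()


@dataclass
class ReassignmentReport:
    """J×J matrix of model class (rows) vs expert class (columns) plus extremes."""

    matrix: np.ndarray
    assignments: pd.DataFrame  # variant_id, expert_class, model_class, flagged
    false_positives: list[str]
    false_negatives: list[str]
    n_discordant: int
    n_flagged: int

    def matrix_frame(self) -> pd.DataFrame:
        J = self.matrix.shape[0]
        return pd.DataFrame(
            self.matrix,
            index=[f"model_{j}" for j in range(1, J + 1)],
            columns=[f"expert_{j}" for j in range(1, J + 1)],
        )


def mean_deviances(
    draws: PosteriorDraws,
    ds: Dataset,
    point_estimate: bool = False,
    chunk: int = 256,
) -> DevianceProfile:
    """Posterior mean deviance per record and the 95th-percentile flag.

    ``point_estimate=True`` evaluates the deviance at the posterior-mean
    parameters instead of averaging over draws (sensitivity alternative).
    The flag threshold is the linear-interpolation 95th percentile of the
    mean deviances; flagging uses strict inequality, so a dataset whose
    deviances are all equal flags nothing.
    """
    y = ds.classes
    if np.any(y < 1):
        raise ValueError("all records need an expert class")
    X = ds.scores[:, None]
    n = len(ds)
    idx = np.arange(n)
    if point_estimate:
        pm = draws.posterior_mean()
        mean_dev = -2.0 * log_class_prob_matrix(pm.theta, pm.beta, X)[idx, y - 1]
    else:
        flat = draws.stacked()  # (S, J-1+k)
        J1 = draws.theta.shape[2]
        total = np.zeros(n)
        n_inf = 0
        for start in range(0, flat.shape[0], chunk):
            block = flat[start : start + chunk]
            for row in block:
                logp = log_class_prob_matrix(row[:J1], row[J1:], X)[idx, y - 1]
                n_inf += int(np.sum(np.isneginf(logp)))
                total += -2.0 * logp
        mean_dev = total / flat.shape[0]
        if n_inf > 0.01 * flat.shape[0] * n:
            logger.warning(
                "infinite deviance in %.2f%% of draw-record pairs: possible model misfit",
                100 * n_inf / (flat.shape[0] * n),
            )
    threshold = float(np.quantile(mean_dev, FLAG_QUANTILE))
    flagged = mean_dev > threshold
    table = pd.DataFrame(
        {
            "variant_id": ds.variant_ids,
            "mean_deviance": mean_dev,
            "flagged": flagged,
        }
    )
    return DevianceProfile(table=table, threshold=threshold)


def reassign(
    profile: DevianceProfile,
    draws: PosteriorDraws,
    ds: Dataset,
    average_probs: bool = False,
) -> ReassignmentReport:
    """Build the observed-vs-model reassignment matrix.

    Unflagged records keep their expert class (they land on the diagonal);
    flagged records receive the model's most probable class.  With
    ``average_probs=True`` the argmax is taken over posterior-averaged class
    probabilities rather than probabilities at the posterior-mean parameters.
    """
    y = ds.classes
    J = ds.n_classes
    X = ds.scores[:, None]
    flagged = profile.table["flagged"].to_numpy()
    if average_probs:
        flat = draws.stacked()
        J1 = draws.theta.shape[2]
        probs = np.zeros((len(ds), J))
        for row in flat:
            probs += np.exp(log_class_prob_matrix(row[:J1], row[J1:], X))
        model_class = probs.argmax(axis=1) + 1
    else:
        pm = draws.posterior_mean()
        model_class = (
            np.exp(log_class_prob_matrix(pm.theta, pm.beta, X)).argmax(axis=1) + 1
        )
    final = np.where(flagged, model_class, y)
    matrix = np.zeros((J, J), dtype=int)
    for m, e in zip(final, y):
        matrix[m - 1, e - 1] += 1
    ids = np.array(ds.variant_ids)
    assignments = pd.DataFrame(
        {
            "variant_id": ids,
            "expert_class": y,
            "model_class": final,
            "flagged": flagged,
        }
    )
    discordant = final != y
    return ReassignmentReport(
        matrix=matrix,
        assignments=assignments,
        false_positives=ids[(y == 1) & (final == J)].tolist(),
        false_negatives=ids[(y == J) & (final == 1)].tolist(),
        n_discordant=int(discordant.sum()),
        n_flagged=int(flagged.sum()),
    )


def spearman_class_score(ds: Dataset) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) between class and score.

    Returns ``(rho, p_value)`` with the large-sample two-sided p-value.
    """
    y = ds.classes
    x = ds.scores
    if len(ds) < 3:
        raise ValueError("need at least 3 records")
    if np.any(y < 1):
        raise ValueError("all records need an expert class")
    if np.all(y == y[0]) or np.all(x == x[0]):
        raise ValueError("zero variance: correlation undefined")
    res = stats.spearmanr(y, x)
    return float(res.statistic), float(res.pvalue)
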