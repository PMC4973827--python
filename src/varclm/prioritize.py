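"""Prioritization of variants of uncertain significance (VUS, class 3).

A class-3 variant whose score gives it at least a threshold probability
(default 99%) of belonging to the extreme pathogenic class under the fitted
model is worth prioritizing for expert reclassification.  The equivalent
score cutoff is derived from the fitted parameters in closed form — for the
pathogenic direction and positive beta,

    P(Y = J | x) = 1 - sigmoid(theta_{J-1} - beta x) >= t
    <=>  x >= (theta_{J-1} - logit(1 - t)) / beta

— so the cutoff is a property of the fit, never a hard-coded number.

Also provides the rank-based AUC used to judge, per gene, how well a score
separates pathogenic from benign variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit

from .io import Dataset
from .inference import PosteriorDraws
from .model import log_class_prob_matrix

logger = logging.getLogger(__name__)

__all__ = ["PriorityList", "prioritize_vus", "overlap_with_list", "score_auc", "grouped_auc"]


@dataclass
class PriorityList:
    """Class-3 variants above the probability threshold, most confident first."""

    entries: pd.DataFrame  # variant_id, gene, score, p_class1..p_classJ
    threshold_probability: float
    direction: str
    implied_score_cutoff: float

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def variant_ids(self) -> list[str]:
        return self.entries["variant_id"].tolist()


def _class_prob_table(draws: PosteriorDraws, X: np.ndarray, average: bool) -> np.ndarray:
    J1 = draws.theta.shape[2]
    if average:
        flat = draws.stacked()
        probs = np.zeros((X.shape[0], J1 + 1))
        for row in flat:
            probs += np.exp(log_class_prob_matrix(row[:J1], row[J1:], X))
        return probs / flat.shape[0]
    pm = draws.posterior_mean()
    return np.exp(log_class_prob_matrix(pm.theta, pm.beta, X))


def prioritize_vus(
    ds: Dataset,
    draws: PosteriorDraws,
    threshold: float = 0.99,
    direction: str = "pathogenic",
    vus_class: int = 3,
    average_probs: bool = False,
) -> PriorityList:
    """Select class-3 variants with extreme-class probability >= threshold.

    ``direction="pathogenic"`` filters on the probability of the highest
    class, ``"benign"`` on the lowest.  Probabilities are evaluated at the
    posterior-mean parameters (``average_probs=True`` switches to posterior-
    averaged probabilities).  Entries are sorted by that probability, then by
    score, both descending.
    """
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must be in (0.5, 1)")
    if direction not in ("pathogenic", "benign"):
        raise ValueError("direction must be 'pathogenic' or 'benign'")
    J = ds.n_classes
    mask = ds.classes == vus_class
    if not np.any(mask):
        logger.warning("no class-%d records to prioritize", vus_class)
    sub = [r for r, m in zip(ds.records, mask) if m]
    X = np.array([r.score for r in sub], dtype=float)[:, None]
    probs = (
        _class_prob_table(draws, X, average_probs) if sub else np.zeros((0, J))
    )
    target_col = J - 1 if direction == "pathogenic" else 0
    keep = probs[:, target_col] >= threshold if sub else np.zeros(0, bool)

    pm = draws.posterior_mean()
    beta = float(pm.beta[0])
    if beta > 0:
        if direction == "pathogenic":
            cutoff = (pm.theta[-1] - logit(1 - threshold)) / beta
        else:
            cutoff = (pm.theta[0] - logit(threshold)) / beta
    else:
        cutoff = np.nan
        logger.warning("non-positive fitted beta: no unique score cutoff exists")

    rows = {
        "variant_id": [r.variant_id for r, k in zip(sub, keep) if k],
        "gene": [r.gene for r, k in zip(sub, keep) if k],
        "score": [r.score for r, k in zip(sub, keep) if k],
    }
    kept_probs = probs[keep] if sub else probs
    for j in range(J):
        rows[f"p_class{j + 1}"] = kept_probs[:, j]
    entries = pd.DataFrame(rows)
    sort_col = f"p_class{J}" if direction == "pathogenic" else "p_class1"
    entries = entries.sort_values(
        [sort_col, "score"], ascending=[False, direction == "benign"]
    ).reset_index(drop=True)
    return PriorityList(
        entries=entries,
        threshold_probability=threshold,
        direction=direction,
        implied_score_cutoff=float(cutoff),
    )


def overlap_with_list(
    pl: PriorityList, external_ids: list[str]
) -> tuple[list[str], list[str]]:
    """Intersection and model-only difference vs an external candidate list.

    Both outputs keep the priority list's order (most confident first).
    Duplicate identifiers in either list are de-duplicated with a warning.
    """
    ours = pl.variant_ids
    if len(set(ours)) < len(ours):
        logger.warning("duplicate ids in priority list; de-duplicating")
        seen: set[str] = set()
        ours = [v for v in ours if not (v in seen or seen.add(v))]
    ext = list(external_ids)
    if len(set(ext)) < len(ext):
        logger.warning("duplicate ids in external list; de-duplicating")
    ext_set = set(ext)
    intersection = [v for v in ours if v in ext_set]
    unique_to_model = [v for v in ours if v not in ext_set]
    return intersection, unique_to_model


def score_auc(scores_pos, scores_neg) -> float:
    """Probability a random positive outscores a random negative (ties = 0.5).

    This is the Mann–Whitney U statistic divided by ``n_pos * n_neg`` —
    identically the area under the ROC curve of the score as a classifier.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))


def grouped_auc(table: pd.DataFrame, group_col: str = "gene", score_col: str = "score",
                label_col: str = "label", min_per_class: int = 1) -> pd.DataFrame:
    """Per-group AUC over a labelled score table (label truthy = positive).

    Groups lacking ``min_per_class`` positives or negatives are reported with
    AUC = NaN rather than dropped.
    """
    out = []
    for g, sub in table.groupby(group_col):
        lab = sub[label_col].astype(bool)
        pos = sub.loc[lab, score_col].to_numpy()
        neg = sub.loc[~lab, score_col].to_numpy()
        auc = (
            score_auc(pos, neg)
            if len(pos) >= min_per_class and len(neg) >= min_per_class
            else np.nan
        )
        out.append({group_col: g, "n_pos": len(pos), "n_neg": len(neg), "auc": auc})
    return pd.DataFrame(out)
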