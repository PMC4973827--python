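"""Synthetic variant datasets for testing every stage of the pipeline.

Three generators:

* :func:`emulate_insight` — reproduces the statistical structure of the
  curated mismatch-repair variant set this analysis was designed around:
  per-class record counts (151, 84, 751, 181, 1043) with Gaussian score
  distributions matched to the published per-class means and SDs.  The
  Gaussian shape is an approximation (the real class-3 distribution is much
  flatter and others are skewed), so checks built on it are tolerance-based.
* :func:`generate_from_clm` — exact sampling from the cumulative link model
  itself, for parameter-recovery experiments where the truth is known by
  construction.
* :func:`make_structural_fixture` — pathogenic (class 5) records whose
  scaled scores are anomalously low, mimicking the rank-scaling failure on
  large structural variants, each tagged with a HIGH-impact effect label so
  the second-tier override can rescue them.

One seed drives everything; each generator draws from a named substream so
modules can be tested independently yet reproducibly.  Scores are not
truncated: negative scaled scores are legal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import Dataset, VariantRecord
from .model import CLMParameters

__all__ = [
    "EmulationSpec",
    "emulate_insight",
    "generate_from_clm",
    "make_structural_fixture",
]

_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")

# published per-class structure of the curated variant set
DEFAULT_CLASS_COUNTS = (151, 84, 751, 181, 1043)
DEFAULT_CLASS_MEANS = (8.41, 11.44, 16.87, 21.41, 29.04)
DEFAULT_CLASS_SDS = (7.46, 7.72, 9.40, 6.13, 10.28)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the global seed (crc32 keys the stream)."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stream.encode())]))


@dataclass(frozen=True)
class EmulationSpec:
    """Per-class counts, score means and SDs, plus the driving seed."""

    class_counts: tuple[int, ...] = DEFAULT_CLASS_COUNTS
    class_means: tuple[float, ...] = DEFAULT_CLASS_MEANS
    class_sds: tuple[float, ...] = DEFAULT_CLASS_SDS
    seed: int = 0

    def __post_init__(self):
        if not len(self.class_counts) == len(self.class_means) == len(self.class_sds):
            raise ValueError("counts, means and sds must have equal length")
        if any(c < 0 for c in self.class_counts):
            raise ValueError("counts must be non-negative")
        if any(s <= 0 for s in self.class_sds):
            raise ValueError("sds must be positive")

    @property
    def n_classes(self) -> int:
        return len(self.class_counts)


def emulate_insight(spec: EmulationSpec | None = None) -> Dataset:
    """Draw a dataset with the published per-class counts and score moments.

    For each class ``j``, ``count_j`` scores are drawn from
    ``Normal(mean_j, sd_j)``.  Deterministic given ``spec.seed``; variant
    identifiers are synthetic (``SYN:<gene>:c.<n>``).
    """
    spec = spec or EmulationSpec()
    rng = _rng(spec.seed, "emulate_insight")
    records = []
    n = 0
    for j, (count, mean, sd) in enumerate(
        zip(spec.class_counts, spec.class_means, spec.class_sds), start=1
    ):
        scores = rng.normal(mean, sd, count)
        for s in scores:
            n += 1
            gene = _GENES[n % len(_GENES)]
            records.append(
                VariantRecord(
                    variant_id=f"SYN:{gene}:c.{n}",
                    gene=gene,
                    score=float(s),
                    expert_class=j,
                )
            )
    return Dataset(records=records, n_classes=spec.n_classes)


def generate_from_clm(params: CLMParameters, scores, seed: int) -> Dataset:
    """Sample ordinal classes from the cumulative link model at given scores.

    For each score the class is drawn from ``Categorical(pi)`` with ``pi``
    the model's class probabilities; deterministic given the seed.  The truth
    is known by construction, so round-tripping through the fitters checks
    parameter recovery.
    """
    from scipy.special import expit

    scores = np.asarray(scores, dtype=float)
    rng = _rng(seed, "generate_from_clm")
    u = rng.random(len(scores))
    # gamma_ij = P(Y_i <= j); the sampled class is the first j with u <= gamma_ij
    gamma = expit(params.theta[None, :] - scores[:, None] * params.beta[0])
    classes = 1 + np.sum(u[:, None] > gamma, axis=1)
    records = []
    for i, (s, cls) in enumerate(zip(scores, classes), start=1):
        cls = int(cls)
        gene = _GENES[i % len(_GENES)]
        records.append(
            VariantRecord(
                variant_id=f"SYN:{gene}:c.{i}",
                gene=gene,
                score=float(s),
                expert_class=cls,
            )
        )
    return Dataset(records=records, n_classes=params.n_classes)


def make_structural_fixture(
    n: int,
    seed: int,
    class_mean: float = DEFAULT_CLASS_MEANS[0],
    class_sd: float = DEFAULT_CLASS_SDS[0],
) -> Dataset:
    """Pathogenic records whose scaled scores collapsed to the benign range.

    Emulates the rank-scaling failure on large structural variants: truly
    pathogenic (class 5) records receive scores from the *lower 5% tail* of
    the benign class-1 score distribution (a truncated normal), i.e. the
    very bottom of the scaled range, which is where failed scaling reverts
    them.  All records carry a HIGH-impact effect label (mostly
    EXON_DELETED, plus FRAME_SHIFT and STOP_GAINED), so a score-trained
    model calls them benign and the second-tier override rescues them.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed, "structural_fixture")
    upper = stats.norm.ppf(0.05, loc=class_mean, scale=class_sd)
    b = (upper - class_mean) / class_sd
    scores = stats.truncnorm.rvs(-np.inf, b, loc=class_mean, scale=class_sd, size=n, random_state=rng)
    labels = ["EXON_DELETED"] * n
    if n >= 2:
        labels[-1] = "STOP_GAINED"
    if n >= 3:
        labels[-2] = "FRAME_SHIFT"
    records = [
        VariantRecord(
            variant_id=f"SYN:SV:{_GENES[i % len(_GENES)]}:c.{i + 1}del",
            gene=_GENES[i % len(_GENES)],
            score=float(s),
            expert_class=5,
            impact="HIGH",
            effect_label=lab,
        )
        for i, (s, lab) in enumerate(zip(scores, labels))
    ]
    return Dataset(records=records, n_classes=5)


def concat(*datasets: Dataset) -> Dataset:
    """Concatenate datasets (shared ``n_classes`` required)."""
    J = {d.n_classes for d in datasets}
    if len(J) != 1:
        raise ValueError("datasets disagree on the number of classes")
    out = Dataset(n_classes=J.pop())
    for d in datasets:
        out.records.extend(d.records)
        out.exclusion_log.extend(d.exclusion_log)
    return out
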