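"""Reading, validating and filtering variant tables.

The canonical interchange format is a tab-separated table with columns
``variant_id, gene, score, expert_class, impact, effect_label`` ("." or empty
marks a missing value).  VCF input is supported read-only: the scaled
deleteriousness score is taken from a configurable INFO key and the effect
impact from the third pipe-delimited subfield of each ``ANN`` entry (SnpEff
convention), taking the maximum impact across entries.

Rows that cannot enter the analysis (missing score, class outside ``1..J``,
ambiguous IUPAC alleles, duplicate identifiers) are never silently dropped:
each exclusion is recorded as a ``(variant_id, reason)`` pair on the dataset.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ranking of SnpEff effect impacts, least to most severe.
IMPACT_LEVELS = ("MODIFIER", "LOW", "MODERATE", "HIGH")

TSV_COLUMNS = ("variant_id", "gene", "score", "expert_class", "impact", "effect_label")

_AMBIGUOUS_BASES = set("RYSWKMBDHVN")
# trailing alt allele of an HGVS-style substitution, e.g. "c.1254T>R"
_HGVS_SUB = re.compile(r">([A-Za-z]+)$")


@dataclass
class VariantRecord:
    """One variant: identifier, scaled score, expert class, optional annotation.

    ``expert_class`` follows the IARC five-tier numbering (1 = not pathogenic
    ... 5 = pathogenic); ``None`` marks an unclassified variant.  ``impact`` is
    the SnpEff-style effect impact (one of :data:`IMPACT_LEVELS`) or ``None``.
    """

    variant_id: str
    score: float
    gene: str | None = None
    expert_class: int | None = None
    impact: str | None = None
    effect_label: str | None = None


@dataclass
class Dataset:
    """An ordered collection of variants plus the log of excluded input rows."""

    records: list[VariantRecord] = field(default_factory=list)
    n_classes: int = 5
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    @property
    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self.records], dtype=float)

    @property
    def classes(self) -> np.ndarray:
        """Expert classes as an integer array; missing encoded as -1."""
        return np.array(
            [r.expert_class if r.expert_class is not None else -1 for r in self.records],
            dtype=int,
        )

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def class_counts(self) -> np.ndarray:
        """Count of records per expert class, indexed ``0..J-1`` for classes ``1..J``."""
        counts = np.zeros(self.n_classes, dtype=int)
        for r in self.records:
            if r.expert_class is not None:
                counts[r.expert_class - 1] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [r.variant_id for r in self.records],
                "gene": [r.gene for r in self.records],
                "score": [r.score for r in self.records],
                "expert_class": [r.expert_class for r in self.records],
                "impact": [r.impact for r in self.records],
                "effect_label": [r.effect_label for r in self.records],
            }
        )


def _is_ambiguous_allele(variant_id: str) -> bool:
    m = _HGVS_SUB.search(variant_id)
    if m is None:
        return False
    alt = m.group(1).upper()
    return any(b in _AMBIGUOUS_BASES for b in alt)


def _clean(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in {"", "."} else s


def _validate_row(
    variant_id: str | None,
    score,
    expert_class,
    n_classes: int,
    seen: set[str],
) -> tuple[VariantRecord | None, str | None]:
    """Validate one raw row; return (record, None) or (None, exclusion reason)."""
    if not variant_id:
        return None, "missing variant_id"
    if variant_id in seen:
        return None, "duplicate id"
    if _is_ambiguous_allele(variant_id):
        return None, "ambiguous allele"
    try:
        score_f = float(score)
    except (TypeError, ValueError):
        return None, "missing score"
    if not np.isfinite(score_f):
        return None, "missing score"
    cls: int | None
    if expert_class is None:
        cls = None
    else:
        try:
            cls_f = float(expert_class)
        except (TypeError, ValueError):
            return None, "unparseable class"
        if cls_f != int(cls_f):
            return None, "unparseable class"
        cls = int(cls_f)
        if not 1 <= cls <= n_classes:
            return None, "class out of range"
    return VariantRecord(variant_id=variant_id, score=score_f, expert_class=cls), None


def read_variant_table(
    path: str | Path,
    format: str = "tsv",
    n_classes: int = 5,
    score_key: str = "CADD_SCALED",
    class_key: str = "EXPERT_CLASS",
) -> Dataset:
    """Read a variant table from TSV or VCF into a :class:`Dataset`.

    Parameters
    ----------
    path
        Input file. Must exist.
    format
        ``"tsv"`` (canonical) or ``"vcf"``.
    score_key, class_key
        INFO keys holding the scaled score and the (optional) expert class
        when reading VCF; ignored for TSV.

    Every input row is either parsed into a record or logged with a reason;
    ``len(records) + len(exclusion_log)`` always equals the row count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"variant table not found: {path}")
    if format == "tsv":
        return _read_tsv(path, n_classes)
    if format == "vcf":
        return _read_vcf(path, n_classes, score_key, class_key)
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'vcf')")


def _read_tsv(path: Path, n_classes: int) -> Dataset:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    missing = {"variant_id", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"mandatory columns missing from {path}: {sorted(missing)}")
    ds = Dataset(n_classes=n_classes)
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        vid = _clean(getattr(row, "variant_id", None))
        rec, reason = _validate_row(
            vid,
            _clean(getattr(row, "score", None)),
            _clean(getattr(row, "expert_class", None)),
            n_classes,
            seen,
        )
        if rec is None:
            ds.exclusion_log.append((vid or "<no id>", reason))
            continue
        rec.gene = _clean(getattr(row, "gene", None))
        impact = _clean(getattr(row, "impact", None))
        if impact is not None and impact not in IMPACT_LEVELS:
            ds.exclusion_log.append((rec.variant_id, "unknown impact"))
            continue
        rec.impact = impact
        rec.effect_label = _clean(getattr(row, "effect_label", None))
        if rec.gene is None and ":" in rec.variant_id:
            rec.gene = rec.variant_id.split(":", 1)[0]
        seen.add(rec.variant_id)
        ds.records.append(rec)
    return ds


def _max_impact(ann_value: str) -> tuple[str | None, str | None]:
    """Extract (max impact, its effect label) from a SnpEff ANN INFO value."""
    best = None
    best_label = None
    for entry in ann_value.split(","):
        fields = entry.split("|")
        if len(fields) < 3:
            continue
        impact = fields[2].strip().upper()
        if impact not in IMPACT_LEVELS:
            continue
        if best is None or IMPACT_LEVELS.index(impact) > IMPACT_LEVELS.index(best):
            best = impact
            best_label = fields[1].strip() or None
    return best, best_label


def _read_vcf(path: Path, n_classes: int, score_key: str, class_key: str) -> Dataset:
    from cyvcf2 import VCF

    ds = Dataset(n_classes=n_classes)
    seen: set[str] = set()
    vcf = VCF(str(path))
    for v in vcf:
        alts = v.ALT or [None]
        if len(alts) > 1:
            # The study's pipeline never stated a multi-allelic policy; we
            # decompose to one record per alt allele and log the divergence.
            logger.info("decomposed multi-allelic record at %s:%s", v.CHROM, v.POS)
        for i, alt in enumerate(alts):
            vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}>{alt}"
            if len(alts) > 1:
                vid = f"{vid}#{i + 1}"
            if alt is None or any(b in _AMBIGUOUS_BASES for b in str(alt).upper()):
                ds.exclusion_log.append((vid, "ambiguous allele"))
                continue
            score = v.INFO.get(score_key)
            if isinstance(score, tuple):
                score = score[i] if i < len(score) else None
            cls = v.INFO.get(class_key)
            if isinstance(cls, tuple):
                cls = cls[i] if i < len(cls) else None
            rec, reason = _validate_row(vid, score, cls, n_classes, seen)
            if rec is None:
                ds.exclusion_log.append((vid, reason))
                continue
            ann = v.INFO.get("ANN")
            if ann is not None:
                rec.impact, rec.effect_label = _max_impact(str(ann))
            gene = v.INFO.get("GENE")
            rec.gene = str(gene) if gene is not None else None
            seen.add(rec.variant_id)
            ds.records.append(rec)
    return ds


def write_variant_table(ds: Dataset, path: str | Path) -> None:
    """Write the canonical TSV; ``.`` marks missing values.

    Scores are written with :func:`repr` so that a read/write cycle
    round-trips bit-identically.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in ds.records:
            fields = [
                r.variant_id,
                r.gene if r.gene is not None else ".",
                repr(r.score),
                str(r.expert_class) if r.expert_class is not None else ".",
                r.impact if r.impact is not None else ".",
                r.effect_label if r.effect_label is not None else ".",
            ]
            fh.write("\t".join(fields) + "\n")


def fit_subset(ds: Dataset) -> Dataset:
    """Restrict a dataset to records usable for model fitting.

    Keeps records with a non-missing expert class and a finite score; the
    per-class counts of the result are reported through the module logger.
    A warning is emitted when fewer than ``n_classes`` classes are observed
    (the model still fits, but some cut-offs are data-starved).
    """
    kept = [
        r
        for r in ds.records
        if r.expert_class is not None and np.isfinite(r.score)
    ]
    out = Dataset(records=[replace(r) for r in kept], n_classes=ds.n_classes)
    counts = out.class_counts()
    logger.info(
        "fit subset: %d of %d records; per-class counts %s",
        len(out),
        len(ds),
        counts.tolist(),
    )
    if len(out) == 0:
        logger.warning("fit subset is empty")
    elif np.count_nonzero(counts) < ds.n_classes:
        logger.warning(
            "only %d of %d classes observed; unobserved cut-offs are prior-driven",
            np.count_nonzero(counts),
            ds.n_classes,
        )
    return out
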