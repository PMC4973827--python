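"""Second-tier impact override.

A PHRED-like scaled deleteriousness score systematically fails on large
structural variants: their raw scores are extreme, but the rank-based scaling
reverts them to very low scaled scores, so the score-driven model calls
truly pathogenic variants benign.  A qualitative effect annotation
(EXON_DELETED, STOP_GAINED, FRAME_SHIFT, ... — HIGH impact in the SnpEff
vocabulary) catches exactly these cases.  The override promotes any variant
the model placed in a benign class (default: class 1 or 2) that carries a
HIGH impact annotation to the pathogenic class (default: 5).  It never
demotes and is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discrepancy import ReassignmentReport
from .io import Dataset

__all__ = ["OverrideResult", "apply_override"]


@dataclass
class OverrideResult:
    """Per-variant override outcome plus candidate/override counts."""

    table: pd.DataFrame  # variant_id, model_class, impact, overridden, final_class
    n_candidates: int  # model class <= cutoff, any impact status
    n_overridden: int
    n_missing_impact: int  # candidates with no impact annotation (untouched)

    @property
    def overridden_ids(self) -> list[str]:
        return self.table.loc[self.table["overridden"], "variant_id"].tolist()


def apply_override(
    report: ReassignmentReport,
    ds: Dataset,
    low_class_cutoff: int = 2,
    override_class: int = 5,
) -> OverrideResult:
    """Promote HIGH-impact variants out of model-assigned benign classes.

    A variant is overridden iff its model class is at most
    ``low_class_cutoff`` and its impact annotation is HIGH; its final class
    becomes ``override_class``.  Variants without an impact annotation are
    left untouched and counted separately.
    """
    if override_class <= low_class_cutoff:
        raise ValueError("override_class must exceed low_class_cutoff")
    impact = {r.variant_id: r.impact for r in ds.records}
    a = report.assignments
    model_class = a["model_class"].to_numpy()
    imp = np.array([impact.get(v) for v in a["variant_id"]], dtype=object)
    candidate = model_class <= low_class_cutoff
    overridden = candidate & (imp == "HIGH")
    final = np.where(overridden, override_class, model_class)
    table = pd.DataFrame(
        {
            "variant_id": a["variant_id"],
            "model_class": model_class,
            "impact": [i if i is not None else "." for i in imp],
            "overridden": overridden,
            "final_class": final,
        }
    )
    return OverrideResult(
        table=table,
        n_candidates=int(candidate.sum()),
        n_overridden=int(overridden.sum()),
        n_missing_impact=int((candidate & (imp == None)).sum()),  # noqa: E711
    )
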