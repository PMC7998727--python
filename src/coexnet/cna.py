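"""GISTIC copy-number prevalence tables and expression-by-category summaries.

Discrete per-patient calls (-2 deep deletion, -1 shallow deletion, 0
diploid, +1 gain, +2 amplification) are tabulated into per-cancer-type
percentage rows plus a pooled row, then summarised the way a pan-cancer
prevalence table is read: how many types show more amplifications than deep
deletions, which type has the highest amplification percentage, and how the
mean expression orders across categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GISTIC_CATEGORIES, GISTIC_LABELS, CnaCohort

__all__ = [
    "PrevalenceTable",
    "filter_paired",
    "prevalence",
    "summarize_prevalence",
    "expression_by_category",
]

OVERALL = "All Cancer types"
CATEGORY_COLUMNS = [GISTIC_LABELS[g] for g in GISTIC_CATEGORIES]


@dataclass
class PrevalenceTable:
    """Per-cancer-type percentage of patients in each GISTIC category.

    ``rows`` is indexed by cancer type with one column per category plus
    ``n_patients``; ``overall`` is the pooled row. Percentages per row sum
    to 100 up to rounding.
    """

    rows: pd.DataFrame
    overall: pd.Series


def filter_paired(cohort: CnaCohort) -> CnaCohort:
    """Keep patients with both a GISTIC call and RNA-seq expression."""
    kept = cohort.records[cohort.records["has_rna"]].reset_index(drop=True)
    return CnaCohort(kept, expression_scale=cohort.expression_scale)


def prevalence(cohort: CnaCohort, round_dp: int = 2) -> PrevalenceTable:
    """Percentage of patients per GISTIC category, by cancer type and pooled."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")

    def _row(grp: pd.DataFrame) -> pd.Series:
        n = len(grp)
        pct = {
            GISTIC_LABELS[g]: round(100.0 * (grp["gistic"] == g).sum() / n, round_dp)
            for g in GISTIC_CATEGORIES
        }
        pct["n_patients"] = n
        return pd.Series(pct)

    rows = (
        cohort.records.groupby("cancer_type", sort=True)
        .apply(_row, include_groups=False)
        .astype({"n_patients": int})
    )
    overall = _row(cohort.records).astype(object)
    overall["n_patients"] = int(overall["n_patients"])
    return PrevalenceTable(rows=rows, overall=overall)


def prevalence_from_percent_frame(frame: pd.DataFrame, overall_label: str = OVERALL) -> PrevalenceTable:
    """Build a PrevalenceTable from an already-tabulated percentage frame.

    Used to summarise published prevalence tables directly; absent cells
    (printed as dashes) must already be 0.0. ``n_patients`` is unknown and
    set to -1.
    """
    frame = frame.copy()
    overall = None
    if overall_label in frame.index:
        overall = frame.loc[overall_label].copy()
        frame = frame.drop(index=overall_label)
    frame["n_patients"] = -1
    if overall is None:
        overall = frame[CATEGORY_COLUMNS].mean()
    overall = overall.astype(object)
    overall["n_patients"] = -1
    return PrevalenceTable(rows=frame, overall=overall)


def summarize_prevalence(table: PrevalenceTable) -> dict:
    """Headline numbers of a prevalence table.

    * ``n_types`` — cancer types tabulated (pooled row excluded);
    * ``n_amp_gt_deepdel`` — types where the amplification percentage
      strictly exceeds the deep-deletion percentage (ties do not count;
      absent categories are 0);
    * ``max_amp_value``/``max_amp_type`` and the runner-up;
    * ``n_types_amp_gt_1pct`` — types with amplification above 1%.
    """
    rows = table.rows
    if rows.empty:
        raise ValueError("empty prevalence table")
    amp = rows["amplification"].astype(float)
    deep = rows["deep_deletion"].astype(float)
    order = amp.sort_values(ascending=False, kind="mergesort")
    out = {
        "n_types": int(len(rows)),
        "n_amp_gt_deepdel": int((amp > deep).sum()),
        "max_amp_value": float(order.iloc[0]),
        "max_amp_type": str(order.index[0]),
        "second_amp_value": float(order.iloc[1]) if len(order) > 1 else float("nan"),
        "second_amp_type": str(order.index[1]) if len(order) > 1 else "",
        "n_types_amp_gt_1pct": int((amp > 1.0).sum()),
    }
    return out


def expression_by_category(cohort: CnaCohort, log_transform: bool | None = None) -> pd.DataFrame:
    """Mean expression per GISTIC category, per cancer type and pooled.

    Expects a paired cohort (see :func:`filter_paired`). By default raw
    RSEM cohorts are summarised on the log2(x+1) scale; cohorts already on
    that scale are averaged as given. The scale used is recorded in the
    ``scale`` column. Categories with no patients are omitted.
    """
    recs = cohort.records[cohort.records["has_rna"]]
    if recs.empty:
        raise ValueError("no paired records")
    if log_transform is None:
        log_transform = cohort.expression_scale == "RSEM"
    expr = recs["expression"].astype(float)
    scale = cohort.expression_scale
    if log_transform and cohort.expression_scale == "RSEM":
        expr = np.log2(expr + 1.0)
        scale = "log2p1"
    work = pd.DataFrame(
        {"cancer_type": recs["cancer_type"], "gistic": recs["gistic"], "expr": expr}
    )
    rows = []
    groups = [(OVERALL, work)] + [
        (ct, grp) for ct, grp in work.groupby("cancer_type", sort=True)
    ]
    for label, grp in groups:
        for g in GISTIC_CATEGORIES:
            sub = grp.loc[grp["gistic"] == g, "expr"]
            if len(sub) == 0:
                continue
            rows.append(
                {
                    "cancer_type": label,
                    "category": GISTIC_LABELS[g],
                    "gistic": g,
                    "mean_expression": float(sub.mean()),
                    "n": int(len(sub)),
                    "scale": scale,
                }
            )
    return pd.DataFrame(rows)
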