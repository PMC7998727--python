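"""Cancer-vs-normal expression calls and stage trajectories.

Works on condition-level summaries (one expression value per gene, cancer
type and stage, plus a ``normal`` reference per cancer type) of the kind
distributed by phenotype-specific expression databases. No per-patient
statistics are attempted at this level.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import ValidationError

__all__ = ["CancerNormalTable", "classify_direction", "stage_trajectory"]

NORMAL = "normal"


@dataclass
class CancerNormalTable:
    """Condition-level expression records.

    ``records`` columns: gene, cancer_type, stage (``normal`` for the
    healthy reference), expression, unit. Units may differ between cancer
    types (e.g. FPKM for some studies, TPM elsewhere) but are never compared
    across types.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "cancer_type", "stage", "expression"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValidationError(f"cancer table missing columns: {sorted(missing)}")
        if (self.records["expression"] < 0).any():
            raise ValidationError("expression must be non-negative")
        if self.records.duplicated(["gene", "cancer_type", "stage"]).any():
            raise ValidationError("duplicate (gene, cancer_type, stage) records")
        if "unit" in self.records.columns:
            per_type = self.records.groupby("cancer_type")["unit"].nunique()
            mixed = per_type[per_type > 1]
            if len(mixed):
                raise ValidationError(
                    f"mixed units within cancer_type: {mixed.index.tolist()}"
                )

    def cancer_types(self):
        return sorted(self.records["cancer_type"].unique())


def classify_direction(table: CancerNormalTable, gene: str, delta: float = 0.0) -> dict:
    """Per-cancer call: ``up``, ``down`` or ``unchanged`` vs the normal stage.

    ``up`` requires every cancer stage above ``normal * (1 + delta)``;
    ``down`` every stage below ``normal * (1 - delta)``; anything else is
    ``unchanged``. The default ``delta = 0`` is the literal
    points-above-the-identity-line reading; set a margin for a fold-change
    requirement. Calls are scale-invariant within a cancer type.
    """
    recs = table.records[table.records["gene"] == gene]
    if recs.empty:
        raise KeyError(f"gene {gene!r} not in table")
    out = {}
    for ctype, grp in recs.groupby("cancer_type"):
        normal = grp.loc[grp["stage"] == NORMAL, "expression"]
        if normal.empty:
            raise ValidationError(f"{ctype}: no normal record for {gene}")
        ref = float(normal.iloc[0])
        stages = grp.loc[grp["stage"] != NORMAL, "expression"]
        if stages.empty:
            raise ValidationError(f"{ctype}: no cancer-stage record for {gene}")
        if (stages > ref * (1 + delta)).all():
            out[ctype] = "up"
        elif (stages < ref * (1 - delta)).all():
            out[ctype] = "down"
        else:
            out[ctype] = "unchanged"
    return out


def stage_trajectory(
    table: CancerNormalTable, gene: str, cancer_type: str, stage_order
) -> list:
    """Expression along ordered stages, normal first.

    Returns ``[(stage, expression), ...]`` in the requested order. Unknown
    stage labels are an error rather than silently skipped.
    """
    recs = table.records[
        (table.records["gene"] == gene) & (table.records["cancer_type"] == cancer_type)
    ]
    if recs.empty:
        raise KeyError(f"no records for gene {gene!r} in {cancer_type!r}")
    by_stage = recs.set_index("stage")["expression"]
    order = list(stage_order)
    if NORMAL not in order:
        order = [NORMAL, *order]
    missing = [s for s in order if s not in by_stage.index]
    if missing:
        raise ValidationError(f"{cancer_type}: unknown stage labels {missing}")
    return [(s, float(by_stage[s])) for s in order]
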