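"""Core domain types shared across the pipeline.

Each type is a thin, validated wrapper around a pandas container. Validation
happens at construction; downstream code can therefore assume invariants
(non-negative expression, unique identifiers, GISTIC categories in -2..2,
integer spectral counts) instead of re-checking them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "AssociationNetwork",
    "AnnotationTable",
    "CnaCohort",
    "SpectralCountSet",
    "EXPRESSION_UNITS",
    "GISTIC_CATEGORIES",
    "GISTIC_LABELS",
]

EXPRESSION_UNITS = ("TPM", "FPKM", "RPKM", "RSEM", "log2p1")
COL_KINDS = ("tissue_median", "sample")

#: GISTIC discrete copy-number calls, most deleted to most amplified.
GISTIC_CATEGORIES = (-2, -1, 0, 1, 2)
GISTIC_LABELS = {
    -2: "deep_deletion",
    -1: "shallow_deletion",
    0: "diploid",
    1: "gain",
    2: "amplification",
}


class ValidationError(ValueError):
    """Raised when an input table violates a domain-type invariant."""


@dataclass
class ExpressionMatrix:
    """Expression values over tissues or samples.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are transcripts/genes, columns are tissues (``tissue_median``)
        or individual samples (``sample``). Row and column labels must be
        unique.
    unit : str
        One of ``TPM``, ``FPKM``, ``RPKM``, ``RSEM`` or ``log2p1``. Units are
        carried as metadata only; transforms are explicit operations.
    col_kind : str
        ``tissue_median`` for per-tissue summaries (a GTEx-style median
        matrix) or ``sample`` for per-sample matrices (CCLE/TCGA style).
    """

    values: pd.DataFrame
    unit: str = "TPM"
    col_kind: str = "tissue_median"

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise ValidationError(f"unknown expression unit {self.unit!r}")
        if self.col_kind not in COL_KINDS:
            raise ValidationError(f"unknown col_kind {self.col_kind!r}")
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate row ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate column ids")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValidationError("expression values must be finite (NaN = missing)")
        if self.unit != "log2p1" and np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError(f"negative values not allowed for unit {self.unit}")

    @property
    def row_ids(self) -> pd.Index:
        return self.values.index

    @property
    def col_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.unit == other.unit
            and self.col_kind == other.col_kind
            and self.values.equals(other.values)
        )


@dataclass
class AssociationNetwork:
    """Undirected protein-association network with per-edge confidence.

    Edges are stored canonically (``a < b`` lexicographically), scores lie in
    ``[0, 1]``. The ``channel`` marks whether an edge comes from the
    co-expression evidence channel or any other evidence type.
    """

    edges: pd.DataFrame  # columns: protein_a, protein_b, score, channel
    nodes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        required = {"protein_a", "protein_b", "score", "channel"}
        missing = required - set(self.edges.columns)
        if missing:
            raise ValidationError(f"edge table missing columns: {sorted(missing)}")
        e = self.edges
        if (e["protein_a"] == e["protein_b"]).any():
            raise ValidationError("self-edges are not allowed")
        if ((e["score"] < 0) | (e["score"] > 1)).any():
            raise ValidationError("edge scores must lie in [0, 1]")
        swapped = e["protein_a"] > e["protein_b"]
        if swapped.any():
            e = e.copy()
            a = e.loc[swapped, "protein_a"].copy()
            e.loc[swapped, "protein_a"] = e.loc[swapped, "protein_b"]
            e.loc[swapped, "protein_b"] = a
            self.edges = e
        pairs = list(zip(e["protein_a"], e["protein_b"]))
        if len(pairs) != len(set(pairs)):
            raise ValidationError("duplicate undirected edges")
        if not self.nodes:
            self.nodes = frozenset(e["protein_a"]) | frozenset(e["protein_b"])

    def neighbors(self, node: str, channel: str | None = "coexpression") -> pd.DataFrame:
        """Partners of ``node`` with scores, best score first, ties by id."""
        e = self.edges
        if channel is not None:
            e = e[e["channel"] == channel]
        fwd = e[e["protein_a"] == node][["protein_b", "score"]].rename(
            columns={"protein_b": "partner"}
        )
        rev = e[e["protein_b"] == node][["protein_a", "score"]].rename(
            columns={"protein_a": "partner"}
        )
        out = pd.concat([fwd, rev], ignore_index=True)
        return out.sort_values(
            ["score", "partner"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)

    def degree(self, node: str, channel: str | None = "coexpression") -> int:
        return len(self.neighbors(node, channel=channel))

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class AnnotationTable:
    """Flat gene -> term annotations (no ontology DAG propagation)."""

    term_to_genes: dict
    term_names: dict = field(default_factory=dict)
    namespace: str = "custom"

    def __post_init__(self) -> None:
        if self.namespace not in ("process", "function", "component", "custom"):
            raise ValidationError(f"unknown namespace {self.namespace!r}")
        clean = {}
        for term, genes in self.term_to_genes.items():
            if not str(term):
                raise ValidationError("empty term id")
            gset = frozenset(genes)
            if not gset:
                raise ValidationError(f"term {term!r} annotates no genes")
            clean[str(term)] = gset
        self.term_to_genes = clean

    def terms(self):
        return self.term_to_genes.keys()

    def name(self, term: str) -> str:
        return self.term_names.get(term, term)


@dataclass
class CnaCohort:
    """Per-patient GISTIC copy-number calls with optional RSEM expression.

    ``records`` columns: patient, cancer_type, gistic, expression (NaN when
    the patient lacks RNA-seq), has_rna. ``expression_scale`` records whether
    expression is raw RSEM or already log2(x+1).
    """

    records: pd.DataFrame
    expression_scale: str = "RSEM"  # "RSEM" or "log2p1"

    def __post_init__(self) -> None:
        required = {"patient", "cancer_type", "gistic", "expression"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValidationError(f"CNA table missing columns: {sorted(missing)}")
        r = self.records
        bad = ~r["gistic"].isin(GISTIC_CATEGORIES)
        if bad.any():
            raise ValidationError(
                f"GISTIC categories must lie in -2..2; offending values: "
                f"{sorted(r.loc[bad, 'gistic'].unique().tolist())[:5]}"
            )
        expr = r["expression"]
        if (expr.dropna() < 0).any():
            raise ValidationError("expression must be non-negative")
        if r.duplicated(["patient", "cancer_type"]).any():
            raise ValidationError("duplicate patient within cancer_type")
        if "has_rna" not in r.columns:
            r = r.copy()
            r["has_rna"] = expr.notna()
            self.records = r

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SpectralCountSet:
    """Protein x run spectral counts with run and protein metadata.

    ``counts`` holds non-negative integers (one column per MS run);
    ``run_info`` maps each run to its condition (``bait``/``control``) and
    experiment set; ``species`` tags each protein row.
    """

    counts: pd.DataFrame
    run_info: pd.DataFrame  # index: run id; columns: condition, experiment_set
    species: pd.Series  # index: protein id
    bait_id: str | None = None

    def __post_init__(self) -> None:
        c = self.counts
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            asfloat = c.to_numpy(dtype=float)
            if not np.allclose(asfloat, np.round(asfloat)):
                raise ValidationError("spectral counts must be integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("spectral counts must be non-negative")
        missing_runs = [r for r in c.columns if r not in self.run_info.index]
        if missing_runs:
            raise ValidationError(f"runs without metadata: {missing_runs}")
        for col in ("condition", "experiment_set"):
            if col not in self.run_info.columns:
                raise ValidationError(f"run metadata missing column {col!r}")
        bad_cond = set(self.run_info["condition"]) - {"bait", "control"}
        if bad_cond:
            raise ValidationError(f"unknown conditions: {sorted(bad_cond)}")
        missing_species = [p for p in c.index if p not in self.species.index]
        if missing_species:
            raise ValidationError(f"proteins without species tag: {missing_species[:5]}")

    @property
    def runs(self) -> pd.Index:
        return self.counts.columns

    @property
    def proteins(self) -> pd.Index:
        return self.counts.index

    def condition_of(self, run: str) -> str:
        return self.run_info.loc[run, "condition"]
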