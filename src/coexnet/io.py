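"""Readers and writers for every external table the pipeline touches.

Conventions: tab-separated UTF-8, ``NA`` for missing values (matching
cBioPortal/GTEx exports). Expression matrices additionally round-trip
through GCT 1.2. STRING-style edge lists may carry integer scores in
0..1000, which are rescaled to [0, 1] on read.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationTable,
    AssociationNetwork,
    CnaCohort,
    ExpressionMatrix,
    SpectralCountSet,
    ValidationError,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_network",
    "write_network",
    "read_annotation",
    "write_annotation",
    "read_cna_table",
    "write_cna_table",
    "read_spectral_counts",
    "write_spectral_counts",
    "load_table2_fixture",
    "load_table3_fixture",
    "load_table5_panel",
    "fixture_path",
]

_NA = "NA"


def _fmt(v: float) -> str:
    """Minimal decimal representation; round-trips through float exactly."""
    if np.isnan(v):
        return _NA
    return np.format_float_positional(v, trim="-", unique=True)


# ---------------------------------------------------------------------------
# Expression matrices (TSV and GCT 1.2)


def read_expression_matrix(
    path, unit: str = "TPM", col_kind: str = "tissue_median"
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT 1.2.

    The format is sniffed from the first line: files opening with ``#1.2``
    are parsed as GCT, anything else as header + row-id TSV. Duplicate row
    ids are an error, never silently merged.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        return _read_gct(path, unit=unit, col_kind=col_kind)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA])
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise ValidationError(f"malformed expression TSV {path}: {exc}") from exc
    if df.columns.size == 0:
        raise ValidationError(f"expression TSV {path} has no data columns")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric expression values in {path}: {exc}") from exc
    return ExpressionMatrix(df, unit=unit, col_kind=col_kind)


def _read_gct(path: Path, unit: str, col_kind: str) -> ExpressionMatrix:
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().rstrip("\n")
        if not version.startswith("#1.2"):
            raise ValidationError(f"{path}: not a GCT 1.2 file")
        dims = fh.readline().split("\t")
        if len(dims) < 2:
            raise ValidationError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if "Description" in df.columns:
        df = df.drop(columns=["Description"])
    if df.shape != (n_rows, n_cols):
        raise ValidationError(
            f"{path}: GCT dimension line says {n_rows}x{n_cols}, data is {df.shape}"
        )
    return ExpressionMatrix(df.astype(float), unit=unit, col_kind=col_kind)


def write_expression_matrix(matrix: ExpressionMatrix, path, format: str = "tsv") -> None:
    """Write a matrix as TSV (default) or GCT 1.2. Exact read round-trip."""
    path = Path(path)
    idx_name = matrix.values.index.name or "id"
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join([idx_name, *map(str, matrix.col_ids)]) + "\n")
            for rid, row in zip(matrix.row_ids, matrix.values.to_numpy()):
                fh.write("\t".join([str(rid), *map(_fmt, row)]) + "\n")
    elif format == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            fh.write("\t".join(["Name", "Description", *map(str, matrix.col_ids)]) + "\n")
            for rid, row in zip(matrix.row_ids, matrix.values.to_numpy()):
                fh.write("\t".join([str(rid), "na", *map(_fmt, row)]) + "\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# Association networks (STRING detailed-links dialect)


def read_network(path, min_score: float = 0.400) -> AssociationNetwork:
    """Read a STRING-style edge list, filter by confidence.

    Scores given as integers 0..1000 (STRING's convention) are divided by
    1000. Edges below ``min_score`` are dropped; duplicate undirected pairs
    collapse keeping the maximum score. The default 0.400 is STRING's
    documented "medium confidence" cutoff. An optional ``channel`` column
    defaults to ``coexpression``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    if df.empty:
        empty = pd.DataFrame(columns=["protein_a", "protein_b", "score", "channel"])
        return AssociationNetwork(empty)
    score_col = "coexpression_score" if "coexpression_score" in df.columns else "score"
    if score_col not in df.columns:
        raise ValidationError(f"{path}: no coexpression_score/score column")
    scores = df[score_col].astype(float)
    # STRING detailed links print integer scores in 0..1000
    if (scores > 1).any():
        scores = scores / 1000.0
    if ((scores < 0) | (scores > 1)).any():
        raise ValidationError(f"{path}: scores outside [0, 1] after scaling")
    out = pd.DataFrame(
        {
            "protein_a": df["protein_a"].astype(str),
            "protein_b": df["protein_b"].astype(str),
            "score": scores,
            "channel": df.get("channel", "coexpression"),
        }
    )
    out = out[out["score"] >= min_score].copy()
    # canonical undirected ordering, then collapse duplicates keeping max score
    a = out[["protein_a", "protein_b"]].min(axis=1)
    b = out[["protein_a", "protein_b"]].max(axis=1)
    out["protein_a"], out["protein_b"] = a, b
    out = (
        out.groupby(["protein_a", "protein_b", "channel"], as_index=False)["score"]
        .max()[["protein_a", "protein_b", "score", "channel"]]
        .sort_values(["protein_a", "protein_b"], kind="mergesort")
        .reset_index(drop=True)
    )
    return AssociationNetwork(out)


def write_network(network: AssociationNetwork, path) -> None:
    """Canonical TSV; ``read_network`` on the output is the identity."""
    e = network.edges.sort_values(["protein_a", "protein_b"], kind="mergesort")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tcoexpression_score\tchannel\n")
        for row in e.itertuples(index=False):
            fh.write(f"{row.protein_a}\t{row.protein_b}\t{_fmt(row.score)}\t{row.channel}\n")


# ---------------------------------------------------------------------------
# Annotations (2-column TSV or GMT)


def read_annotation(path, format: str = "two_column", namespace: str = "custom") -> AnnotationTable:
    """Read gene->term annotations.

    ``two_column``: tab-separated (gene, term) pairs, optional header line
    ``gene\tterm``. ``gmt``: term, description, then member genes.
    """
    term_to_genes: dict[str, set] = {}
    term_names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        if format == "two_column":
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValidationError(f"{path}:{i + 1}: expected 2 columns")
                gene, term = parts
                if i == 0 and (gene, term) == ("gene", "term"):
                    continue
                if not term:
                    raise ValidationError(f"{path}:{i + 1}: empty term id")
                term_to_genes.setdefault(term, set()).add(gene)
        elif format == "gmt":
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValidationError(f"{path}:{i + 1}: GMT line needs term, desc, genes")
                term, desc, *genes = parts
                if not term:
                    raise ValidationError(f"{path}:{i + 1}: empty term id")
                term_to_genes.setdefault(term, set()).update(g for g in genes if g)
                term_names[term] = desc
        else:
            raise ValueError(f"unknown annotation format {format!r}")
    return AnnotationTable(term_to_genes, term_names, namespace=namespace)


def write_annotation(table: AnnotationTable, path, format: str = "gmt") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(table.terms()):
            genes = sorted(table.term_to_genes[term])
            if format == "gmt":
                fh.write("\t".join([term, table.name(term), *genes]) + "\n")
            elif format == "two_column":
                for g in genes:
                    fh.write(f"{g}\t{term}\n")
            else:
                raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# CNA cohorts


def read_cna_table(path, expression_scale: str = "RSEM") -> CnaCohort:
    """Read a cBioPortal-style patient-level CNA table.

    Columns: patient, cancer_type, gistic, expression (``NA`` when the
    patient lacks RNA-seq). ``has_rna`` is derived, never trusted from file.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        na_values=[_NA],
        dtype={"patient": str, "cancer_type": str},
    )
    required = {"patient", "cancer_type", "gistic", "expression"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    gist = df["gistic"].astype(float)
    if not np.allclose(gist, np.round(gist)):
        raise ValidationError(f"{path}: non-integer GISTIC categories")
    df["gistic"] = gist.astype(int)
    df["expression"] = df["expression"].astype(float)
    df["has_rna"] = df["expression"].notna()
    return CnaCohort(df.reset_index(drop=True), expression_scale=expression_scale)


def write_cna_table(cohort: CnaCohort, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient\tcancer_type\tgistic\texpression\n")
        for row in cohort.records.itertuples(index=False):
            fh.write(f"{row.patient}\t{row.cancer_type}\t{row.gistic}\t{_fmt(row.expression)}\n")


# ---------------------------------------------------------------------------
# Spectral counts


def read_spectral_counts(counts_path, runs_path, bait_id: str | None = None) -> SpectralCountSet:
    """Read a protein x run count table plus its run-metadata sidecar.

    ``counts_path``: columns ``protein``, ``species``, then one integer
    column per run. ``runs_path``: columns ``run``, ``condition``,
    ``experiment_set``. Every count column must have a metadata row.
    """
    df = pd.read_csv(counts_path, sep="\t", dtype={"protein": str, "species": str})
    for col in ("protein", "species"):
        if col not in df.columns:
            raise ValidationError(f"{counts_path}: missing column {col!r}")
    if df["protein"].duplicated().any():
        raise ValidationError(f"{counts_path}: duplicate protein ids")
    df = df.set_index("protein")
    species = df.pop("species")
    vals = df.to_numpy(dtype=float)
    if not np.allclose(vals, np.round(vals)):
        raise ValidationError(f"{counts_path}: spectral counts must be integers")
    counts = df.astype(np.int64)

    runs = pd.read_csv(runs_path, sep="\t", dtype=str)
    for col in ("run", "condition", "experiment_set"):
        if col not in runs.columns:
            raise ValidationError(f"{runs_path}: missing column {col!r}")
    runs = runs.set_index("run")
    missing = [r for r in counts.columns if r not in runs.index]
    if missing:
        raise ValidationError(f"runs missing from metadata {runs_path}: {missing}")
    return SpectralCountSet(counts, runs.loc[list(counts.columns)], species, bait_id=bait_id)


def write_spectral_counts(scs: SpectralCountSet, counts_path, runs_path) -> None:
    with open(counts_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["protein", "species", *map(str, scs.runs)]) + "\n")
        for pid in scs.proteins:
            row = scs.counts.loc[pid]
            fh.write("\t".join([str(pid), str(scs.species.loc[pid]), *map(str, row.tolist())]) + "\n")
    with open(runs_path, "w", encoding="utf-8") as fh:
        fh.write("run\tcondition\texperiment_set\n")
        for run in scs.runs:
            info = scs.run_info.loc[run]
            fh.write(f"{run}\t{info['condition']}\t{info['experiment_set']}\n")


# ---------------------------------------------------------------------------
# Packaged fixtures


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture TSV."""
    return Path(importlib.resources.files("coexnet") / "fixtures" / name)


def load_table2_fixture() -> ExpressionMatrix:
    """The 53-tissue median-TPM matrix for the four RNase H genes."""
    return read_expression_matrix(
        fixture_path("table2_gtex_medians.tsv"), unit="TPM", col_kind="tissue_median"
    )


def load_table3_fixture(numeric: bool = True) -> pd.DataFrame:
    """Pan-cancer CNA prevalence percentages per GISTIC category.

    With ``numeric=True``, ``x%`` strings become floats and dashes (printed
    for categories with no patients) become 0.0. With ``numeric=False`` the
    verbatim string table is returned, re-serializable byte-for-byte.
    """
    raw = pd.read_csv(
        fixture_path("table3_cna_prevalence.tsv"),
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    if not numeric:
        return raw
    return raw.apply(lambda col: col.map(lambda v: 0.0 if v == "-" else float(v.rstrip("%"))))


def load_table5_panel() -> pd.DataFrame:
    """The 40-gene correlation panel (query + 39 genes) with role labels."""
    return pd.read_csv(fixture_path("table5_panel.tsv"), sep="\t", dtype=str)
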