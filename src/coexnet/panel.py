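"""Query-vs-panel correlation across cancer samples, with clustering.

A configured gene panel (cell-cycle phases, genes up/down-regulated in
cancer, proliferative markers, the RNase H genes, predicted binding
partners) is correlated pairwise across samples on the log2(x+1) scale;
average-linkage hierarchical clustering on 1 - R orders the genes for
heatmap display, and a per-gene report gives each panel member's
correlation with the query within its role group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

from .datatypes import ExpressionMatrix, ValidationError
from .enrichment import bh_adjust

__all__ = ["PanelCorrelation", "panel_correlate", "cluster_order", "panel_report"]


@dataclass
class PanelCorrelation:
    """Pairwise Pearson R over a gene panel.

    ``r_matrix``/``p_matrix``/``n_matrix`` are symmetric gene x gene frames;
    p-values come from the t transform of R with n - 2 df on the pairwise-
    complete sample count, and are 1 on the diagonal. ``genes`` holds the
    display order (set by :func:`cluster_order`), ``linkage`` the merge tree.
    """

    r_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    n_matrix: pd.DataFrame
    genes: list
    linkage: np.ndarray | None = None


def panel_correlate(matrix: ExpressionMatrix, panel) -> PanelCorrelation:
    """Pairwise Pearson correlation of panel genes across samples.

    ``matrix`` must be sample-level (``col_kind='sample'``, samples in
    columns) with at least 4 samples. Values are log2(x+1)-transformed
    unless the unit already is ``log2p1``. Missing values are handled
    pairwise-complete, with the per-pair n reported.
    """
    panel = list(dict.fromkeys(panel))  # preserve order, drop repeats
    if matrix.col_kind != "sample":
        raise ValidationError("panel correlation needs a sample-level matrix")
    if matrix.shape[1] < 4:
        raise ValidationError("need at least 4 samples")
    missing = [g for g in panel if g not in matrix.row_ids]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {missing}")

    data = matrix.values.loc[panel].T.astype(float)  # samples x genes
    if matrix.unit != "log2p1":
        data = np.log2(data + 1.0)
    r = data.corr(method="pearson", min_periods=3)
    notna = data.notna().astype(int)
    n = notna.T @ notna
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = r.to_numpy(dtype=float)
        nn = n.to_numpy(dtype=float)
        t = rr * np.sqrt((nn - 2) / np.clip(1.0 - rr**2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), np.clip(nn - 2, 1, None))
    p = np.where(np.abs(rr) >= 1.0, 0.0, p)
    np.fill_diagonal(p, 1.0)
    p_matrix = pd.DataFrame(p, index=r.index, columns=r.columns)
    return PanelCorrelation(r_matrix=r, p_matrix=p_matrix, n_matrix=n, genes=panel)


def cluster_order(
    pc: PanelCorrelation,
    linkage_method: str = "average",
    absolute: bool = False,
) -> list:
    """Leaf order from agglomerative clustering on d = 1 - R.

    Genes are pre-sorted lexicographically so the order is invariant to the
    panel's input order; ``absolute=True`` clusters on 1 - |R| instead,
    grouping strong negative correlates with their positive mirrors.
    """
    genes = sorted(pc.r_matrix.index, key=str)
    r = pc.r_matrix.loc[genes, genes].to_numpy(dtype=float)
    if np.isnan(r).any():
        raise ValidationError("correlation matrix has missing entries")
    d = 1.0 - (np.abs(r) if absolute else r)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    if len(genes) == 1:
        pc.genes = list(genes)
        return pc.genes
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage_method)
    order = hierarchy.leaves_list(Z)
    pc.linkage = Z
    pc.genes = [genes[i] for i in order]
    return pc.genes


def panel_report(pc: PanelCorrelation, query: str, groups: dict | None = None) -> pd.DataFrame:
    """Per-gene correlation with the query, grouped by role.

    ``groups`` maps gene -> role label (e.g. the packaged panel roles);
    unknown or missing labels fall into ``other`` with a warning. Rows are
    sorted by descending R within each role; a BH-adjusted q column
    accompanies the unadjusted p-values.
    """
    if query not in pc.r_matrix.index:
        raise KeyError(f"query {query!r} not in panel")
    groups = dict(groups or {})
    known = set(groups.values())
    rows = []
    for gene in pc.r_matrix.index:
        role = groups.get(gene)
        if role is None or role not in known:
            if groups and gene not in groups:
                warnings.warn(f"gene {gene!r} has no role label; grouped as 'other'",
                              stacklevel=2)
            role = role if role in known else "other"
        rows.append(
            {
                "gene": gene,
                "role": role,
                "r_with_query": float(pc.r_matrix.loc[gene, query]),
                "p_value": float(pc.p_matrix.loc[gene, query]),
                "n": int(pc.n_matrix.loc[gene, query]),
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    return (
        df.sort_values(["role", "r_with_query"], ascending=[True, False], kind="mergesort")
        .reset_index(drop=True)
    )
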