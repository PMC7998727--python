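"""Term enrichment over co-expression sets.

Two routes are provided:

* ``enrich_set`` — fixed-threshold over-representation: hypergeometric tail
  of the overlap between a target set (e.g. the top-2% co-expressed genes)
  and each annotation term, with Benjamini-Hochberg FDR across terms.
* ``mhg_enrich`` — threshold-free minimum-hypergeometric (mHG) enrichment on
  the full ranked list: the statistic minimises the hypergeometric tail over
  all list cutoffs, and its exact p-value is computed by dynamic programming
  over the binary-occurrence lattice (path counting under the uniform
  permutation null), so no multiple-cutoff correction is needed.

Annotations are used flat; no ontology-graph propagation is performed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import AnnotationTable

__all__ = ["hypergeometric_tail", "enrich_set", "mhg_enrich", "bh_adjust"]

# relative tolerance when testing "tail <= mHG score" on the DP lattice;
# guards against the score and the lattice tail differing in the last ulp
_REL_TOL = 1e-9


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    N is the background size, K the annotated genes in the background, n the
    target-set size, k the annotated genes in the target. Computed via the
    log-space survival function for numerical stability in the far tail.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need K, n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(np.exp(hypergeom.logsf(k - 1, N, K, n)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich_set(
    target,
    annotation: AnnotationTable,
    background,
    p_report: float = 0.001,
) -> pd.DataFrame:
    """Over-representation of each annotation term in ``target``.

    ``target`` must be a subset of ``background`` (by default the expressed
    transcript set, not all annotated genes). Every term with at least one
    background gene is tested; terms with p >= ``p_report`` are flagged
    ``reported=False`` rather than dropped. Rows are sorted by ascending p,
    ties by term id.
    """
    target = frozenset(target)
    background = frozenset(background)
    if not background:
        raise ValueError("empty background")
    stray = target - background
    if stray:
        raise ValueError(f"target genes outside background: {sorted(stray)[:5]}")

    N, n = len(background), len(target)
    rows = []
    for term, genes in annotation.term_to_genes.items():
        K = len(genes & background)
        if K == 0:
            continue
        k = len(genes & target)
        rows.append(
            {
                "term_id": term,
                "term_name": annotation.name(term),
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p_value": hypergeometric_tail(k, K, n, N),
            }
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "N", "K", "n", "k", "p_value"]
    )
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["q_value"] = pd.Series(dtype=float)
    df["method"] = "hypergeometric"
    df["reported"] = df["p_value"] < p_report
    return df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)


def _mhg_tail_matrix(N: int, K: int, max_cutoff: int) -> np.ndarray:
    """tails[c, k] = P[X >= k], X ~ Hypergeom(N, K, c), for c <= max_cutoff."""
    tails = np.ones((max_cutoff + 1, K + 1))
    for c in range(1, max_cutoff + 1):
        kmax = min(K, c)
        ks = np.arange(1, kmax + 1)
        tails[c, 1 : kmax + 1] = np.exp(hypergeom.logsf(ks - 1, N, K, c))
        tails[c, kmax + 1 :] = 0.0  # unreachable cells
    return tails


def mhg_enrich(ranked, term_genes, max_cutoff: int | None = None):
    """Minimum-hypergeometric enrichment of ``term_genes`` in a ranked list.

    Returns ``(mhg_score, best_cutoff, exact_p)``:

    * ``mhg_score`` — min over cutoffs ``c <= max_cutoff`` of the
      hypergeometric tail of the term count in the top ``c``;
    * ``best_cutoff`` — the smallest cutoff attaining the minimum;
    * ``exact_p`` — P[mHG <= mhg_score] under the uniform permutation null,
      by the O(N*K) lattice dynamic program: path probabilities are
      propagated through cells (c, k), zeroing every cell whose tail already
      beats the observed score; one minus the surviving mass is the exact
      p-value. Always ``exact_p >= mhg_score``.
    """
    ranked = list(ranked)
    N = len(ranked)
    if len(set(ranked)) != N:
        raise ValueError("ranked list contains duplicates")
    term_genes = frozenset(term_genes)
    if not term_genes:
        raise ValueError("empty term")
    stray = term_genes - set(ranked)
    if stray:
        raise ValueError(f"term genes missing from ranked list: {sorted(stray)[:5]}")
    K = len(term_genes)
    if max_cutoff is None:
        max_cutoff = N
    max_cutoff = min(max_cutoff, N)

    occ = np.fromiter((g in term_genes for g in ranked), dtype=bool, count=N)
    kcum = np.cumsum(occ)

    tails = _mhg_tail_matrix(N, K, max_cutoff)
    cutoff_tails = tails[np.arange(1, max_cutoff + 1), kcum[:max_cutoff]]
    best_idx = int(np.argmin(cutoff_tails))
    mhg_score = float(cutoff_tails[best_idx])
    best_cutoff = best_idx + 1

    exact_p = _mhg_exact_p(N, K, mhg_score, tails, max_cutoff)
    # p >= score holds exactly; guard against last-ulp rounding in the DP sum
    exact_p = min(1.0, max(float(exact_p), mhg_score))
    return mhg_score, best_cutoff, exact_p


def _mhg_exact_p(N: int, K: int, score: float, tails: np.ndarray, max_cutoff: int) -> float:
    """P[min-tail <= score] by path counting on the (cutoff, count) lattice."""
    thresh = score * (1.0 + _REL_TOL)
    # R[k] = P[prefix of current length has k hits and never entered the
    # rejection region at any earlier cutoff]
    R = np.zeros(K + 1)
    R[0] = 1.0
    k_hi = 0
    for i in range(N):  # extending prefix from length i to i+1
        remaining = N - i
        k_hi_new = min(K, i + 1)
        new = np.zeros(K + 1)
        # gain-a-one transition: only possible while k < K
        m = min(k_hi, K - 1)
        ks_one = np.arange(0, m + 1)
        new[1 : m + 2] += R[: m + 1] * ((K - ks_one) / remaining)
        # stay-at-k transition
        ks = np.arange(0, k_hi + 1)
        new[: k_hi + 1] += R[: k_hi + 1] * (1.0 - (K - ks) / remaining)
        if i + 1 <= max_cutoff:
            # kill paths whose running tail is already as extreme as observed
            reject = tails[i + 1, : k_hi_new + 1] <= thresh
            new[: k_hi_new + 1][reject] = 0.0
        R = new
        k_hi = k_hi_new
    return min(1.0, max(0.0, 1.0 - float(R.sum())))
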