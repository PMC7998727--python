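"""Cross-database overlap validation of a co-expression profile.

The procedure mirrors the published workflow: walk the correlation ranking
from the query downwards, keep "seed" genes that also have at least a
minimum number of co-expression partners in a protein-association network,
pull each seed's top partners, deduplicate the pooled partner list, and
count how many unique partners fall inside the top correlation percentiles.
A permutation null (partners drawn uniformly from the ranked background)
turns the raw counts into empirical p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .coexpression import CorrelationProfile, top_set_size
from .datatypes import AssociationNetwork

__all__ = [
    "ValidationReport",
    "select_seeds",
    "collect_partners",
    "dedupe_and_count",
    "overlap_null",
]


@dataclass
class ValidationReport:
    seeds: list
    partners_raw: list  # seed-by-seed partner lists concatenated, duplicates kept
    partners_unique: frozenset
    counts_above: dict  # fraction -> unique partners inside the top-f set
    thresholds: dict  # fraction -> R of the last member of the top-f set
    n_background: int
    unranked_partners: frozenset = field(default_factory=frozenset)

    @property
    def n_raw(self) -> int:
        return len(self.partners_raw)

    @property
    def n_unique(self) -> int:
        return len(self.partners_unique)

    def to_dict(self) -> dict:
        return {
            "seeds": list(self.seeds),
            "n_raw": self.n_raw,
            "n_unique": self.n_unique,
            "partners_unique": sorted(self.partners_unique),
            "counts_above": {str(f): int(c) for f, c in self.counts_above.items()},
            "thresholds": {str(f): float(t) for f, t in self.thresholds.items()},
            "n_background": self.n_background,
            "unranked_partners": sorted(self.unranked_partners),
        }


def select_seeds(
    profile: CorrelationProfile,
    network: AssociationNetwork,
    n_seeds: int = 10,
    min_partners: int = 20,
    degree_channel: str | None = "coexpression",
) -> list:
    """Top-ranked genes with network degree >= ``min_partners``.

    Walks the profile in rank order — the query gene, at rank 1 with R = 1,
    is therefore always the first candidate — keeping genes whose degree in
    the chosen evidence channel meets the cutoff, until ``n_seeds`` seeds
    are found. ``degree_channel=None`` counts edges of every channel.
    """
    seeds = []
    for gene in profile.ranked_ids():
        if network.degree(str(gene), channel=degree_channel) >= min_partners:
            seeds.append(gene)
            if len(seeds) == n_seeds:
                return seeds
    raise ValueError(
        f"only {len(seeds)} of {n_seeds} requested seeds have degree >= "
        f"{min_partners} in the network"
    )


def collect_partners(
    seeds,
    network: AssociationNetwork,
    per_seed: int = 20,
    channel: str | None = "coexpression",
) -> list:
    """For each seed, its ``per_seed`` best-scoring partners, concatenated.

    Ties in score break by partner id. Duplicates across seeds are kept at
    this stage (10 seeds x 20 partners = 200 entries); deduplication happens
    in :func:`dedupe_and_count`.
    """
    out = []
    for seed in seeds:
        nb = network.neighbors(str(seed), channel=channel)
        if len(nb) < per_seed:
            raise ValueError(
                f"seed {seed!r} has only {len(nb)} partners, needs {per_seed}"
            )
        out.extend(nb["partner"].head(per_seed).tolist())
    return out


def dedupe_and_count(
    partners,
    profile: CorrelationProfile,
    fractions=(0.05, 0.01),
) -> ValidationReport:
    """Deduplicate the partner list and count members of each top set.

    Membership uses the rank (rank <= ceil(f * n_background)) so boundary
    ties are handled exactly as in ``top_percentile_set``; the reported
    threshold is the R of the last gene inside each set. Partners absent
    from the ranked profile count as not-above, with a warning.
    """
    partners = list(partners)
    unique = frozenset(partners)
    ranked = profile.rank
    unranked = frozenset(p for p in unique if p not in ranked.index)
    if unranked:
        warnings.warn(
            f"{len(unranked)} partners absent from the correlation profile; "
            "counted as below every threshold",
            stacklevel=2,
        )
    counts, thresholds = {}, {}
    order = profile.ranked_ids()
    for f in fractions:
        m = top_set_size(profile.n_background, f)
        counts[f] = sum(
            1 for p in unique if p in ranked.index and int(ranked[p]) <= m
        )
        thresholds[f] = float(profile.r[order[m - 1]])
    return ValidationReport(
        seeds=[],
        partners_raw=partners,
        partners_unique=unique,
        counts_above=counts,
        thresholds=thresholds,
        n_background=profile.n_background,
        unranked_partners=unranked,
    )


def overlap_null(
    report: ValidationReport,
    profile: CorrelationProfile,
    n_perm: int = 1000,
    seed: int = 0,
    return_counts: bool = False,
):
    """Empirical p-value of each overlap count under a uniform draw null.

    Each permutation draws ``n_unique`` genes without replacement from the
    ranked background and counts how many land inside the top-``f`` set;
    p = (1 + #{count >= observed}) / (1 + n_perm). With
    ``return_counts=True`` the per-permutation null counts are returned as
    a second value (fraction -> integer array), e.g. to compare the null
    mean against the closed-form expectation n_unique * ceil(f*N) / N.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    N = profile.n_background
    n_draw = report.n_unique
    cuts = {f: top_set_size(N, f) for f in report.counts_above}
    null_counts = {f: np.empty(n_perm, dtype=np.int64) for f in cuts}
    for i in range(n_perm):
        draw = rng.choice(N, size=n_draw, replace=False)  # 0-based ranks
        for f, m in cuts.items():
            null_counts[f][i] = int((draw < m).sum())
    pvals = {
        f: (1 + int((null_counts[f] >= report.counts_above[f]).sum())) / (1 + n_perm)
        for f in cuts
    }
    return (pvals, null_counts) if return_counts else pvals
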