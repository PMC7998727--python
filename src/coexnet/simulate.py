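"""Seeded generators for every input type the pipeline consumes.

Each generator plants the structure its consuming stage is designed to
detect: tissue matrices carry latent-factor co-expression modules; networks
and annotations are built consistently with those modules; CNA cohorts get
a monotone dosage effect on expression; spectral counts spike the bait and
its partners in bait runs; sample panels share block factors with the
query. All generators are deterministic given the config seed, and every
output passes the corresponding reader/domain-type validation.

Default sizes follow the study conditions where those are stated (53
tissues, two IP experiment sets, a 40-gene panel); the transcriptome is
scaled to 20,000 transcripts by default so the full property suite runs in
minutes — ``full_scale_config`` restores the 56,202/42,548 background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cancer import CancerNormalTable
from .datatypes import (
    AnnotationTable,
    AssociationNetwork,
    CnaCohort,
    ExpressionMatrix,
    SpectralCountSet,
)
from .io import load_table3_fixture

__all__ = [
    "ModuleSpec",
    "NetworkSpec",
    "CnaSpec",
    "MsSpec",
    "PanelSpec",
    "SimConfig",
    "full_scale_config",
    "pan_cancer_cna_spec",
    "sim_tissue_matrix",
    "sim_network_and_annotation",
    "sim_cna_cohort",
    "sim_spectral_counts",
    "sim_panel_and_crn",
]


@dataclass
class ModuleSpec:
    """A planted co-expression module: ``size`` genes sharing one latent
    per-tissue profile with loading ``a`` and residual noise ``sigma``."""

    size: int = 100
    a: float = 3.0
    sigma: float = 1.0
    term_id: str = "TERM_M1"


@dataclass
class NetworkSpec:
    per_seed_degree: int = 20
    p_within: float = 0.5
    p_background: float = 0.002
    n_background_nodes: int = 300
    n_decoy_terms: int = 10
    decoys_per_term: int = 50


@dataclass
class CnaSpec:
    """Per-cancer-type patient counts and GISTIC category probabilities.

    ``types`` maps cancer type -> (n_patients, probabilities over the five
    categories -2..2). ``n_paired`` patients (chosen at random across the
    cohort) carry expression; the rest lack RNA-seq. Expression follows a
    multiplicative dosage effect, monotone in the GISTIC category, times
    lognormal noise.
    """

    types: dict = field(
        default_factory=lambda: {
            "Carcinoma A": (400, (0.02, 0.20, 0.60, 0.15, 0.03)),
            "Carcinoma B": (350, (0.01, 0.10, 0.70, 0.17, 0.02)),
            "Sarcoma C": (250, (0.005, 0.15, 0.65, 0.18, 0.015)),
        }
    )
    n_paired: int | None = None  # None: ~90% of the cohort
    base_expression: float = 1000.0
    dosage: tuple = (0.25, 0.6, 1.0, 1.6, 2.8)  # multiplier per category -2..2
    noise_sd_log: float = 0.5


@dataclass
class MsSpec:
    """Two-set IP design: ``runs_per_condition_per_set`` bait and control
    runs in each of two experiment sets; the bait plus two complex partners
    plus ``n_extra_partners`` further partners are enriched ``spike_fold``-
    fold in bait runs; a ``bovine_fraction`` of proteins is tagged as the
    non-target species (feeder-serum decoys for the species filter)."""

    n_proteins: int = 300
    runs_per_condition_per_set: int = 3
    n_sets: int = 2
    baseline_rate: float = 5.0
    partner_rate: float = 2.5
    bait_rate_bait: float = 30.0
    bait_rate_control: float = 0.2
    spike_fold: float = 8.0
    n_extra_partners: int = 2
    bovine_fraction: float = 0.25
    nb_dispersion: float = 10.0  # negative-binomial size; larger = closer to Poisson
    size_factor_range: tuple = (0.8, 1.25)


@dataclass
class PanelSpec:
    """Block-correlated sample panel. ``blocks`` maps block label -> (list
    of genes, within-block R); ``query_block`` is the block containing the
    query gene; ``block_coupling`` couples block factors to one shared
    latent axis (0 = independent blocks)."""

    n_samples: int = 1000
    blocks: dict = field(
        default_factory=lambda: {
            "proliferation": ([f"PRO{i}" for i in range(1, 7)], 0.8),
            "housekeeping": ([f"HKG{i}" for i in range(1, 7)], 0.8),
        }
    )
    query_gene: str = "QUERY"
    query_block: str = "proliferation"
    block_coupling: float = 0.0
    n_noise_genes: int = 6
    # CRN-style condition-level table
    n_cancer_types: int = 29
    n_stages: int = 3
    down_gene: str = "DOWNG"
    n_neutral_genes: int = 2


@dataclass
class SimConfig:
    seed: int = 0
    n_tissues: int = 53
    n_transcripts: int = 20000
    n_zero_rows: int = 0
    module_specs: list = field(
        default_factory=lambda: [
            ModuleSpec(size=100, a=3.0, sigma=1.0, term_id="TERM_M1"),
            ModuleSpec(size=100, a=3.0, sigma=1.0, term_id="TERM_M2"),
        ]
    )
    network_spec: NetworkSpec = field(default_factory=NetworkSpec)
    cna_spec: CnaSpec = field(default_factory=CnaSpec)
    ms_spec: MsSpec = field(default_factory=MsSpec)
    panel_spec: PanelSpec = field(default_factory=PanelSpec)

    def to_dict(self) -> dict:
        return asdict(self)


def full_scale_config(seed: int = 0) -> SimConfig:
    """The full-size background: 56,202 transcripts of which 13,654 are
    all-zero, so the expressed background is 42,548."""
    return SimConfig(seed=seed, n_transcripts=56202, n_zero_rows=13654)


def pan_cancer_cna_spec(n_total: int = 10967, n_paired: int = 9889) -> CnaSpec:
    """CnaSpec with the packaged pan-cancer prevalence table as category
    probabilities, patients spread evenly over the 35 types."""
    tab = load_table3_fixture(numeric=True)
    tab = tab.drop(index="All Cancer types")
    n_types = len(tab)
    base, extra = divmod(n_total, n_types)
    types = {}
    for i, (ctype, row) in enumerate(tab.iterrows()):
        probs = np.array(
            [row["deep_deletion"], row["shallow_deletion"], row["diploid"],
             row["gain"], row["amplification"]],
            dtype=float,
        )
        probs = probs / probs.sum()
        types[ctype] = (base + (1 if i < extra else 0), tuple(probs))
    return CnaSpec(types=types, n_paired=n_paired)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent stream per generator so simulating one input never
    # perturbs another
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % (2**31), stream]))


def _softplus(x: np.ndarray) -> np.ndarray:
    # numerically stable log(1 + e^x); keeps simulated TPM non-negative
    # without truncation artifacts
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------


def sim_tissue_matrix(cfg: SimConfig):
    """Tissue-median expression matrix with planted co-expression modules.

    Module gene g of module m: expr(t) = softplus(a * z_m(t) + eps), with
    z_m a standard-normal latent tissue profile and eps ~ N(0, sigma).
    Background genes get independent noise around a gene-level baseline;
    ``n_zero_rows`` all-zero transcripts are appended (the never-expressed
    fraction removed by ``filter_expressed``). The query transcript is the
    first member of module 1.

    Returns ``(matrix, truth)`` with truth = {"query", "modules": {term ->
    gene list}}.
    """
    rng = _rng(cfg, 1)
    T = cfg.n_tissues
    n_module = sum(m.size for m in cfg.module_specs)
    n_bg = cfg.n_transcripts - n_module - cfg.n_zero_rows
    if n_bg < 0:
        raise ValueError("n_transcripts smaller than modules + zero rows")

    ids_mod, rows, truth_modules = [], [], {}
    gi = 0
    for mi, m in enumerate(cfg.module_specs):
        z = rng.standard_normal(T)
        eps = rng.normal(0.0, m.sigma, size=(m.size, T))
        block = _softplus(m.a * z[None, :] + eps)
        rows.append(block)
        members = [f"T{gi + j:06d}" for j in range(m.size)]
        truth_modules[m.term_id] = members
        ids_mod.extend(members)
        gi += m.size
    baseline = rng.normal(1.0, 1.0, size=(n_bg, 1))
    bg = _softplus(baseline + rng.standard_normal((n_bg, T)))
    ids_bg = [f"T{gi + j:06d}" for j in range(n_bg)]
    values = np.vstack([*rows, bg])
    ids = ids_mod + ids_bg
    if cfg.n_zero_rows:
        values = np.vstack([values, np.zeros((cfg.n_zero_rows, T))])
        ids = ids + [f"Z{j:06d}" for j in range(cfg.n_zero_rows)]
    df = pd.DataFrame(values, index=ids, columns=[f"tissue_{t:02d}" for t in range(T)])
    df.index.name = "transcript_id"
    matrix = ExpressionMatrix(df, unit="TPM", col_kind="tissue_median")
    truth = {"query": truth_modules[cfg.module_specs[0].term_id][0], "modules": truth_modules}
    return matrix, truth


def sim_network_and_annotation(cfg: SimConfig, truth: dict):
    """Association network and annotations consistent with planted modules.

    Within-module pairs are linked with probability ``p_within`` at high
    confidence; a sample of background genes is wired sparsely at lower
    confidence. The first ``per_seed_degree``-eligible module-1 genes are
    topped up with extra within-module edges if random wiring left them
    short, so the seed-selection procedure always finds its seeds. Each
    module's term annotates its members plus decoy background genes, and
    decoy-only terms are added for competition.
    """
    rng = _rng(cfg, 2)
    ns = cfg.network_spec
    modules = truth["modules"]
    module_genes = [g for genes in modules.values() for g in genes]
    all_module = set(module_genes)
    bg_pool = [
        f"T{j:06d}"
        for j in range(len(module_genes), min(cfg.n_transcripts - cfg.n_zero_rows,
                                              len(module_genes) + 5000))
    ]
    bg_nodes = list(rng.choice(bg_pool, size=min(ns.n_background_nodes, len(bg_pool)),
                               replace=False))
    edges: dict[tuple, float] = {}

    def add_edge(a, b, score):
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        edges[key] = max(edges.get(key, 0.0), score)

    for genes in modules.values():
        g = list(genes)
        for i in range(len(g)):
            draws = rng.random(len(g) - i - 1)
            scores = rng.uniform(0.6, 0.95, size=len(g) - i - 1)
            for off, (u, s) in enumerate(zip(draws, scores), start=i + 1):
                if u < ns.p_within:
                    add_edge(g[i], g[off], float(np.round(s, 3)))
    nodes = module_genes + bg_nodes
    n_pairs_target = int(ns.p_background * len(nodes) * (len(nodes) - 1) / 2)
    for _ in range(n_pairs_target):
        i, j = rng.integers(0, len(nodes), size=2)
        if i != j:
            add_edge(nodes[i], nodes[j], float(np.round(rng.uniform(0.4, 0.7), 3)))

    # guarantee the seed-selection precondition for module 1
    m1 = modules[cfg.module_specs[0].term_id]
    degree: dict[str, int] = {}
    for a, b in edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    for gene in m1[: max(10, ns.per_seed_degree // 2)]:
        deficit = ns.per_seed_degree - degree.get(gene, 0)
        if deficit > 0:
            others = [g for g in m1 if g != gene]
            picks = rng.choice(others, size=len(others), replace=False)
            added = 0
            for p in picks:
                key = (gene, p) if gene < p else (p, gene)
                if key not in edges:
                    add_edge(gene, p, float(np.round(rng.uniform(0.6, 0.95), 3)))
                    degree[gene] = degree.get(gene, 0) + 1
                    degree[p] = degree.get(p, 0) + 1
                    added += 1
                    if added >= deficit:
                        break

    edge_df = pd.DataFrame(
        [(a, b, s, "coexpression") for (a, b), s in sorted(edges.items())],
        columns=["protein_a", "protein_b", "score", "channel"],
    )
    network = AssociationNetwork(edge_df)

    term_to_genes, term_names = {}, {}
    for term, genes in modules.items():
        decoys = list(rng.choice(bg_pool, size=ns.decoys_per_term, replace=False))
        term_to_genes[term] = set(genes) | set(decoys)
        term_names[term] = f"planted module {term}"
    for d in range(cfg.network_spec.n_decoy_terms):
        term = f"TERM_D{d + 1}"
        term_to_genes[term] = set(rng.choice(bg_pool, size=ns.decoys_per_term, replace=False))
        term_names[term] = f"decoy term {d + 1}"
    annotation = AnnotationTable(term_to_genes, term_names, namespace="process")
    return network, annotation


def sim_cna_cohort(cfg: SimConfig) -> CnaCohort:
    """Patient-level GISTIC cohort with a monotone dosage effect.

    Categories are drawn per cancer type from the configured probabilities;
    expression = base * dosage(category) * lognormal noise for the paired
    patients, missing for the rest. Exactly ``n_paired`` patients carry
    expression when that field is set.
    """
    rng = _rng(cfg, 3)
    spec = cfg.cna_spec
    recs = []
    pid = 0
    for ctype, (n, probs) in spec.types.items():
        cats = rng.choice(np.arange(-2, 3), size=n, p=np.asarray(probs, float))
        for c in cats:
            recs.append((f"P{pid:06d}", ctype, int(c)))
            pid += 1
    total = len(recs)
    n_paired = spec.n_paired if spec.n_paired is not None else int(round(0.9 * total))
    if n_paired > total:
        raise ValueError("n_paired exceeds cohort size")
    paired_idx = set(rng.choice(total, size=n_paired, replace=False).tolist())
    dosage = dict(zip(range(-2, 3), spec.dosage))
    rows = []
    for i, (pat, ctype, cat) in enumerate(recs):
        if i in paired_idx:
            expr = spec.base_expression * dosage[cat] * float(
                np.exp(rng.normal(0.0, spec.noise_sd_log))
            )
        else:
            expr = np.nan
        rows.append((pat, ctype, cat, expr))
    df = pd.DataFrame(rows, columns=["patient", "cancer_type", "gistic", "expression"])
    df["has_rna"] = df["expression"].notna()
    return CnaCohort(df, expression_scale="RSEM")


def sim_spectral_counts(cfg: SimConfig):
    """Two-set IP-MS spectral counts with spiked bait partners.

    Counts are negative binomial around protein rates times run-level size
    factors. The bait is near-absent in control runs and strong in bait
    runs; the two complex partners and ``n_extra_partners`` further human
    partners are enriched ``spike_fold``-fold in bait runs. Returns
    ``(SpectralCountSet, truth)`` with truth = {"bait", "partners"}.
    """
    rng = _rng(cfg, 4)
    ms = cfg.ms_spec
    partners = [f"PART{i + 1}" for i in range(2 + ms.n_extra_partners)]
    n_bg = ms.n_proteins - 1 - len(partners)
    if n_bg < 0:
        raise ValueError("n_proteins too small for bait + partners")
    bg_ids = [f"PROT{i:04d}" for i in range(n_bg)]
    proteins = ["BAIT", *partners, *bg_ids]

    n_bovine = int(round(ms.bovine_fraction * n_bg))
    species = pd.Series("Homo sapiens", index=proteins)
    bovine_ids = rng.choice(bg_ids, size=n_bovine, replace=False)
    species.loc[bovine_ids] = "Bos taurus"

    runs, cond, eset = [], [], []
    for s in range(1, ms.n_sets + 1):
        for condition in ("control", "bait"):
            for r in range(1, ms.runs_per_condition_per_set + 1):
                runs.append(f"set{s}_{condition}_{r}")
                cond.append(condition)
                eset.append(f"set{s}")
    run_info = pd.DataFrame({"condition": cond, "experiment_set": eset}, index=runs)

    base = rng.lognormal(mean=np.log(ms.baseline_rate), sigma=0.8, size=n_bg)
    rates = pd.DataFrame(index=proteins, columns=runs, dtype=float)
    sf = rng.uniform(*ms.size_factor_range, size=len(runs))
    for j, run in enumerate(runs):
        is_bait = cond[j] == "bait"
        col = np.empty(len(proteins))
        col[0] = ms.bait_rate_bait if is_bait else ms.bait_rate_control
        col[1 : 1 + len(partners)] = ms.partner_rate * (ms.spike_fold if is_bait else 1.0)
        col[1 + len(partners) :] = base
        rates[run] = col * sf[j]

    k = ms.nb_dispersion
    lam = rates.to_numpy()
    # NB via gamma-Poisson mixture: mean lam, variance lam + lam^2 / k
    counts = rng.poisson(rng.gamma(k, lam / k))
    counts_df = pd.DataFrame(counts.astype(np.int64), index=proteins, columns=runs)
    counts_df.index.name = "protein"
    scs = SpectralCountSet(counts_df, run_info, species, bait_id="BAIT")
    return scs, {"bait": "BAIT", "partners": partners}


def sim_panel_and_crn(cfg: SimConfig):
    """Sample-level panel matrix plus a condition-level cancer table.

    Panel genes within a block share a latent factor at the configured
    within-block R on the log2(x+1) scale; the query gene belongs to
    ``query_block``. The cancer table plants the query above its normal
    reference in every cancer type and the designated down-gene below it;
    neutral genes alternate around the reference.

    Returns ``(ExpressionMatrix, CancerNormalTable, truth)``.
    """
    rng = _rng(cfg, 5)
    ps = cfg.panel_spec
    n = ps.n_samples
    shared = rng.standard_normal(n)
    cols, gene_block = {}, {}
    for label, (genes, rho) in ps.blocks.items():
        w = ps.block_coupling
        f = w * shared + np.sqrt(max(0.0, 1 - w**2)) * rng.standard_normal(n)
        members = list(genes)
        if label == ps.query_block:
            members = [ps.query_gene, *members]
        for g in members:
            z = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n)
            cols[g] = z
            gene_block[g] = label
    for i in range(ps.n_noise_genes):
        g = f"NOISE{i + 1}"
        cols[g] = rng.standard_normal(n)
        gene_block[g] = "noise"
    # expression chosen so log2(x + 1) recovers the latent gaussian exactly
    # (up to rare clipping at zero)
    values = {
        g: np.clip(np.exp2(5.0 + z) - 1.0, 0.0, None) for g, z in cols.items()
    }
    df = pd.DataFrame(values).T
    df.columns = [f"sample_{i:04d}" for i in range(n)]
    df.index.name = "gene"
    matrix = ExpressionMatrix(df, unit="RPKM", col_kind="sample")

    # condition-level cancer table
    recs = []
    stages = [f"stage{s}" for s in range(1, ps.n_stages + 1)]
    neutral = [f"NEUT{i + 1}" for i in range(ps.n_neutral_genes)]
    for c in range(1, ps.n_cancer_types + 1):
        ctype = f"cancer_{c:02d}"
        for gene in [ps.query_gene, ps.down_gene, *neutral]:
            ref = float(rng.uniform(5.0, 50.0))
            recs.append((gene, ctype, "normal", ref, "TPM"))
            for si, stage in enumerate(stages):
                if gene == ps.query_gene:
                    fac = float(rng.uniform(1.5, 3.0))
                elif gene == ps.down_gene:
                    fac = float(rng.uniform(0.3, 0.7))
                else:
                    # force a mixed pattern: alternate above/below normal
                    u = float(rng.uniform(0.05, 0.2))
                    fac = 1.0 + u if si % 2 == 0 else 1.0 - u
                recs.append((gene, ctype, stage, ref * fac, "TPM"))
    crn = CancerNormalTable(
        pd.DataFrame(recs, columns=["gene", "cancer_type", "stage", "expression", "unit"])
    )
    truth = {
        "query": ps.query_gene,
        "down_gene": ps.down_gene,
        "blocks": {
            label: ([ps.query_gene] if label == ps.query_block else []) + list(genes)
            for label, (genes, _rho) in ps.blocks.items()
        },
    }
    return matrix, crn, truth
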