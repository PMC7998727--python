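# Methods

This note documents the statistical models, defaults and numerical choices
behind `coexnet`, and what the synthetic benchmarks do and do not show.

## Co-expression ranking

The profile of a query transcript is the vector of Pearson correlation
coefficients R between the query's expression and every other transcript's,
computed across tissue columns (or samples). Transcripts with zero variance
— including the never-expressed rows removed by `filter_expressed` — have an
undefined R; they are placed in an `excluded` set and receive no rank rather
than being assigned R = 0, because silently ranking them would deflate every
percentile cutoff. Ranks sort by descending R with ties broken by
lexicographic transcript id, so rankings are bit-reproducible.

The top-`f` set contains ⌈f·n⌉ transcripts. The ceiling rule is a
deliberate choice: 0.02 × 42,548 = 850.96, and the published top-2% set for
that background has 851 genes, which only the ceiling reproduces. The
percentile threshold is the R of the last member of the set, so membership
and threshold are always mutually consistent even with ties at the
boundary. Correlation is computed on raw abundance values by default
(tissue-median TPM is already a summary statistic); `transform="log2p1"`
is available for sample-level count-like matrices. Ranking uses signed R;
an absolute-value option exists but is off by default, since the network
validation counts agree with signed ranking.

## Term enrichment

Two statistics are provided over flat gene→term annotations:

* **Fixed threshold.** For each term with K annotated genes in the
  N-gene background and k in the n-gene target, p = P[X ≥ k] for
  X ~ Hypergeometric(N, K, n), evaluated through the log-space survival
  function. The background defaults to the expressed-transcript set, not
  all annotated genes — percentile sets are defined relative to that
  background, and using a smaller background would overstate enrichment.
  BH adjustment runs over all tested terms; terms with p above the
  reporting threshold (default 0.001, the conventional "no network found"
  criterion) are flagged, never dropped.
* **Minimum hypergeometric (mHG).** On the full ranked list the statistic
  is s = min over cutoffs c of the hypergeometric tail of the term count in
  the top c, removing the need to pick a threshold. Its exact p-value
  P[mHG ≤ s] under the uniform permutation null is computed by dynamic
  programming on the (cutoff, count) lattice: path probabilities are
  propagated with the sampling-without-replacement transition weights, and
  every cell whose running tail is already ≤ s is zeroed; one minus the
  surviving mass at the end of the list is the exact p. The program is
  O(N·K) time. A relative tolerance of 1e-9 guards the "tail ≤ s"
  comparison against last-ulp asymmetry, and the returned p is clamped to
  [s, 1] (a mathematical identity that floating summation can violate by
  one ulp). The cutoff cap defaults to the full list.

No ontology-DAG propagation is performed: annotations are used as given.
Propagation depends on an ontology release and changes K per term; the flat
statistic is the part that is testable against enumeration.

## Cross-network validation

Seeds are collected by walking the ranking from the query down, keeping
genes with at least `min_partners` (default 20) partners in the network's
co-expression evidence channel, until `n_seeds` (default 10) are found; the
query, at rank 1 with R = 1, is always seed #1. "Co-expressed partners"
counts only co-expression-channel edges by default (a `degree_channel`
switch uses all channels). Each seed contributes its `per_seed` (20)
best-scoring partners, ties broken by id; the pooled list (10 × 20 = 200)
is deduplicated and unique partners are counted inside each top-`f` set by
rank membership (rank ≤ ⌈f·n⌉) so boundary ties behave exactly as in the
percentile sets. Partners missing from the ranked profile count as
not-above, with a warning.

The permutation null draws `n_unique` genes uniformly without replacement
from the ranked background; the empirical p uses the add-one estimator
(1 + exceedances)/(1 + permutations). Under this null the count inside a
top-m set is hypergeometric with mean n_unique·m/N, which the
Monte-Carlo calibration test checks to within 3 standard errors.

## Cancer-vs-normal calls and CNA prevalence

Direction calls operate on condition-level summaries: a gene is "up" in a
cancer type only if every stage exceeds the normal reference (times an
optional 1 + δ margin; δ defaults to 0, the literal above-the-identity-line
reading), "down" symmetrically, else "unchanged". Calls are scale-invariant
within a cancer type, and units are never compared across types.

Prevalence tables give the percentage of patients per GISTIC category
(−2 … +2) per cancer type plus a pooled row; percentages per row sum to 100
before rounding (default 2 decimals). The summary counts types whose
amplification percentage strictly exceeds the deep-deletion percentage —
ties do not count, and absent categories (printed as dashes in the packaged
table) are 0%; both conventions are required to reproduce the packaged
table's 16-of-35 headline. Mean expression per category is reported on the
log2(x+1) scale for raw-RSEM cohorts (recorded in the output), since RSEM
values are heavy-tailed and the arithmetic mean on the raw scale is
dominated by outliers.

## IP-MS differential enrichment

Spectral counts are normalized per experiment set: run j is scaled by
(mean total of the set's runs)/(total of run j), with totals taken over all
proteins before species filtering, so each set's mean total is preserved
exactly. After restricting to the target species and transforming with
log2(x+1) (a zero count maps to 0), each protein is fitted by least squares
with an intercept, a bait indicator, and — when both experiment sets are
present — an additive set covariate; the bait coefficient is the log2 fold
change. Proteins never observed in bait runs are kept, not dropped.

Variance moderation follows the empirical-Bayes scheme of the moderated t:
the per-protein residual variances s² (df residual degrees of freedom) are
assumed to follow a scaled inverse-chi-square prior with hyperparameters
(d₀, s₀²), estimated by moment-matching log s² against its scaled-F
marginal — the mean and excess variance of e = log s² − ψ(df/2) + log(df/2)
give s₀² and d₀ through the digamma/trigamma equations, with the trigamma
inverse solved by Newton iteration. If the empirical excess variance is
non-positive the prior is degenerate (d₀ = ∞, complete shrinkage); if the
solve fails a warning falls back to the same limit. The moderated variance
is s̃² = (d₀s₀² + df·s²)/(d₀ + df) and t = logFC/√(s̃²·v) is referred to a
t distribution with df + d₀ degrees of freedom (two-sided p, as in the
reference implementation, which the test suite matches to machine
precision on a frozen fixture). `d0_override` exposes the two limits:
0 recovers the ordinary t, ∞ the fully pooled t.

Candidates require log₂FC > 1.5, BH q < 0.05 and at least 3 bait-side
spectra (`n_psm_bait`, defined here as the maximum raw count over bait
runs). The fold-change threshold is interpreted on the log2 scale
(≈ 2.83-fold), the conventional scale of the moderated-t output. Only
positive log-fold-changes (enrichment in the bait IP) are candidates by
default; `two_sided=True` lifts that. A `per_set` mode fits each
experiment set separately and intersects the candidate flags.

## Panel correlation

Panel values are transformed log2(x+1) unless already on that scale, then
correlated pairwise-complete (per-pair n reported) with p-values from the
t transform of R on n − 2 degrees of freedom. Clustering for display uses
average linkage on d = 1 − R; genes are sorted lexicographically before
linkage so the leaf order is independent of input order, and a 1 − |R|
option groups anti-correlated genes with their mirrors. The linkage and
distance are display choices, not inference; complete/single/ward are
accepted. Reported p-values are unadjusted with a BH column alongside.

## Synthetic data: what it emulates, and what it does not

* **Tissue matrices.** Module gene g in module m has expression
  softplus(a·z_m(t) + ε) with z_m a standard-normal latent tissue profile,
  ε ~ N(0, σ); background genes get independent noise around a gene-level
  baseline, and a configurable number of all-zero rows emulates the
  never-expressed fraction. Softplus keeps values positive without the
  correlation artifacts of hard truncation. Defaults: 53 tissues, 20,000
  transcripts, two modules of 100 genes at a/σ = 3 (a clearly detectable
  but not deterministic signal: within-module R ≈ 0.85). The full-scale
  configuration (56,202 transcripts, 13,654 all-zero, hence a 42,548
  expressed background) exists for the arithmetic checks; routine tests use
  the 20,000-transcript default so the suite runs in minutes.
* **Networks/annotations.** Within-module edges at probability 0.5 with
  confidence scores in [0.6, 0.95]; sparse background edges in [0.4, 0.7].
  The first module-1 genes are topped up with within-module edges when
  random wiring leaves them below the seed-degree threshold — this makes
  the seed-selection precondition deterministic rather than probabilistic.
  Terms annotate module members plus 50 background decoys, with 10
  decoy-only terms for competition.
* **CNA cohorts.** Categories are multinomial per cancer type (optionally
  the packaged prevalence table renormalized); expression is
  base·dosage(category)·lognormal noise with dosage multipliers
  (0.25, 0.6, 1, 1.6, 2.8) — monotone in copy number, the pattern the
  expression-by-category summary is designed to detect. A configurable
  subset of patients (exactly 9,889 of 10,967 in the pan-cancer-sized
  configuration) carries expression.
* **Spectral counts.** Negative-binomial counts (gamma-Poisson, dispersion
  10) around protein rates times run size factors in [0.8, 1.25]; two
  experiment sets with 3 bait and 3 control runs each, the stated two-set
  IP design. The bait is near-absent in controls (rate 0.2 vs 30); the two
  complex partners and two further partners are enriched 8-fold over a
  2.5-count baseline, mirroring a five-protein ground truth (bait + 4
  partners); 25% of background proteins are tagged as the non-target
  species to exercise the species filter.
* **Panels/cancer tables.** Panel genes share block latent factors so that
  log2(x+1) recovers the latent Gaussian exactly and within-block R equals
  the configured value (0.8 by default, 1,000 samples). The cancer table
  plants the query above normal in all 29 types (uplift U(1.5, 3)), a down
  gene below normal, and neutral genes forced to alternate around normal.

These generators validate the statistical machinery against known truth;
they do not model read-level noise, GC/length bias, shared-peptide
ambiguity in protein inference, batch effects beyond the two-set IP
covariate, or the correlated annotation structure of a real ontology.
Passing the planted-recovery benchmarks therefore demonstrates correctness
of the algorithms under their stated assumptions, not performance on any
particular public dataset — the published overlap counts and GO p-values
that depend on specific GTEx/STRING/ontology releases are deliberately out
of scope.

## Determinism and problem sizes

Every generator takes one integer seed and derives an independent
sub-stream per input type, so outputs are bit-reproducible and simulating
one input never perturbs another. The acceptance script and the property
tests use: 20 seeds × 20,000-transcript transcriptomes for module recovery;
10,000 permutations for the overlap-null calibration; 20 seeds × 500
proteins for hyperparameter recovery (d₀ = 4, s₀² = 0.05, 3 + 3 runs);
20 seeds × 300 proteins for spiked-IP recovery and × 1,000 proteins for
the null candidate-rate bound; 20 seeds × 1,000-sample panels for block
contiguity. These sizes keep each benchmark's Monte-Carlo error well below
the margins being asserted while the whole suite completes in minutes.

## Known limitations

* GCT support is the 1.2 dialect only (the one used for expression
  snapshots); GCT 1.3 metadata rows are not parsed.
* The mHG exact p is exact under exchangeable rankings; correlated gene
  ranks (co-regulated genes) make it conservative in practice.
* `classify_direction` operates on condition-level summaries and therefore
  carries no patient-level uncertainty; it is a description of a published
  summary table, not a differential-expression test.
* The moderated-t pipeline assumes log-transformed normalized counts are
  approximately Gaussian per protein; for very low counts a count model
  would be more faithful, at the cost of the closed-form moderation this
  package reproduces.
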