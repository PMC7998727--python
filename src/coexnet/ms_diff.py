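"""Differential spectral-count analysis of bait-vs-control IP-MS runs.

Pipeline: per-experiment-set total-count normalization, species filter,
log2(x+1) transform, per-protein linear model (bait-vs-control contrast
with an additive experiment-set covariate when both sets are present), and
empirical-Bayes variance moderation: per-protein residual variances s_g^2
are shrunk toward a prior (d0, s0^2) estimated by moment-matching the
marginal distribution of log s_g^2 against a scaled-F prior, giving a
moderated t with df + d0 degrees of freedom. Candidates then pass a
log-fold-change, FDR, and minimum-bait-count filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import SpectralCountSet, ValidationError
from .enrichment import bh_adjust

__all__ = [
    "EbHyper",
    "normalize_runs",
    "prepare",
    "fit_eb",
    "call_candidates",
    "run_ms_diff",
]


@dataclass
class EbHyper:
    """Hyperparameters of the inverse-chi-square variance prior.

    ``d0`` is the prior degrees of freedom (``inf`` means complete
    shrinkage to ``s0_sq``); ``s0_sq`` the prior variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValidationError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValidationError("s0_sq must be positive")


def normalize_runs(scs: SpectralCountSet) -> pd.DataFrame:
    """Scale each run so totals within an experiment set are equal.

    Run j in set S is multiplied by mean(totals in S) / total_j; totals are
    computed over all proteins, before any species filtering. Each set's
    mean total count is preserved exactly.
    """
    totals = scs.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise ValidationError(f"runs with zero total counts: {zero}")
    factors = pd.Series(index=scs.runs, dtype=float)
    for _, runs in scs.run_info.groupby("experiment_set").groups.items():
        runs = [r for r in runs if r in totals.index]
        if len(runs) < 2:
            raise ValidationError("each experiment set needs at least 2 runs")
        mean_total = totals[runs].mean()
        factors[runs] = mean_total / totals[runs]
    return scs.counts.astype(float) * factors


def prepare(scs: SpectralCountSet, species_keep: str = "Homo sapiens") -> pd.DataFrame:
    """Normalize, restrict to one species, and log2(x+1)-transform."""
    norm = normalize_runs(scs)
    keep = scs.species[scs.species == species_keep].index
    if len(keep) == 0:
        raise ValidationError(f"no proteins tagged {species_keep!r}")
    return np.log2(norm.loc[keep] + 1.0)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s_sq: np.ndarray, df: np.ndarray) -> EbHyper:
    """Moment-match log s^2 against the scaled-F marginal.

    With s_g^2 | sigma_g^2 ~ sigma_g^2 chi^2_df / df and
    sigma_g^2 ~ s0^2 d0 / chi^2_d0, the residuals
    e_g = log s_g^2 - digamma(df/2) + log(df/2) have mean
    log s0^2 + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2); the digamma/trigamma equations are inverted to recover
    (d0, s0^2). Falls back to d0 = inf (complete shrinkage) when the
    empirical excess variance is non-positive.
    """
    ok = (s_sq > 0) & (df > 0)
    if not ok.any():
        raise ValidationError(
            "all proteins have zero residual variance or zero df; "
            "cannot estimate the variance prior"
        )
    x, d = s_sq[ok], df[ok].astype(float)
    z = np.log(x)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    n = len(e)
    evar = float(((e - emean) ** 2).sum() / max(n - 1, 1))
    evar -= float(special.polygamma(1, d / 2.0).mean())
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        if not np.isfinite(d0):
            warnings.warn("variance-prior solve failed; using d0 = inf", stacklevel=2)
            return EbHyper(d0=np.inf, s0_sq=float(np.exp(emean)))
        s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return EbHyper(d0=d0, s0_sq=s0)
    return EbHyper(d0=np.inf, s0_sq=float(np.exp(emean)))


def fit_eb(
    log_matrix: pd.DataFrame,
    condition: pd.Series,
    experiment_set: pd.Series | None = None,
    d0_override: float | None = None,
) -> tuple[pd.DataFrame, EbHyper]:
    """Per-protein bait-vs-control contrast with moderated variance.

    ``log_matrix`` is proteins x runs on the log2 scale; ``condition`` maps
    each run to ``bait``/``control``. With two experiment sets an additive
    set covariate enters the design. Returns a per-protein frame
    (``log_fc``, ``s_sq``, ``df``, ``t_mod``, ``df_total``, ``p_value``)
    and the estimated prior. ``d0_override`` forces a prior df (``0`` gives
    the ordinary t, ``inf`` complete shrinkage) — useful for limits.
    """
    runs = list(log_matrix.columns)
    cond = condition.loc[runs]
    bad = set(cond) - {"bait", "control"}
    if bad:
        raise ValidationError(f"unknown conditions {sorted(bad)}")
    if (cond == "bait").sum() < 2 or (cond == "control").sum() < 2:
        raise ValidationError("need at least 2 runs per condition")

    cols = [np.ones(len(runs)), (cond == "bait").to_numpy(float)]
    if experiment_set is not None:
        sets = pd.Categorical(experiment_set.loc[runs])
        for level in sets.categories[1:]:
            cols.append((sets == level).astype(float))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    df_resid = len(runs) - rank
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom")

    Y = log_matrix.to_numpy(dtype=float).T  # runs x proteins
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    s_sq = np.einsum("ij,ij->j", resid, resid) / df_resid
    log_fc = beta[1]
    v_contrast = float(np.linalg.pinv(X.T @ X)[1, 1])

    df_arr = np.full_like(s_sq, float(df_resid))
    if d0_override is not None:
        hyper = (
            EbHyper(d0=np.inf, s0_sq=float(np.mean(s_sq[s_sq > 0])))
            if np.isinf(d0_override)
            else None
        )
        if d0_override == 0:
            # ordinary t: no shrinkage, prior weight zero
            s_tilde = s_sq.copy()
            df_total = df_arr.copy()
            hyper = EbHyper(d0=np.finfo(float).tiny, s0_sq=float(np.mean(s_sq[s_sq > 0])))
        elif np.isinf(d0_override):
            s_tilde = np.full_like(s_sq, hyper.s0_sq)
            df_total = np.full_like(s_sq, np.inf)
        else:
            hyper = EbHyper(d0=float(d0_override), s0_sq=float(np.mean(s_sq[s_sq > 0])))
            s_tilde = (hyper.d0 * hyper.s0_sq + df_arr * s_sq) / (hyper.d0 + df_arr)
            df_total = df_arr + hyper.d0
    else:
        hyper = _fit_variance_prior(s_sq, df_arr)
        if np.isinf(hyper.d0):
            s_tilde = np.full_like(s_sq, hyper.s0_sq)
            df_total = np.full_like(s_sq, np.inf)
        else:
            s_tilde = (hyper.d0 * hyper.s0_sq + df_arr * s_sq) / (hyper.d0 + df_arr)
            df_total = df_arr + hyper.d0

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log_fc / np.sqrt(s_tilde * v_contrast)
    t_mod = np.where(np.isfinite(t_mod), t_mod, 0.0)
    finite_df = np.where(np.isinf(df_total), 1e12, df_total)
    p = 2.0 * stats.t.sf(np.abs(t_mod), finite_df)

    table = pd.DataFrame(
        {
            "log_fc": log_fc,
            "s_sq": s_sq,
            "df": df_arr,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_value": p,
        },
        index=log_matrix.index,
    )
    return table, hyper


def call_candidates(
    results: pd.DataFrame,
    logfc_min: float = 1.5,
    q_max: float = 0.05,
    min_psm_bait: int = 3,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Flag differentially enriched proteins.

    Requires a ``p_value`` column (BH q is computed over all tested
    proteins) and an ``n_psm_bait`` column with the maximum raw spectral
    count over bait runs. Defaults follow the conventional filter: log2
    fold change > 1.5, FDR-adjusted p < 0.05, and at least 3 bait-side
    spectra. By default only enrichment in the bait IP (positive log_fc)
    can be a candidate; ``two_sided=True`` accepts either direction.
    """
    out = results.copy()
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    fc_ok = out["log_fc"].abs() > logfc_min if two_sided else out["log_fc"] > logfc_min
    out["candidate"] = (
        fc_ok & (out["q_value"] < q_max) & (out["n_psm_bait"] >= min_psm_bait)
    )
    return out.sort_values(
        ["candidate", "t_mod"], ascending=[False, False], kind="mergesort"
    )


def run_ms_diff(
    scs: SpectralCountSet,
    species_keep: str = "Homo sapiens",
    logfc_min: float = 1.5,
    q_max: float = 0.05,
    min_psm_bait: int = 3,
    per_set: bool = False,
    two_sided: bool = False,
) -> tuple[pd.DataFrame, EbHyper]:
    """The full spectral-count pipeline on one SpectralCountSet.

    With ``per_set=True`` each experiment set is fitted separately and the
    candidate flags are intersected (a protein must be called in every
    set); the returned statistics come from the pooled fit either way.
    """
    log_mat = prepare(scs, species_keep=species_keep)
    cond = scs.run_info["condition"]
    sets = scs.run_info["experiment_set"]
    use_covariate = sets.nunique() > 1
    table, hyper = fit_eb(log_mat, cond, experiment_set=sets if use_covariate else None)

    bait_runs = scs.run_info.index[scs.run_info["condition"] == "bait"]
    bait_runs = [r for r in bait_runs if r in scs.counts.columns]
    table["n_psm_bait"] = scs.counts.loc[log_mat.index, bait_runs].max(axis=1)
    called = call_candidates(
        table, logfc_min=logfc_min, q_max=q_max, min_psm_bait=min_psm_bait,
        two_sided=two_sided,
    )
    if per_set and use_covariate:
        flags = None
        for s in sets.unique():
            runs = [r for r in scs.runs if sets[r] == s]
            sub = log_mat[runs]
            t_s, _ = fit_eb(sub, cond.loc[runs])
            t_s["n_psm_bait"] = scs.counts.loc[
                log_mat.index, [r for r in runs if cond[r] == "bait"]
            ].max(axis=1)
            c_s = call_candidates(
                t_s, logfc_min=logfc_min, q_max=q_max, min_psm_bait=min_psm_bait,
                two_sided=two_sided,
            )["candidate"]
            flags = c_s if flags is None else (flags & c_s)
        called["candidate"] = flags.loc[called.index]
    return called, hyper
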