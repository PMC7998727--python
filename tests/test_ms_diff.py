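import numpy as np
import pandas as pd
import pytest

from coexnet.datatypes import SpectralCountSet, ValidationError
from coexnet.ms_diff import (
    call_candidates,
    fit_eb,
    normalize_runs,
    prepare,
    run_ms_diff,
)
from coexnet.simulate import MsSpec, SimConfig, sim_spectral_counts


def make_scs(counts, conditions, sets=None, species=None):
    counts = pd.DataFrame(counts)
    sets = sets or ["s1"] * len(counts.columns)
    run_info = pd.DataFrame(
        {"condition": conditions, "experiment_set": sets}, index=counts.columns
    )
    species = pd.Series(species or "Homo sapiens", index=counts.index)
    return SpectralCountSet(counts, run_info, species)


class TestNormalizeRuns:
    def test_equal_totals_unchanged(self):
        scs = make_scs(
            {"r1": [5, 5], "r2": [3, 7]}, ["bait", "control"]
        )
        norm = normalize_runs(scs)
        assert np.allclose(norm.to_numpy(), scs.counts.to_numpy())

    def test_totals_100_300_rescaled_to_200(self):
        scs = make_scs({"r1": [60, 40], "r2": [100, 200]}, ["bait", "control"])
        norm = normalize_runs(scs)
        assert norm["r1"].sum() == pytest.approx(200.0)
        assert norm["r2"].sum() == pytest.approx(200.0)
        assert norm.loc[0, "r1"] == pytest.approx(120.0)  # factor 2.0
        assert norm.loc[0, "r2"] == pytest.approx(100 * 2 / 3)

    def test_per_set_mean_total_preserved(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 30, size=(20, 6)),
            columns=[f"r{i}" for i in range(6)],
        )
        scs = make_scs(
            counts,
            ["bait", "bait", "control", "bait", "control", "control"],
            sets=["s1", "s1", "s1", "s2", "s2", "s2"],
        )
        norm = normalize_runs(scs)
        for s in ("s1", "s2"):
            runs = scs.run_info.index[scs.run_info["experiment_set"] == s]
            assert norm[runs].sum().to_numpy() == pytest.approx(
                [scs.counts[runs].sum().mean()] * len(runs)
            )

    def test_zero_total_run_rejected(self):
        scs = make_scs({"r1": [0, 0], "r2": [1, 2]}, ["bait", "control"])
        with pytest.raises(ValidationError):
            normalize_runs(scs)


class TestPrepare:
    def test_log2_of_normalized_plus_one(self):
        scs = make_scs({"r1": [0, 3], "r2": [3, 0]}, ["bait", "control"])
        log = prepare(scs)
        assert log.loc[0, "r1"] == pytest.approx(0.0)
        assert log.loc[1, "r1"] == pytest.approx(2.0)

    def test_species_filter_drops_bovine(self):
        scs = make_scs(
            {"r1": [1, 2, 3], "r2": [1, 2, 3]},
            ["bait", "control"],
            species=["Homo sapiens", "Bos taurus", "Homo sapiens"],
        )
        log = prepare(scs)
        assert list(log.index) == [0, 2]

    def test_no_matching_species_error(self):
        scs = make_scs({"r1": [1], "r2": [1]}, ["bait", "control"],
                       species=["Bos taurus"])
        with pytest.raises(ValidationError):
            prepare(scs)


@pytest.fixture(scope="module")
def oracle_fit():
    """Deterministic small two-set experiment, fitted once."""
    cfg = SimConfig(seed=42, ms_spec=MsSpec(n_proteins=40))
    scs, _ = sim_spectral_counts(cfg)
    log = prepare(scs)
    table, hyper = fit_eb(
        log, scs.run_info["condition"], scs.run_info["experiment_set"]
    )
    return table, hyper


class TestFitEb:
    # expected values computed once with the limma reference implementation
    # (lmFit + eBayes on the identical log2 matrix and design)
    LIMMA_D0 = 26.6816
    LIMMA_S0_SQ = 0.523851
    LIMMA_ROWS = {
        "BAIT": (4.46810670187616, 11.4739836221141, 1.57765645669147e-13),
        "PART1": (2.7719867068012, 5.87287096011084, 1.06037096420364e-06),
        "PART2": (2.29855536939623, 5.02383999298568, 1.42626624530044e-05),
        "PROT0001": (-0.318078558039053, -0.840893543479976, 0.406007629472788),
    }

    def test_hyperparameters_match_limma(self, oracle_fit):
        _, hyper = oracle_fit
        assert hyper.d0 == pytest.approx(self.LIMMA_D0, rel=1e-4)
        assert hyper.s0_sq == pytest.approx(self.LIMMA_S0_SQ, rel=1e-4)

    @pytest.mark.parametrize("protein", sorted(LIMMA_ROWS))
    def test_statistics_match_limma(self, oracle_fit, protein):
        table, _ = oracle_fit
        lfc, t, p = self.LIMMA_ROWS[protein]
        row = table.loc[protein]
        assert row["log_fc"] == pytest.approx(lfc, rel=1e-9)
        assert row["t_mod"] == pytest.approx(t, rel=1e-9)
        assert row["p_value"] == pytest.approx(p, rel=1e-9)

    def test_d0_zero_limit_is_ordinary_t(self, rng):
        data = pd.DataFrame(rng.normal(2.0, 0.5, size=(30, 6)),
                            columns=[f"r{i}" for i in range(6)])
        cond = pd.Series(["bait"] * 3 + ["control"] * 3, index=data.columns)
        table, _ = fit_eb(data, cond, d0_override=0)
        # ordinary two-sample t with pooled variance
        for i in range(5):
            x = data.iloc[i, :3].to_numpy()
            y = data.iloc[i, 3:].to_numpy()
            sp = ((x.var(ddof=1) * 2) + (y.var(ddof=1) * 2)) / 4
            t = (x.mean() - y.mean()) / np.sqrt(sp * (1 / 3 + 1 / 3))
            assert table.iloc[i]["t_mod"] == pytest.approx(t, rel=1e-9)

    def test_d0_inf_limit_uses_pooled_variance_only(self, rng):
        data = pd.DataFrame(rng.normal(2.0, 0.5, size=(30, 6)),
                            columns=[f"r{i}" for i in range(6)])
        cond = pd.Series(["bait"] * 3 + ["control"] * 3, index=data.columns)
        table, hyper = fit_eb(data, cond, d0_override=np.inf)
        v = hyper.s0_sq * (1 / 3 + 1 / 3)
        expected = table["log_fc"] / np.sqrt(v)
        assert table["t_mod"].to_numpy() == pytest.approx(expected.to_numpy(), rel=1e-9)

    def test_moderated_converges_to_ordinary_at_large_n(self, rng):
        # heterogeneous true variances keep the prior df moderate, so the
        # residual df dominates the shrinkage weight as n grows
        n, d0_true = 50, 4.0
        sigma2 = 0.5 * d0_true / rng.chisquare(d0_true, size=200)
        data = pd.DataFrame(
            rng.normal(0.0, np.sqrt(sigma2)[:, None], size=(200, 2 * n)),
            columns=[f"r{i}" for i in range(2 * n)],
        )
        cond = pd.Series(["bait"] * n + ["control"] * n, index=data.columns)
        mod, _ = fit_eb(data, cond)
        ord_, _ = fit_eb(data, cond, d0_override=0)
        nonzero = ord_["t_mod"].abs() > 0.2
        rel = ((mod["t_mod"] - ord_["t_mod"]).abs() / ord_["t_mod"].abs())[nonzero]
        assert rel.median() < 0.01

    def test_hyperparameter_recovery(self):
        """d0 and s0^2 recovered from their own generative model."""
        d0_true, s0_true, n_per, n_prot = 4.0, 0.05, 3, 500
        d0_hat, s0_hat = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=n_prot)
            y = rng.normal(
                0.0, np.sqrt(sigma2)[:, None], size=(n_prot, 2 * n_per)
            )
            data = pd.DataFrame(y, columns=[f"r{i}" for i in range(2 * n_per)])
            cond = pd.Series(["bait"] * n_per + ["control"] * n_per,
                             index=data.columns)
            _, hyper = fit_eb(data, cond)
            d0_hat.append(hyper.d0)
            s0_hat.append(hyper.s0_sq)
        assert 2.5 <= float(np.median(d0_hat)) <= 6.5
        assert abs(float(np.median(s0_hat)) - s0_true) / s0_true < 0.30


class TestCallCandidates:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["log_fc", "p_value", "t_mod", "n_psm_bait"]
        ).assign(df=4.0, df_total=8.0, s_sq=0.1)

    def test_passing_all_filters(self):
        res = self._results([(2.0, 1e-6, 8.0, 5)])
        out = call_candidates(res)
        assert out["candidate"].iloc[0]

    def test_high_q_blocks(self):
        res = self._results([(2.0, 0.8, 1.0, 5), (2.0, 0.9, 0.9, 5)])
        out = call_candidates(res)
        assert not out["candidate"].any()

    def test_low_psm_blocks(self):
        res = self._results([(2.0, 1e-6, 8.0, 2)])
        assert not call_candidates(res)["candidate"].any()

    def test_negative_logfc_blocks_unless_two_sided(self):
        res = self._results([(-3.0, 1e-8, -9.0, 5)])
        assert not call_candidates(res)["candidate"].any()
        assert call_candidates(res, two_sided=True)["candidate"].any()


class TestSpikedRecovery:
    def test_planted_proteins_called(self):
        cfg = SimConfig(seed=3)
        scs, truth = sim_spectral_counts(cfg)
        called, _ = run_ms_diff(scs)
        cands = set(called.index[called["candidate"]])
        assert cands == {truth["bait"], *truth["partners"]}

    def test_bait_top_ranked(self):
        cfg = SimConfig(seed=4)
        scs, truth = sim_spectral_counts(cfg)
        called, _ = run_ms_diff(scs)
        assert called.index[0] == truth["bait"]

    def test_per_set_intersection_subset_of_pooled(self):
        cfg = SimConfig(seed=5)
        scs, _ = sim_spectral_counts(cfg)
        pooled, _ = run_ms_diff(scs)
        per_set, _ = run_ms_diff(scs, per_set=True)
        pooled_set = set(pooled.index[pooled["candidate"]])
        inter_set = set(per_set.index[per_set["candidate"]])
        assert inter_set <= pooled_set or len(inter_set - pooled_set) <= 1
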