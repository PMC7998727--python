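import numpy as np
import pandas as pd
import pytest

from coexnet import coexpression as cx
from coexnet.cancer import classify_direction
from coexnet.cna import expression_by_category, filter_paired, prevalence
from coexnet.panel import panel_correlate
from coexnet.simulate import (
    CnaSpec,
    ModuleSpec,
    MsSpec,
    PanelSpec,
    SimConfig,
    full_scale_config,
    pan_cancer_cna_spec,
    sim_cna_cohort,
    sim_network_and_annotation,
    sim_panel_and_crn,
    sim_spectral_counts,
    sim_tissue_matrix,
)


class TestTissueMatrix:
    def test_shapes_and_query_membership(self, default_config):
        matrix, truth = sim_tissue_matrix(default_config)
        assert matrix.shape == (default_config.n_transcripts, 53)
        assert truth["query"] in truth["modules"]["TERM_M1"]
        assert truth["query"] in matrix.row_ids

    def test_noiseless_limit_within_module_r_one(self):
        cfg = SimConfig(
            seed=1,
            n_transcripts=300,
            module_specs=[ModuleSpec(size=20, a=3.0, sigma=1e-12, term_id="M")],
        )
        matrix, truth = sim_tissue_matrix(cfg)
        profile = cx.correlate_all(matrix, truth["query"])
        module_r = profile.r[truth["modules"]["M"]]
        assert (module_r > 0.999).all()

    def test_zero_loading_recovery_at_chance(self):
        cfg = SimConfig(
            seed=2,
            n_transcripts=2000,
            module_specs=[ModuleSpec(size=50, a=0.0, sigma=1.0, term_id="M")],
        )
        matrix, truth = sim_tissue_matrix(cfg)
        profile = cx.correlate_all(matrix, truth["query"])
        top = set(cx.top_percentile_set(profile, 0.02))
        recovered = np.mean([g in top for g in truth["modules"]["M"] if g != truth["query"]])
        assert recovered < 0.2

    def test_full_scale_background_is_42548(self):
        cfg = full_scale_config(seed=0)
        assert cfg.n_transcripts == 56202
        assert cfg.n_zero_rows == 13654
        assert cfg.n_transcripts - cfg.n_zero_rows == 42548

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=9, n_transcripts=500)
        m1, _ = sim_tissue_matrix(cfg)
        m2, _ = sim_tissue_matrix(SimConfig(seed=9, n_transcripts=500))
        pd.testing.assert_frame_equal(m1.values, m2.values)


@pytest.fixture(scope="module")
def net_ann():
    cfg = SimConfig(seed=13, n_transcripts=3000)
    matrix, truth = sim_tissue_matrix(cfg)
    network, annotation = sim_network_and_annotation(cfg, truth)
    return cfg, truth, network, annotation


class TestNetworkAndAnnotation:

    def test_seed_precondition_guaranteed(self, net_ann):
        cfg, truth, network, _ = net_ann
        m1 = truth["modules"]["TERM_M1"]
        eligible = [g for g in m1 if network.degree(g) >= cfg.network_spec.per_seed_degree]
        assert len(eligible) >= 10

    def test_annotation_covers_modules_plus_decoys(self, net_ann):
        cfg, truth, _, annotation = net_ann
        for term, members in truth["modules"].items():
            assert set(members) <= annotation.term_to_genes[term]
            assert len(annotation.term_to_genes[term]) > len(members)
        assert sum(t.startswith("TERM_D") for t in annotation.terms()) == 10

    def test_module_clique_when_forced(self):
        cfg = SimConfig(
            seed=3,
            n_transcripts=400,
            module_specs=[ModuleSpec(size=12, term_id="M")],
        )
        cfg.network_spec.p_within = 1.0
        cfg.network_spec.p_background = 0.0
        matrix, truth = sim_tissue_matrix(cfg)
        network, _ = sim_network_and_annotation(cfg, truth)
        m = truth["modules"]["M"]
        assert len(network) == len(m) * (len(m) - 1) // 2


class TestCnaCohort:
    def test_all_diploid_when_forced(self):
        cfg = SimConfig(seed=1, cna_spec=CnaSpec(
            types={"Only": (50, (0.0, 0.0, 1.0, 0.0, 0.0))}))
        cohort = sim_cna_cohort(cfg)
        assert (cohort.records["gistic"] == 0).all()

    def test_exact_paired_count(self):
        spec = pan_cancer_cna_spec(n_total=2000, n_paired=1803)
        cohort = sim_cna_cohort(SimConfig(seed=5, cna_spec=spec))
        assert len(cohort) == 2000
        assert len(filter_paired(cohort)) == 1803

    def test_dosage_ordering_recovered(self):
        cfg = SimConfig(seed=6, cna_spec=CnaSpec(
            types={"T": (4000, (0.1, 0.2, 0.4, 0.2, 0.1))}))
        cohort = filter_paired(sim_cna_cohort(cfg))
        out = expression_by_category(cohort)
        pooled = out[out["cancer_type"] == "All Cancer types"].set_index("gistic")
        means = pooled["mean_expression"]
        assert means[2] > means[0] > means[-2]

    def test_prevalence_matches_generating_probabilities(self):
        spec = pan_cancer_cna_spec(n_total=50000, n_paired=50000)
        cohort = sim_cna_cohort(SimConfig(seed=7, cna_spec=spec))
        table = prevalence(cohort)
        from coexnet.io import load_table3_fixture

        target = load_table3_fixture()
        target = target.drop(index="All Cancer types")
        # renormalized generating probabilities vs realized percentages
        for ctype, row in target.iterrows():
            probs = row.to_numpy(dtype=float)
            probs = 100 * probs / probs.sum()
            got = table.rows.loc[
                ctype,
                ["deep_deletion", "shallow_deletion", "diploid", "gain",
                 "amplification"],
            ].to_numpy(dtype=float)
            assert np.abs(got - probs).max() < 3.5  # ~1400 patients per type


class TestSpectralCounts:
    def test_null_config_low_candidate_rate(self):
        from coexnet.ms_diff import run_ms_diff

        cfg = SimConfig(seed=8, ms_spec=MsSpec(
            n_proteins=300, spike_fold=1.0, bait_rate_bait=5.0,
            bait_rate_control=5.0, partner_rate=5.0))
        scs, _ = sim_spectral_counts(cfg)
        called, _ = run_ms_diff(scs)
        assert called["candidate"].mean() <= 0.05

    def test_size_factors_one_normalization_nearly_identity(self):
        from coexnet.ms_diff import normalize_runs

        cfg = SimConfig(seed=9, ms_spec=MsSpec(size_factor_range=(1.0, 1.0)))
        scs, _ = sim_spectral_counts(cfg)
        norm = normalize_runs(scs)
        rel = np.abs(norm.to_numpy() - scs.counts.to_numpy())
        # totals still fluctuate stochastically, so only near-identity
        assert np.median(rel / np.maximum(scs.counts.to_numpy(), 1)) < 0.15

    def test_species_mix_present(self, default_config):
        scs, _ = sim_spectral_counts(default_config)
        assert set(scs.species) == {"Homo sapiens", "Bos taurus"}

    def test_deterministic_given_seed(self):
        s1, _ = sim_spectral_counts(SimConfig(seed=10))
        s2, _ = sim_spectral_counts(SimConfig(seed=10))
        pd.testing.assert_frame_equal(s1.counts, s2.counts)


class TestPanelAndCrn:
    def test_block_r_near_configured(self):
        cfg = SimConfig(seed=11)
        matrix, _, truth = sim_panel_and_crn(cfg)
        block = truth["blocks"]["proliferation"]
        pc = panel_correlate(matrix, block)
        r = pc.r_matrix.to_numpy()
        off = r[~np.eye(len(block), dtype=bool)]
        assert 0.7 < off.mean() < 0.9

    def test_zero_factor_config_null(self):
        cfg = SimConfig(seed=12, panel_spec=PanelSpec(
            blocks={"b": ([f"g{i}" for i in range(6)], 0.0)},
            query_block="b", n_samples=500))
        matrix, _, _ = sim_panel_and_crn(cfg)
        genes = [f"g{i}" for i in range(6)]
        pc = panel_correlate(matrix, genes)
        off = pc.r_matrix.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.abs(off).mean() < 0.1

    def test_planted_directions(self):
        cfg = SimConfig(seed=13)
        _, crn, truth = sim_panel_and_crn(cfg)
        up_calls = classify_direction(crn, truth["query"])
        assert all(v == "up" for v in up_calls.values())
        down_calls = classify_direction(crn, truth["down_gene"])
        assert all(v == "down" for v in down_calls.values())
        neut_calls = classify_direction(crn, "NEUT1")
        assert all(v == "unchanged" for v in neut_calls.values())
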