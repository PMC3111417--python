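"""Synthetic compendium generator and recovery evaluation."""

import numpy as np
import pytest
import scipy.stats

from mirhost import (
    ConfigError,
    SimulationConfig,
    evaluate_recovery,
    evaluate_surrogacy,
    run_analysis,
    simulate_compendium,
    write_compendium,
)
from mirhost.annotation import build_design
from mirhost.calibration import SurrogacyReport
from mirhost.enrichment import InteractionScore
from mirhost.expression import filter_genes, normalize_host_profile, read_expression_tsv
from mirhost.regression import fit_ulm
from mirhost.simulate import GroundTruth


def _score(host, target, significant, negative=True):
    return InteractionScore(
        host_gene_id=host, target_gene_id=target, method="ULM", n_datasets=5,
        p_real=0.001 if significant else 0.5, p_perm=0.5,
        mean_weight=0.5 if negative else -0.5, null_mean=0.0,
        sign="negative" if negative else "non-negative", significant=significant,
    )


class TestConfigValidation:
    def test_too_many_design_hosts(self):
        with pytest.raises(ConfigError, match="exceeds"):
            SimulationConfig(n_hosts=3, regulators_per_target=2, n_decoys=2)

    def test_unknown_scenario(self):
        with pytest.raises(ConfigError, match="scenario"):
            SimulationConfig(n_hosts=2, host_scenarios=["coupled", "weird"],
                             regulators_per_target=1, n_decoys=1)

    def test_scenario_length_mismatch(self):
        with pytest.raises(ConfigError, match="length"):
            SimulationConfig(n_hosts=3, host_scenarios=["coupled"],
                             regulators_per_target=1, n_decoys=1)

    def test_planted_edge_unknown_id(self):
        with pytest.raises(ConfigError, match="unknown id"):
            SimulationConfig(planted_edges=[("HOST99", "TGT001", 1.0)])

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigError, match="noise_sd"):
            SimulationConfig(noise_sd=-1.0)

    def test_json_round_trip(self, tmp_path):
        cfg = SimulationConfig(rng_seed=3, n_datasets=2, planted_edges=[("HOST01", "TGT001", 1.5)])
        cfg.to_json(tmp_path / "cfg.json")
        back = SimulationConfig.from_json(tmp_path / "cfg.json")
        assert back == cfg


class TestGenerator:
    def test_seeded_config_is_reproducible(self):
        cfg = SimulationConfig(rng_seed=11, n_datasets=3, n_background=50)
        c1, c2 = simulate_compendium(cfg), simulate_compendium(cfg)
        for d1, d2 in zip(c1.datasets, c2.datasets):
            np.testing.assert_array_equal(d1.values, d2.values)
        assert c1.truth.edges == c2.truth.edges
        c3 = simulate_compendium(SimulationConfig(rng_seed=12, n_datasets=3, n_background=50))
        assert not np.array_equal(c1.datasets[0].values, c3.datasets[0].values)

    def test_null_config_has_no_edges_and_flat_targets(self):
        cfg = SimulationConfig(rng_seed=2, n_datasets=2, regulators_per_target=0,
                               n_decoys=3, n_background=50)
        comp = simulate_compendium(cfg)
        assert comp.truth.edges == []
        ds = comp.datasets[0]
        target_rows = ds.values[cfg.n_hosts:cfg.n_hosts + cfg.n_targets]
        # pure noise around the baseline: spread bounded by a few noise sd
        assert np.abs(target_rows - cfg.baseline_mean).max() < 6 * (
            cfg.noise_sd + cfg.baseline_sd
        )

    def test_noiseless_coupled_single_edge_recovers_unit_weight(self):
        cfg = SimulationConfig(
            rng_seed=5, n_datasets=1, n_samples=10, n_hosts=2, n_targets=1,
            n_background=400, regulators_per_target=1, n_decoys=0,
            noise_sd=0.0, baseline_sd=0.0, w_range=(1.0, 1.0),
        )
        comp = simulate_compendium(cfg)
        (host, target, w) = comp.truth.edges[0]
        ds = filter_genes(comp.datasets[0])
        x = normalize_host_profile(ds, host).x
        d = ds.values.mean(axis=0) - ds.row(target)
        vec = fit_ulm(x[:, None], d, host_gene_ids=[host])
        np.testing.assert_allclose(vec.rescaled, [1.0])
        # raw weight recovers w* up to the host rows' contribution to the
        # per-sample universe mean (shrinks as the gene universe grows)
        assert vec.raw[0] == pytest.approx(w, abs=0.35)

    def test_round_robin_covers_every_host(self):
        cfg = SimulationConfig(rng_seed=1, n_datasets=1, n_hosts=5, n_targets=10,
                               regulators_per_target=1, n_decoys=1, n_background=50)
        comp = simulate_compendium(cfg)
        hosts_used = {h for h, _, _ in comp.truth.edges}
        assert hosts_used == set(comp.truth.host_scenario)

    def test_multiple_mirnas_per_host_fan_into_maps(self):
        cfg = SimulationConfig(rng_seed=1, n_datasets=1, n_hosts=3, n_targets=2,
                               regulators_per_target=1, n_decoys=1,
                               mirnas_per_host=2, n_background=40)
        comp = simulate_compendium(cfg)
        assert len(comp.host_map.records) == 6
        design = build_design("TGT001", comp.host_map, comp.target_map)
        assert all(len(v) == 2 for v in design.mirna_edges.values())

    def test_written_compendium_reloads_identically(self, tmp_path, tiny_sim):
        write_compendium(tiny_sim, tmp_path)
        ds0 = tiny_sim.datasets[0]
        back = read_expression_tsv(
            tmp_path / "expression" / f"{ds0.dataset_id}.tsv", ds0.dataset_id
        )
        assert back.gene_ids == ds0.gene_ids
        np.testing.assert_allclose(back.values, ds0.values, rtol=1e-6)
        assert (tmp_path / "host_map.tsv").exists()
        assert (tmp_path / "truth.json").exists()


class TestRecoveryMetrics:
    def test_perfect_recovery(self):
        truth = GroundTruth(edges=[("H1", "T1", 1.0)], host_scenario={"H1": "coupled",
                                                                      "H2": "coupled"})
        scores = [_score("H1", "T1", True), _score("H2", "T1", False)]
        m = evaluate_recovery(scores, truth)
        assert (m.sensitivity, m.precision, m.specificity) == (1.0, 1.0, 1.0)

    def test_empty_prediction_set(self):
        truth = GroundTruth(edges=[("H1", "T1", 1.0)], host_scenario={"H1": "coupled"})
        m = evaluate_recovery([_score("H1", "T1", False)], truth)
        assert m.sensitivity == 0.0 and np.isnan(m.precision)

    def test_id_mismatch_rejected(self):
        truth = GroundTruth(edges=[], host_scenario={"H1": "coupled"})
        with pytest.raises(ConfigError, match="not in ground truth"):
            evaluate_recovery([_score("H9", "T1", False)], truth)

    def test_surrogacy_accuracy_mapping(self):
        truth = GroundTruth(
            edges=[],
            host_scenario={"H1": "coupled", "H2": "independent_promoter"},
        )
        reports = [
            SurrogacyReport("H1", 5, 4, 4, 2.0, 100.0, "good_surrogate"),
            SurrogacyReport("H2", 5, 0, 0, float("nan"), float("nan"), "uninformative"),
        ]
        acc, per = evaluate_surrogacy(reports, truth)
        assert acc == 1.0
        assert per == {"coupled": 1.0, "independent_promoter": 1.0}


class TestStatisticalBehaviour:
    def test_planted_weights_unbiased_across_datasets(self):
        # coupled hosts, snr >= 1: per-dataset ULM raw weights average w*
        # (up to the small documented column-mean leak) within 3 SE
        cfg = SimulationConfig(rng_seed=9, n_datasets=50, w_range=(1.0, 1.0))
        comp = simulate_compendium(cfg)
        res = run_analysis(comp.datasets, comp.host_map, comp.target_map,
                           methods=("ULM",), rng_seed=9)
        planted = comp.truth.edge_pairs
        raw = []
        for vec in res.per_method["ULM"].fits.real_vectors:
            for h, w in zip(vec.host_gene_ids, vec.raw):
                if (h, vec.target_gene_id) in planted:
                    raw.append(w)
        raw = np.asarray(raw)
        se = raw.std() / np.sqrt(raw.size)
        assert abs(raw.mean() - 1.0) < 3 * se + 0.25

    def test_scenario_separation(self):
        # coupled hosts give enriched small p on their true targets while
        # independent-promoter hosts stay at the null
        scen = ["coupled"] * 3 + ["independent_promoter"] * 3
        cfg = SimulationConfig(rng_seed=4, n_datasets=30, n_hosts=6, n_targets=12,
                               regulators_per_target=1, n_decoys=1,
                               host_scenarios=scen, w_range=(1.0, 1.0))
        comp = simulate_compendium(cfg)
        res = run_analysis(comp.datasets, comp.host_map, comp.target_map,
                           methods=("ULM",), rng_seed=4)
        planted = comp.truth.edge_pairs
        coupled_p, indep_p = [], []
        for s in res.per_method["ULM"].scores:
            if (s.host_gene_id, s.target_gene_id) not in planted:
                continue
            scenario = comp.truth.host_scenario[s.host_gene_id]
            (coupled_p if scenario == "coupled" else indep_p).append(s.p_real)
        assert np.median(coupled_p) < 0.01
        assert scipy.stats.kstest(indep_p, "uniform").pvalue > 0.01

    def test_ulm_beats_corr_sensitivity_on_paired_seeds(self):
        # paired ULM/CORR comparison at matched (100% predicted) specificity
        sens = {"ULM": [], "CORR": []}
        for seed in (1, 2, 3):
            cfg = SimulationConfig(rng_seed=seed, w_range=(1.0, 1.0))
            comp = simulate_compendium(cfg)
            res = run_analysis(comp.datasets, comp.host_map, comp.target_map,
                               methods=("ULM", "CORR"), cutoff_mode="roc",
                               target_specificity=1.0, rng_seed=seed)
            for m in ("ULM", "CORR"):
                sens[m].append(
                    evaluate_recovery(res.per_method[m].scores, comp.truth).sensitivity
                )
        assert np.mean(sens["ULM"]) > np.mean(sens["CORR"])
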