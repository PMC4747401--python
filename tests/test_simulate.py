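from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from crgpipe import (
    GeneratorConfig,
    GroundTruth,
    generate_cellline_experiment,
    generate_clinical_cohorts,
    make_truth,
)


class TestGeneratorConfig:
    def test_class_sizes_validated(self):
        with pytest.raises(ValueError, match="n_genes"):
            GeneratorConfig(seed=1, n_genes=100, n_resistance_shared=50,
                            n_resistance_specific=50, n_drug_response=50, n_basal=0)
        with pytest.raises(ValueError, match="n_stratum"):
            GeneratorConfig(seed=1, n_stratum=1000)

    def test_truth_class_counts(self, small_config):
        truth = make_truth(small_config)
        counts = truth.table["gene_class"].value_counts()
        assert counts["resistance"] == 30 + 30 * 2
        assert counts["drug_response"] == 80
        assert counts["basal_difference"] == 40
        assert truth.table["stratum"].sum() == 10
        # shared resistance genes carry the same direction for both drugs
        shared = truth.table[
            (truth.table["res_dir_5-FU"] != 0) & (truth.table["res_dir_L-OHP"] != 0)
        ]
        assert (shared["res_dir_5-FU"] == shared["res_dir_L-OHP"]).all()


class TestCellLineExperiment:
    def test_bit_identical_for_same_config(self, small_config):
        m1, _ = generate_cellline_experiment(small_config, "5-FU")
        m2, _ = generate_cellline_experiment(small_config, "5-FU")
        pd.testing.assert_frame_equal(m1.values, m2.values)
        # but different drugs / seeds differ
        m3, _ = generate_cellline_experiment(small_config, "L-OHP")
        assert not m1.values.equals(m3.values)

    def test_design_layout(self, small_config, small_experiment):
        matrix, _ = small_experiment
        cfg = small_config
        treated_times = [t for t in cfg.time_points if t > 0]
        expected = 2 * (1 + len(treated_times)) * cfg.n_replicates
        assert matrix.n_samples == expected
        assert matrix.scale == "linear"
        for line in ("parental", "resistant"):
            assert len(matrix.sample_ids(resistance_status=line, drug="none")) == cfg.n_replicates
            for t in treated_times:
                assert (
                    len(matrix.sample_ids(resistance_status=line, drug="5-FU",
                                          treatment_time_h=t))
                    == cfg.n_replicates
                )

    def test_resistance_effect_only_in_treated_resistant_arm(self, small_config):
        cfg = replace(small_config, noise_sd_log2=1e-6)
        truth = make_truth(cfg)
        matrix, _ = generate_cellline_experiment(cfg, "5-FU", truth)
        gene = [
            g for g in truth.resistance_genes("5-FU")
            if truth.table.loc[g, "gene_class"] == "resistance"
            and truth.table.loc[g, "res_dir_L-OHP"] == 0  # 5-FU-specific
        ][0]
        log2 = np.log2(matrix.values.loc[gene])
        untr_p = log2[matrix.sample_ids(resistance_status="parental", drug="none")].mean()
        untr_r = log2[matrix.sample_ids(resistance_status="resistant", drug="none")].mean()
        tr_p = log2[matrix.sample_ids(resistance_status="parental", drug="5-FU",
                                      treatment_time_h=24)].mean()
        tr_r = log2[matrix.sample_ids(resistance_status="resistant", drug="5-FU",
                                      treatment_time_h=24)].mean()
        direction = truth.table.loc[gene, "res_dir_5-FU"]
        assert untr_r - untr_p == pytest.approx(0.0, abs=1e-4)
        assert tr_p - untr_p == pytest.approx(0.0, abs=1e-4)
        assert tr_r - tr_p == pytest.approx(direction * cfg.resistance_effect, abs=1e-4)

    def test_drug_response_transient_and_imprinted(self, small_config):
        cfg = replace(small_config, noise_sd_log2=1e-6)
        truth = make_truth(cfg)
        matrix, _ = generate_cellline_experiment(cfg, "5-FU", truth)
        gene = truth.genes_of_class("drug_response")[0]
        direction = truth.table.loc[gene, "dr_dir"]
        log2 = np.log2(matrix.values.loc[gene]) * direction
        untr_p = log2[matrix.sample_ids(resistance_status="parental", drug="none")].mean()
        peak = log2[matrix.sample_ids(resistance_status="parental", drug="5-FU",
                                      treatment_time_h=cfg.drug_response_t_peak)].mean()
        late = log2[matrix.sample_ids(resistance_status="parental", drug="5-FU",
                                      treatment_time_h=24)].mean()
        untr_r = log2[matrix.sample_ids(resistance_status="resistant", drug="none")].mean()
        assert peak - untr_p == pytest.approx(cfg.drug_response_effect, abs=1e-4)
        assert 0 < late - untr_p < peak - untr_p  # decayed by 24 h
        # chronic imprint: the untreated resistant line already carries it
        assert untr_r - untr_p == pytest.approx(
            cfg.chronic_imprint * cfg.drug_response_effect, abs=1e-4
        )

    def test_null_baseline_distribution(self):
        cfg = GeneratorConfig(seed=4)  # default 5000 genes
        truth = make_truth(cfg)
        nulls = truth.table.loc[truth.table["gene_class"] == "null", "baseline_log2"]
        stat = kstest(
            nulls, "norm", args=(cfg.baseline_mean_log2, cfg.baseline_sd_log2)
        )
        assert stat.pvalue > 0.01


class TestClinicalCohorts:
    def test_cohort_layout_and_determinism(self, small_config):
        truth = make_truth(small_config)
        pre1, post1 = generate_clinical_cohorts(small_config, truth)
        pre2, post2 = generate_clinical_cohorts(small_config, truth)
        pd.testing.assert_frame_equal(pre1.values, pre2.values)
        pd.testing.assert_frame_equal(post1.values, post2.values)
        sizes = small_config.clinical_datasets
        assert pre1.n_samples == sum(r + n for r, n in sizes)
        assert set(pre1.samples["cohort"]) == {"pre_chemo"}
        assert set(post1.samples["cohort"]) == {"post_chemo"}
        assert len(set(pre1.samples["dataset_id"])) == len(sizes)

    def test_nonresponders_carry_attenuated_resistance_signal(self, small_config):
        cfg = replace(small_config, noise_sd_log2=1e-6, heterogeneity_sd=1e-6,
                      batch_sd=0.0, clinical_datasets=((6, 6),))
        truth = make_truth(cfg)
        pre, _ = generate_clinical_cohorts(cfg, truth, regimen_drugs=("5-FU",))
        gene = [
            g for g in truth.resistance_genes("5-FU")
            if not truth.table.loc[g, "stratum"]
            and truth.table.loc[g, "res_dir_L-OHP"] == 0
        ][0]
        log2 = np.log2(pre.values.loc[gene])
        diff = (
            log2[pre.sample_ids(response="non_responder")].mean()
            - log2[pre.sample_ids(response="responder")].mean()
        )
        expected = (
            truth.table.loc[gene, "res_dir_5-FU"]
            * cfg.attenuation
            * cfg.resistance_effect
        )
        assert diff == pytest.approx(expected, abs=1e-3)

    def test_zero_attenuation_removes_clinical_signal(self, small_config):
        cfg = replace(small_config, attenuation=0.0, clinical_datasets=((6, 6),))
        truth = make_truth(cfg)
        pre, _ = generate_clinical_cohorts(cfg, truth)
        nr = pre.sample_ids(response="non_responder")
        r = pre.sample_ids(response="responder")
        log2 = np.log2(pre.values)
        diffs = log2[nr].mean(axis=1) - log2[r].mean(axis=1)
        planted = truth.resistance_genes("5-FU")
        assert diffs.loc[planted].abs().max() < 1.0  # noise scale only

    def test_unknown_regimen_drug_rejected(self, small_config):
        truth = make_truth(small_config)
        with pytest.raises(ValueError, match="unknown"):
            generate_clinical_cohorts(small_config, truth, regimen_drugs=("nope",))


class TestGroundTruthIO:
    def test_round_trip(self, small_config, tmp_path):
        truth = make_truth(small_config)
        path = tmp_path / "truth.tsv"
        truth.to_tsv(path)
        back = GroundTruth.from_tsv(path)
        assert back.drugs == truth.drugs
        pd.testing.assert_frame_equal(back.table, truth.table)
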