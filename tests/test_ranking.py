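import numpy as np
import pandas as pd
import pytest

from crgpipe import (
    DirectionalGeneSet,
    compute_ad,
    compute_fc,
    define_gene_class,
    expression_bias_report,
    top_n,
    two_drug_intersection,
)
from conftest import random_linear_matrix


class TestComputeFC:
    def test_definition(self, toy_matrix):
        rl = compute_fc(toy_matrix, ["a1", "a2"], ["b1", "b2"])
        # g1: mean_A=200, mean_B=100 -> FC 2, up
        assert rl.table.loc["g1", "stat"] == pytest.approx(2.0)
        assert rl.table.loc["g1", "direction"] == "up"
        # g3: equal means -> FC 1, none
        assert rl.table.loc["g3", "stat"] == pytest.approx(1.0)
        assert rl.table.loc["g3", "direction"] == "none"
        # g2: 20 vs 20 -> none; g4: 8 vs 4 -> up
        assert rl.table.loc["g4", "direction"] == "up"

    def test_against_loop_oracle(self):
        m = random_linear_matrix(50, {"a": 3, "b": 2}, seed=5)
        rl = compute_fc(m, ["a0", "a1", "a2"], ["b0", "b1"])
        for gene in m.feature_ids:
            mean_a = sum(m.values.loc[gene, f"a{i}"] for i in range(3)) / 3
            mean_b = sum(m.values.loc[gene, f"b{i}"] for i in range(2)) / 2
            assert rl.table.loc[gene, "stat"] == pytest.approx(mean_a / mean_b)

    def test_empty_group_is_error(self, toy_matrix):
        with pytest.raises(ValueError, match="non-empty"):
            compute_fc(toy_matrix, [], ["b1"])


class TestComputeAD:
    def test_definition(self, toy_matrix):
        rl = compute_ad(toy_matrix, ["a1", "a2"], ["b1", "b2"])
        assert rl.table.loc["g1", "stat"] == pytest.approx(100.0)
        assert rl.table.loc["g1", "direction"] == "up"
        assert rl.table.loc["g3", "stat"] == pytest.approx(0.0)
        assert rl.table.loc["g3", "direction"] == "none"

    def test_sign_concordance_with_fc(self):
        # For positive group means, AD > 0 iff FC > 1, gene by gene.
        m = random_linear_matrix(200, {"a": 3, "b": 3}, seed=6)
        ga, gb = ["a0", "a1", "a2"], ["b0", "b1", "b2"]
        fc = compute_fc(m, ga, gb).table["stat"].sort_index()
        ad = compute_ad(m, ga, gb).table["stat"].sort_index()
        assert ((ad > 0) == (fc > 1)).all()
        assert ((ad < 0) == (fc < 1)).all()

    def test_group_swap_inverts_statistics(self):
        m = random_linear_matrix(30, {"a": 2, "b": 2}, seed=7)
        ga, gb = ["a0", "a1"], ["b0", "b1"]
        fc_ab = compute_fc(m, ga, gb).table
        fc_ba = compute_fc(m, gb, ga).table
        np.testing.assert_allclose(fc_ab["stat"], 1.0 / fc_ba["stat"])
        ad_ab = compute_ad(m, ga, gb).table
        ad_ba = compute_ad(m, gb, ga).table
        np.testing.assert_allclose(ad_ab["stat"], -ad_ba["stat"])
        flipped = {"up": "down", "down": "up", "none": "none"}
        assert (ad_ab["direction"].map(flipped) == ad_ba["direction"]).all()


class TestTopN:
    def _toy_list(self):
        m = random_linear_matrix(5, {"a": 1, "b": 1}, seed=8)
        m.values["a0"] = [90.0, 3.0, 50.0, 7.0, 1.0]
        m.values["b0"] = [10.0, 21.0, 10.0, 21.0, 1.0]
        # FC magnitudes: 9, 7, 5, 3, 1(none)
        return compute_fc(m, ["a0"], ["b0"])

    def test_top_by_magnitude(self):
        rl = self._toy_list()
        top3 = top_n(rl, 3)
        assert top3.genes == {"g0000", "g0001", "g0002"}
        assert top3.members["g0001"] == "down"

    def test_all_directional_genes_returned(self):
        rl = self._toy_list()
        assert len(top_n(rl, 4)) == 4  # g0004 has direction none

    def test_overflow_is_error(self):
        with pytest.raises(ValueError, match="directional"):
            top_n(self._toy_list(), 5)

    def test_idempotent_and_order_invariant(self):
        m = random_linear_matrix(40, {"a": 2, "b": 2}, seed=9)
        rl = compute_fc(m, ["a0", "a1"], ["b0", "b1"])
        first = top_n(rl, 10)
        # re-rank a shuffled copy of the matrix rows
        shuffled = m.subset_genes(list(np.random.default_rng(0).permutation(m.feature_ids)))
        rl2 = compute_fc(shuffled, ["a0", "a1"], ["b0", "b1"])
        assert top_n(rl2, 10).members == first.members
        # selecting again from the selected genes changes nothing
        sub = m.subset_genes(sorted(first.genes))
        rl3 = compute_fc(sub, ["a0", "a1"], ["b0", "b1"])
        assert top_n(rl3, 10).members == first.members


class TestTwoDrugIntersection:
    def test_definition(self):
        s1 = DirectionalGeneSet("x", {"A": "up", "B": "down", "C": "up"})
        s2 = DirectionalGeneSet("y", {"A": "up", "B": "up", "D": "down"})
        assert two_drug_intersection(s1, s2).members == {"A": "up"}

    def test_identity_and_disjoint(self):
        s = DirectionalGeneSet("x", {"A": "up", "B": "down"})
        assert two_drug_intersection(s, s).members == s.members
        other = DirectionalGeneSet("y", {"C": "up"})
        assert len(two_drug_intersection(s, other)) == 0


class TestDefineGeneClass:
    def test_planted_genes_dominate_lists(self, small_config, small_experiment):
        matrix, truth = small_experiment
        planted = set(truth.resistance_genes("5-FU"))
        id24 = define_gene_class(matrix, "ID", "5-FU", 24, "fc", len(planted))
        assert len(id24.genes & planted) / len(planted) > 0.6
        bd = define_gene_class(matrix, "BD", "5-FU", None, "fc", 80)
        confounders = set(truth.genes_of_class("drug_response")) | set(
            truth.genes_of_class("basal_difference")
        )
        assert len(bd.genes & confounders) / len(bd) > 0.9

    def test_null_generator_directions_balanced(self, small_config):
        from dataclasses import replace
        from crgpipe import generate_cellline_experiment, make_truth

        null_cfg = replace(
            small_config,
            seed=21,
            resistance_effect=0.0,
            stratum_effect=0.0,
            drug_response_effect=0.0,
            basal_effect=0.0,
        )
        matrix, _ = generate_cellline_experiment(null_cfg, "5-FU", make_truth(null_cfg))
        bd = define_gene_class(matrix, "BD", "5-FU", None, "fc", 400)
        frac_up = sum(d == "up" for d in bd.members.values()) / len(bd)
        assert 0.4 < frac_up < 0.6

    def test_missing_condition_is_error(self, small_experiment):
        matrix, _ = small_experiment
        with pytest.raises(ValueError, match="no samples"):
            define_gene_class(matrix, "ID", "no-such-drug", 24, "fc", 10)
        with pytest.raises(ValueError, match="treatment time"):
            define_gene_class(matrix, "IP", "5-FU", None, "fc", 10)


class TestExpressionBias:
    def test_identical_sets_give_empty_exclusives(self, toy_matrix):
        s = DirectionalGeneSet("x", {"g1": "up"})
        rep = expression_bias_report(s, s, toy_matrix, ["a1", "a2"], ["b1", "b2"])
        assert rep.exclusive_x == [] and rep.exclusive_y == []

    def test_means_match_loop_oracle(self, toy_matrix):
        sx = DirectionalGeneSet("FC", {"g1": "up", "g2": "down"})
        sy = DirectionalGeneSet("AD", {"g1": "up", "g4": "up"})
        rep = expression_bias_report(
            sx, sy, toy_matrix, ["a1", "a2"], ["b1", "b2"],
            group_a_label="A", group_b_label="B",
        )
        assert rep.exclusive_x == ["g2"] and rep.exclusive_y == ["g4"]
        assert rep.mean_expr_x["A"] == pytest.approx((10 + 30) / 2)
        assert rep.mean_expr_x["B"] == pytest.approx(20.0)
        assert rep.mean_expr_y["A"] == pytest.approx(8.0)
        assert rep.mean_expr_y["B"] == pytest.approx(4.0)

    def test_high_expression_stratum_shows_ad_bias(self, small_experiment):
        matrix, truth = small_experiment
        fc = define_gene_class(matrix, "ID", "5-FU", 24, "fc", 60)
        ad = define_gene_class(matrix, "ID", "5-FU", 24, "ad", 60)
        ga = matrix.sample_ids(resistance_status="resistant", drug="5-FU", treatment_time_h=24)
        gb = matrix.sample_ids(resistance_status="parental", drug="5-FU", treatment_time_h=24)
        rep = expression_bias_report(fc, ad, matrix, ga, gb, "A", "B")
        assert rep.mean_expr_y["A"] > rep.mean_expr_x["A"]
        stratum = set(truth.table.index[truth.table["stratum"]])
        assert stratum & set(rep.exclusive_y)
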