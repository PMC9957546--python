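import numpy as np
import pandas as pd
import pytest
from oracles import clr_oracle

import grninfer as g
from grninfer.containers import ScoreMatrix
from grninfer.inference import clr_from_mi, mutual_information_matrix


def expression(rows, genes, conditions=None):
    rows = np.asarray(rows, dtype=float)
    conditions = conditions or [f"c{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=conditions)


class TestCoexpression:
    def test_perfect_linear_dependence_scores_one(self, rng):
        tf = rng.normal(size=50)
        expr = expression([tf, 2 * tf + 1], ["TF", "TG"])
        sm = g.score_coexpression(expr, ["TF"], "pr")
        assert sm.scores.at["TF", "TG"] == pytest.approx(1.0)

    def test_independent_noise_scores_low(self):
        rng = np.random.default_rng(123)
        expr = expression(rng.normal(size=(2, 1000)), ["TF", "TG"])
        sm = g.score_coexpression(expr, ["TF"], "pr")
        assert sm.scores.at["TF", "TG"] < 0.1

    def test_spearman_invariant_to_monotone_maps(self, rng):
        tf = rng.normal(size=40)
        expr = expression([tf, np.exp(tf)], ["TF", "TG"])
        spearman = g.score_coexpression(expr, ["TF"], "sr").scores.at["TF", "TG"]
        pearson = g.score_coexpression(expr, ["TF"], "pr").scores.at["TF", "TG"]
        assert spearman == pytest.approx(1.0)
        assert pearson < 1.0

    @pytest.mark.parametrize("statistic", ["pr", "sr", "kt"])
    def test_scores_bounded_and_symmetric_between_tfs(self, statistic, rng):
        expr = expression(rng.normal(size=(4, 30)), ["A", "B", "C", "D"])
        sm = g.score_coexpression(expr, ["A", "B"], statistic)
        values = sm.scores.to_numpy()
        finite = values[np.isfinite(values)]
        assert (finite >= 0).all() and (finite <= 1).all()
        assert sm.scores.at["A", "B"] == pytest.approx(sm.scores.at["B", "A"])

    def test_constant_gene_scores_zero_with_warning(self, rng):
        expr = expression([rng.normal(size=20), np.full(20, 3.0)], ["TF", "flat"])
        with pytest.warns(RuntimeWarning, match="constant gene"):
            sm = g.score_coexpression(expr, ["TF"], "pr")
        assert sm.scores.at["TF", "flat"] == 0.0

    def test_too_few_conditions_is_an_error(self):
        expr = expression([[1.0, 2.0], [2.0, 1.0]], ["A", "B"])
        with pytest.raises(ValueError, match="at least 3 conditions"):
            g.score_coexpression(expr, ["A"], "pr")


class TestCLR:
    def test_matches_brute_force_on_random_mi_matrices(self, rng):
        for _ in range(20):
            mi = pd.DataFrame(
                rng.uniform(0, 1, size=(4, 4)),
                index=["t1", "t2", "t3", "t4"],
                columns=["g1", "g2", "g3", "g4"],
            )
            np.testing.assert_allclose(
                clr_from_mi(mi).to_numpy(), clr_oracle(mi.to_numpy()), atol=1e-9
            )

    def test_equal_mi_gives_all_zero_scores(self):
        mi = pd.DataFrame(np.full((3, 3), 0.4), index=list("abc"), columns=list("xyz"))
        assert (clr_from_mi(mi).to_numpy() == 0).all()

    def test_outstanding_pair_is_strictly_maximal(self):
        mi = pd.DataFrame(
            [[0.9, 0.1], [0.1, 0.1]], index=["t1", "t2"], columns=["g1", "g2"]
        )
        scores = clr_from_mi(mi)
        top = scores.at["t1", "g1"]
        others = scores.to_numpy()[scores.to_numpy() != top]
        assert (top > others).all()

    def test_hand_computed_two_by_two(self):
        # row/col stats of [[0.9,0.1],[0.1,0.1]]: both strata of the (t1,g1)
        # cell have mean 0.5 and sd 0.4, so z=1 twice -> score sqrt(2)
        mi = pd.DataFrame(
            [[0.9, 0.1], [0.1, 0.1]], index=["t1", "t2"], columns=["g1", "g2"]
        )
        scores = clr_from_mi(mi)
        assert scores.at["t1", "g1"] == pytest.approx(np.sqrt(2.0))
        assert scores.at["t2", "g2"] == 0.0

    def test_end_to_end_excludes_self_links(self, small_dataset):
        grn, expr, _ = small_dataset
        sm = g.score_clr(expr, grn.tf_ids)
        assert np.isnan(sm.scores.at[grn.tf_ids[0], grn.tf_ids[0]])
        finite = sm.scores.to_numpy()[np.isfinite(sm.scores.to_numpy())]
        assert (finite >= 0).all()

    def test_mi_matrix_detects_dependence(self, rng):
        tf = rng.normal(size=200)
        expr = expression([tf, tf + rng.normal(0, 0.1, 200), rng.normal(size=200)],
                          ["TF", "linked", "noise"])
        mi = mutual_information_matrix(expr, ["TF"], ["linked", "noise"])
        assert mi.at["TF", "linked"] > mi.at["TF", "noise"]


class TestFeatureImportance:
    def test_bayesian_ridge_recovers_the_linear_regulator(self):
        rng = np.random.default_rng(5)
        tf1 = rng.normal(size=200)
        tf2 = rng.normal(size=200)
        tg = 3 * tf1 + rng.normal(0, 0.01, size=200)
        expr = expression([tf1, tf2, tg], ["TF1", "TF2", "TG"])
        sm = g.score_feature_importance(expr, ["TF1", "TF2"], "brsr")
        assert sm.scores.at["TF1", "TG"] > 10 * sm.scores.at["TF2", "TG"]

    @pytest.mark.parametrize("model", ["rfr", "xrtr", "gbr", "abr"])
    def test_tree_regressor_importances_sum_to_one(self, model, small_dataset):
        grn, expr, _ = small_dataset
        cfg = g.MethodConfig(seed=1, n_estimators=20)
        sm = g.score_feature_importance(
            expr, grn.tf_ids, model, config=cfg, targets=grn.tg_ids[:4]
        )
        sums = np.nansum(sm.scores.to_numpy(), axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_single_predictor_gets_full_importance(self, rng):
        # B is both TF and target, so A is its only predictor
        expr = expression(rng.normal(size=(2, 30)), ["A", "B"])
        sm = g.score_feature_importance(expr, ["A", "B"], "rfr",
                                        config=g.MethodConfig(seed=0, n_estimators=10))
        assert sm.scores.at["A", "B"] == pytest.approx(1.0)

    def test_separable_classification_ranks_the_informative_tf_first(self):
        rng = np.random.default_rng(9)
        tf1 = rng.normal(size=120)
        tf2 = rng.normal(size=120)
        tg = (tf1 > 0).astype(float)
        expr = expression([tf1, tf2, tg], ["TF1", "TF2", "TG"])
        cfg = g.MethodConfig(seed=2, n_estimators=30, n_levels=2)
        sm = g.score_feature_importance(expr, ["TF1", "TF2"], "rfc", config=cfg)
        assert sm.scores.at["TF1", "TG"] > sm.scores.at["TF2", "TG"]

    def test_single_class_target_scores_zero_with_warning(self, rng):
        expr = expression([rng.normal(size=20), rng.normal(size=20), np.full(20, 2.0)],
                          ["TF1", "TF2", "flat"])
        with pytest.warns(RuntimeWarning, match="single-class"):
            sm = g.score_feature_importance(
                expr, ["TF1", "TF2"], "rfc", config=g.MethodConfig(n_estimators=10)
            )
        assert (sm.scores["flat"] == 0).all()

    @pytest.mark.parametrize("model", ["svmc", "cnbc", "abc"])
    def test_classifier_scores_are_nonnegative(self, model, small_dataset):
        grn, expr, _ = small_dataset
        cfg = g.MethodConfig(seed=3, n_estimators=10)
        sm = g.score_feature_importance(
            expr, grn.tf_ids, model, config=cfg, targets=grn.tg_ids[:3]
        )
        assert (np.nan_to_num(sm.scores.to_numpy()) >= 0).all()


class TestStabilitySelection:
    def test_exact_copy_is_always_selected(self, rng):
        tf1 = rng.normal(size=40)
        tf2 = rng.normal(size=40)
        expr = expression([tf1, tf2, tf1.copy()], ["TF1", "TF2", "TG"])
        cfg = g.MethodConfig(seed=0, n_resamples=50, n_lars_steps=1)
        sm = g.score_stability_selection(expr, ["TF1", "TF2"], "tigress", config=cfg)
        assert sm.scores.at["TF1", "TG"] == pytest.approx(1.0)

    def test_uncorrelated_tf_rarely_selected(self):
        rng = np.random.default_rng(21)
        tf1 = rng.normal(size=300)
        decoy = rng.normal(size=300)
        tg = tf1 + rng.normal(0, 0.1, size=300)
        expr = expression([tf1, decoy, tg], ["TF1", "decoy", "TG"])
        cfg = g.MethodConfig(seed=4, n_resamples=50, n_lars_steps=1)
        sm = g.score_stability_selection(expr, ["TF1", "decoy"], "tigress", config=cfg)
        assert sm.scores.at["decoy", "TG"] < 0.2

    @pytest.mark.parametrize("variant", ["tigress", "srl"])
    def test_scores_are_selection_frequencies(self, variant, small_dataset):
        grn, expr, _ = small_dataset
        cfg = g.MethodConfig(seed=5, n_resamples=16)
        sm = g.score_stability_selection(
            expr, grn.tf_ids, variant, config=cfg, targets=grn.tg_ids[:5]
        )
        values = sm.scores.to_numpy()
        finite = values[np.isfinite(values)]
        assert (finite >= 0).all() and (finite <= 1).all()
        np.testing.assert_allclose(finite * 16, np.round(finite * 16), atol=1e-12)

    def test_lars_steps_clamped_with_warning(self, rng):
        expr = expression(rng.normal(size=(3, 30)), ["A", "B", "TG"])
        cfg = g.MethodConfig(seed=0, n_resamples=4, n_lars_steps=10)
        with pytest.warns(RuntimeWarning, match="clamped"):
            g.score_stability_selection(expr, ["A", "B"], "tigress", config=cfg)


class TestScorerContracts:
    @pytest.mark.parametrize("method", ["pr", "clr", "rfr", "tigress"])
    def test_deterministic_given_seed(self, method, small_dataset):
        grn, expr, _ = small_dataset
        cfg = g.MethodConfig(seed=8, n_estimators=15, n_resamples=8)
        first = g.score_links(expr, grn.tf_ids, method, config=cfg, targets=grn.tg_ids[:6])
        second = g.score_links(expr, grn.tf_ids, method, config=cfg, targets=grn.tg_ids[:6])
        pd.testing.assert_frame_equal(first.scores, second.scores)

    @pytest.mark.parametrize("method", ["pr", "rfr"])
    def test_invariant_to_gene_row_order(self, method, small_dataset):
        grn, expr, _ = small_dataset
        cfg = g.MethodConfig(seed=8, n_estimators=15)
        shuffled = expr.sample(frac=1.0, random_state=2)
        first = g.score_links(expr, grn.tf_ids, method, config=cfg, targets=grn.tg_ids[:6])
        second = g.score_links(shuffled, grn.tf_ids, method, config=cfg, targets=grn.tg_ids[:6])
        pd.testing.assert_frame_equal(first.scores, second.scores)

    def test_requested_frame_is_returned_with_self_links_excluded(self, small_dataset):
        grn, expr, _ = small_dataset
        sm = g.score_links(expr, grn.tf_ids, "pr")
        assert sm.tf_ids == grn.tf_ids
        assert sm.tg_ids == list(expr.index)
        for tf in grn.tf_ids:
            assert np.isnan(sm.scores.at[tf, tf])


class TestScoresToEdges:
    def test_sorted_with_exclusion(self):
        frame = pd.DataFrame(
            [[0.9, 0.2], [0.5, np.nan]], index=["tf1", "x"], columns=["tg1", "x"]
        )
        edges = g.scores_to_edges(ScoreMatrix(frame, "toy"))
        assert list(map(tuple, edges.itertuples(index=False))) == [
            ("tf1", "tg1", 0.9),
            ("x", "tg1", 0.5),
            ("tf1", "x", 0.2),
        ]

    def test_ties_break_lexically(self):
        frame = pd.DataFrame(
            np.full((2, 2), 0.5), index=["b", "a"], columns=["y", "x"]
        )
        edges = g.scores_to_edges(ScoreMatrix(frame, "toy"))
        assert list(map(tuple, edges[["tf", "tg"]].itertuples(index=False))) == [
            ("a", "x"), ("a", "y"), ("b", "x"), ("b", "y"),
        ]

    def test_self_links_never_emitted(self, small_dataset):
        grn, expr, _ = small_dataset
        edges = g.scores_to_edges(g.score_links(expr, grn.tf_ids, "pr"))
        assert not (edges["tf"] == edges["tg"]).any()
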