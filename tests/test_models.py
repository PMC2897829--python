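import numpy as np
import pandas as pd
import pytest

from cnvclass import models
from cnvclass.genome_io import DGVRecord, ValidationError
from cnvclass.models import (
    ConfusionCounts,
    EvaluationReport,
    adhoc_dgv_rule,
    evaluate,
    load_model,
    predict_published_tree,
    save_model,
    train_cart,
    train_rf,
    univariate_screen,
)
from conftest import make_candidate


def fv(**kw):
    base = {
        "database_score": 0.0, "length_bp": 100_000, "overlap_pct": 0.0,
        "matching_bkpt_pct": 0.0, "relative_height": 1.0,
    }
    base.update(kw)
    return base


class TestPublishedTrees:
    @pytest.mark.parametrize("tree,vec,expected", [
        # smoothed CBS, full model
        ("cbs_smoothed_full", fv(database_score=3.0), "CNV"),
        ("cbs_smoothed_full", fv(database_score=2.45), "CNV"),  # inclusive split
        ("cbs_smoothed_full", fv(database_score=1.0, length_bp=20_000), "CNV"),
        ("cbs_smoothed_full", fv(database_score=1.0, length_bp=100_000,
                                 overlap_pct=0.10), "CNA"),
        ("cbs_smoothed_full", fv(database_score=1.0, length_bp=100_000,
                                 overlap_pct=0.37), "CNV"),
        ("cbs_smoothed_full", fv(database_score=1.0, length_bp=30_000), "CNA"),
        # GLAD full: high score needs relative height; low score needs overlap
        ("glad_full", fv(database_score=3.0, relative_height=2.0), "CNV"),
        ("glad_full", fv(database_score=3.0, relative_height=1.5), "CNA"),
        ("glad_full", fv(database_score=2.9, overlap_pct=0.38), "CNV"),
        ("glad_full", fv(database_score=2.9, overlap_pct=0.30), "CNA"),
        # unsmoothed CBS full
        ("cbs_unsmoothed_full", fv(matching_bkpt_pct=0.02, length_bp=100_000), "CNV"),
        ("cbs_unsmoothed_full", fv(matching_bkpt_pct=0.02, length_bp=500_000,
                                   database_score=4.5), "CNV"),
        ("cbs_unsmoothed_full", fv(matching_bkpt_pct=0.02, length_bp=500_000,
                                   database_score=4.0), "CNA"),
        ("cbs_unsmoothed_full", fv(length_bp=10_000), "CNV"),
        ("cbs_unsmoothed_full", fv(length_bp=50_000, database_score=1.3), "CNV"),
        ("cbs_unsmoothed_full", fv(length_bp=50_000, database_score=1.2), "CNA"),
        ("cbs_unsmoothed_full", fv(length_bp=200_000, database_score=3.1), "CNV"),
        ("cbs_unsmoothed_full", fv(length_bp=200_000, database_score=3.0), "CNA"),
        # score-only stumps
        ("cbs_smoothed_dgv_only", fv(database_score=2.45), "CNV"),
        ("cbs_smoothed_dgv_only", fv(database_score=2.44), "CNA"),
        ("glad_dgv_only", fv(database_score=3.0), "CNV"),
        ("glad_dgv_only", fv(database_score=2.9), "CNA"),
    ])
    def test_printed_rules(self, tree, vec, expected):
        assert predict_published_tree(vec, tree) == expected

    def test_pure_function_and_overlap_rebinding(self):
        vec = fv(database_score=1.0, length_bp=100_000,
                 overlap_pct=0.0, matching_bkpt_pct=0.40)
        assert predict_published_tree(vec, "cbs_smoothed_full") == "CNA"
        assert predict_published_tree(
            vec, "cbs_smoothed_full", overlap_feature="matching_bkpt_pct") == "CNV"

    def test_incomplete_vector_rejected(self):
        with pytest.raises(ValidationError):
            predict_published_tree({"length_bp": 1000}, "cbs_smoothed_full")
        with pytest.raises(ValidationError):
            predict_published_tree(fv(), "no_such_tree")


class TestAdhocRule:
    def _dgv(self):
        return [
            DGVRecord("V1", "1", 100_000, 150_000, "studyA"),
            DGVRecord("V2", "1", 120_000, 160_000, "studyA"),
            DGVRecord("V3", "1", 130_000, 170_000, "studyA"),
            DGVRecord("V4", "1", 140_000, 180_000, "studyB"),
        ]

    def test_single_study_is_cna(self):
        cand = make_candidate(start=100_000, end=135_000)
        assert adhoc_dgv_rule(cand, self._dgv()[:3]) == "CNA"

    def test_two_studies_is_cnv(self):
        cand = make_candidate(start=100_000, end=150_000)
        assert adhoc_dgv_rule(cand, self._dgv()) == "CNV"

    def test_no_overlap_is_cna(self):
        cand = make_candidate(start=900_000, end=950_000)
        assert adhoc_dgv_rule(cand, self._dgv()) == "CNA"


class TestEvaluate:
    def test_pooled_accuracy_from_confusion_counts(self):
        rep = EvaluationReport.from_counts(ConfusionCounts(tn=654, fn=54, fp=182, tp=793))
        assert round(rep.accuracy, 2) == 0.86

    def test_predictive_values(self):
        rep = EvaluationReport.from_counts(ConfusionCounts(tn=659, fn=42, fp=177, tp=805))
        assert round(rep.ppv, 2) == 0.82
        assert round(rep.npv, 2) == 0.94

    def test_all_correct(self):
        rep = evaluate(["CNV", "CNA"], ["CNV", "CNA"], ["s1", "s2"])
        assert rep.accuracy == 1.0 and rep.per_tumor_median == 1.0

    def test_counts_recount_oracle(self):
        rng = np.random.default_rng(0)
        pred = rng.choice(["CNV", "CNA"], 200)
        true = rng.choice(["CNV", "CNA"], 200)
        rep = evaluate(pred, true)
        c = rep.counts
        assert c.total == 200
        assert rep.accuracy == pytest.approx((c.tn + c.tp) / 200)
        assert c.tp == int(np.sum((pred == "CNV") & (true == "CNV")))

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            evaluate([], [])


def threshold_data(seed, n=400, cutoff=2.0, noise=0.05):
    """Labels generated by a single database_score threshold plus label noise."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "database_score": rng.uniform(0, 5, n),
        "length_bp": rng.uniform(1e3, 2e6, n),
        "overlap_pct": rng.uniform(0, 1, n),
        "relative_height": rng.uniform(0, 8, n),
    })
    y = np.where(X["database_score"] >= cutoff, "CNV", "CNA").astype(object)
    flip = rng.random(n) < noise
    y[flip] = np.where(y[flip] == "CNV", "CNA", "CNV")
    return X, y


class TestCart:
    def test_recovers_threshold_feature_and_value(self):
        X, y = threshold_data(seed=1)
        model = train_cart(X, y, seed=1)
        assert model.root_feature == "database_score"
        root_threshold = model.tree.tree_.threshold[0]
        gap = np.diff(np.sort(X["database_score"])).max()
        assert abs(root_threshold - 2.0) <= max(gap, 0.1)

    def test_separable_data_gives_depth_one(self):
        X, y = threshold_data(seed=2, noise=0.0)
        model = train_cart(X, y, seed=2)
        assert model.tree.get_depth() == 1

    def test_seed_determinism(self):
        X, y = threshold_data(seed=3)
        m1 = train_cart(X, y, seed=7)
        m2 = train_cart(X, y, seed=7)
        assert m1.describe() == m2.describe()

    def test_single_class_rejected(self):
        X, _ = threshold_data(seed=4)
        with pytest.raises(ValidationError):
            train_cart(X, ["CNV"] * len(X), seed=0)


class TestForest:
    def test_planted_signal_tops_importance(self):
        X, y = threshold_data(seed=5)
        model = train_rf(X, y, n_trees=200, seed=5)
        assert model.importances.index[0] == "database_score"

    def test_importance_ranking_stable_across_seeds(self):
        X, y = threshold_data(seed=6)
        tops = {train_rf(X, y, n_trees=200, seed=s).importances.index[0]
                for s in range(5)}
        assert tops == {"database_score"}

    def test_training_accuracy_at_least_cart(self):
        X, y = threshold_data(seed=7)
        cart = train_cart(X, y, seed=7)
        forest = train_rf(X, y, n_trees=200, seed=7)
        acc = lambda m: np.mean(m.predict(X) == y)
        assert acc(forest) >= acc(cart)

    def test_seed_determinism(self):
        X, y = threshold_data(seed=8)
        p1 = train_rf(X, y, n_trees=100, seed=9).predict(X)
        p2 = train_rf(X, y, n_trees=100, seed=9).predict(X)
        assert (p1 == p2).all()


class TestUnivariateScreen:
    def test_null_feature_type_one_rate(self):
        rng = np.random.default_rng(11)
        n = 2000
        hits = 0
        reps = 200
        for _ in range(reps):
            X = pd.DataFrame({"noise": rng.normal(size=n)})
            y = rng.choice(["CNV", "CNA"], n)
            res = univariate_screen(X, y)
            hits += res["p_value"].iloc[0] < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.05)

    def test_perfect_separation_flagged_not_raised(self):
        X = pd.DataFrame({"sep": np.r_[np.zeros(50), np.ones(50)]})
        y = ["CNA"] * 50 + ["CNV"] * 50
        res = univariate_screen(X, y)
        assert not res["converged"].iloc[0]

    def test_beta_sign_flips_with_labels(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=500)
        y = np.where(x + rng.normal(scale=2, size=500) > 0, "CNV", "CNA")
        X = pd.DataFrame({"x": x})
        b1 = univariate_screen(X, y)["beta"].iloc[0]
        flipped = np.where(y == "CNV", "CNA", "CNV")
        b2 = univariate_screen(X, flipped)["beta"].iloc[0]
        assert np.sign(b1) == -np.sign(b2) and b1 > 0

    def test_constant_feature_p_one(self):
        X = pd.DataFrame({"const": np.ones(100)})
        y = ["CNV"] * 50 + ["CNA"] * 50
        res = univariate_screen(X, y)
        assert res["p_value"].iloc[0] == 1.0 and res["note"].iloc[0] == "constant"

    def test_factor_expanded_to_contrasts(self):
        rng = np.random.default_rng(13)
        lv = rng.choice(["None", "GG", "LL", "GL"], 400)
        y = np.where((lv == "GL") & (rng.random(400) < 0.9), "CNV", "CNA")
        res = univariate_screen(pd.DataFrame({"pattern": lv}), y)
        assert set(res["level"]) == {"GG", "LL", "GL"}
        assert res["p_value"].nunique() == 1  # one LR test for the factor


class TestSerialization:
    def test_cart_round_trip(self, tmp_path):
        X, y = threshold_data(seed=20)
        model = train_cart(X, y, seed=0)
        path = tmp_path / "cart.json"
        save_model(model, path)
        frozen = load_model(path)
        assert (frozen.predict(X) == model.predict(X)).all()

    def test_forest_round_trip(self, tmp_path):
        X, y = threshold_data(seed=21)
        model = train_rf(X, y, n_trees=50, seed=0)
        path = tmp_path / "rf.json"
        save_model(model, path)
        frozen = load_model(path)
        assert (frozen.predict(X) == model.predict(X)).all()
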