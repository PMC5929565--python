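import numpy as np
import pandas as pd
import pytest
from scipy import stats

import perturbnet as pn
from perturbnet.biomarkers import nested_de_cv_auc
from perturbnet.errors import DataError

from conftest import all_edge_candidates


@pytest.fixture(scope="module")
def features(small_pipeline):
    return pn.build_features(
        small_pipeline["delta_tumor"],
        small_pipeline["delta_control"],
        all_edge_candidates(small_pipeline["scores"]),
    )


class TestBuildFeatures:
    def test_shape_and_labels(self, small_pipeline, features):
        dt = small_pipeline["delta_tumor"]
        dc = small_pipeline["delta_control"]
        assert features.X.shape == (dt.n_samples + dc.n_samples, dt.n_edges)
        assert features.y.sum() == dt.n_samples
        assert len(features.y) == dt.n_samples + dc.n_samples

    def test_all_defined_means_nothing_imputed(self, features, small_pipeline):
        if small_pipeline["delta_tumor"].defined.all():
            assert features.n_imputed == 0

    def test_rows_match_delta_columns(self, small_pipeline, features):
        """A tumor sample's feature row is its ΔPCC column restricted to candidates."""
        dt = small_pipeline["delta_tumor"]
        s = dt.sample_ids[3]
        j = dt.sample_ids.index(s)
        np.testing.assert_allclose(
            features.X.loc[s].to_numpy(), dt.delta[:, j], atol=1e-12
        )

    def test_missing_candidate_edge_is_fatal(self, small_pipeline):
        bogus = pn.CandidateSet(
            edges=pd.DataFrame(
                {"mirna": ["nope"], "lncrna": ["nope"], "score": [1.0], "catalog_index": [0]}
            ),
            threshold=0.8,
        )
        with pytest.raises(DataError, match="missing"):
            pn.build_features(
                small_pipeline["delta_tumor"], small_pipeline["delta_control"], bogus
            )


def planted_feature_table(seed, n_noise=20, n_per_class=30):
    """One perfectly separating feature among pure-noise features."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = pd.DataFrame(
        rng.normal(size=(n, n_noise + 1)),
        columns=["signal"] + [f"noise{i}" for i in range(n_noise)],
    )
    y = pd.Series([1] * n_per_class + [0] * n_per_class)
    X.loc[y == 1, "signal"] = rng.normal(5.0, 0.5, n_per_class)
    X.loc[y == 0, "signal"] = rng.normal(-5.0, 0.5, n_per_class)
    return pn.FeatureTable(X=X, y=y)


class TestImportanceRanking:
    @pytest.mark.parametrize("seed", range(10))
    def test_perfect_separator_ranks_first(self, seed):
        feats = planted_feature_table(seed)
        ranking = pn.rank_by_importance(feats, seed=seed, n_trees=100)
        assert ranking["feature"].iloc[0] == "signal"
        assert list(ranking["rank"]) == list(range(1, len(feats.X.columns) + 1))

    def test_constant_feature_has_zero_importance(self):
        feats = planted_feature_table(0)
        feats.X["flat"] = 3.14
        ranking = pn.rank_by_importance(feats, seed=0, n_trees=100)
        assert ranking.set_index("feature").loc["flat", "importance"] == 0.0

    def test_deterministic_under_fixed_seed(self):
        feats = planted_feature_table(1)
        a = pn.rank_by_importance(feats, seed=7, n_trees=100)
        b = pn.rank_by_importance(feats, seed=7, n_trees=100)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_is_fatal(self):
        feats = planted_feature_table(0)
        feats.y[:] = 1
        with pytest.raises(DataError):
            pn.rank_by_importance(feats, seed=0)


class TestCvAuc:
    def test_separable_feature_gives_auc_one(self):
        feats = planted_feature_table(0)
        report = pn.cv_auc(feats, subset=["signal"], folds=5, seed=0, n_trees=50)
        assert report.auc == 1.0

    def test_null_feature_auc_near_half(self):
        """An uninformative feature scores ~0.5 over 20 independent cohorts."""
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame({"f": rng.normal(size=500)})
            y = pd.Series(rng.permutation([1] * 250 + [0] * 250))
            report = pn.cv_auc(
                pn.FeatureTable(X=X, y=y), folds=5, seed=seed, n_trees=50
            )
            aucs.append(report.auc)
        assert 0.45 <= float(np.median(aucs)) <= 0.55

    def test_auc_invariant_under_monotone_transform(self):
        feats = planted_feature_table(2)
        base = pn.cv_auc(feats, subset=["signal"], folds=5, seed=3, n_trees=50).auc
        feats.X["signal"] = np.exp(feats.X["signal"] / 4.0)
        trans = pn.cv_auc(feats, subset=["signal"], folds=5, seed=3, n_trees=50).auc
        assert trans == pytest.approx(base, abs=1e-12)

    def test_roc_is_valid_step_curve(self, features):
        report = pn.cv_auc(features, subset=list(features.X.columns[:3]),
                           folds=4, seed=1, n_trees=50)
        assert report.fpr[0] == 0.0 and report.tpr[0] == 0.0
        assert report.fpr[-1] == 1.0 and report.tpr[-1] == 1.0
        assert (np.diff(report.fpr) >= 0).all() and (np.diff(report.tpr) >= 0).all()
        assert report.auc == pytest.approx(np.trapezoid(report.tpr, report.fpr), abs=1e-15)

    def test_too_many_folds_is_fatal(self):
        feats = planted_feature_table(0, n_per_class=5)
        with pytest.raises(DataError, match="folds"):
            pn.cv_auc(feats, folds=10, seed=0)


class TestActivityScores:
    @staticmethod
    def make(catalog_pairs, candidate_pairs, scores):
        catalog = pn.InteractionCatalog(
            edges=pd.DataFrame(catalog_pairs, columns=["mirna", "lncrna"])
        )
        score_df = pd.DataFrame(
            [(m, l, scores.get((m, l), 0.0)) for m, l in catalog_pairs],
            columns=["mirna", "lncrna", "score"],
        )
        cands = pn.CandidateSet(
            edges=pd.DataFrame(
                [
                    (m, l, scores[(m, l)], catalog_pairs.index((m, l)))
                    for m, l in candidate_pairs
                ],
                columns=["mirna", "lncrna", "score", "catalog_index"],
            ),
            threshold=0.8,
        )
        return catalog, score_df, cands

    def test_hand_computed_value(self):
        """2 candidate pairs (scores 1.0, 0.9) of 4 catalog pairs -> 0.95."""
        catalog_pairs = [("m1", "l1"), ("m1", "l2"), ("m1", "l3"), ("m1", "l4"), ("m2", "l1")]
        scores = {("m1", "l1"): 1.0, ("m1", "l2"): 0.9, ("m2", "l1"): 0.3}
        catalog, score_df, cands = self.make(
            catalog_pairs, [("m1", "l1"), ("m1", "l2")], scores
        )
        table = pn.activity_scores(cands, score_df, catalog).set_index("mirna")
        assert table.loc["m1", "activity"] == pytest.approx((1.0 + 0.9) * (2 / 4), abs=1e-12)
        assert table.loc["m1", "c1"] == 2 and table.loc["m1", "c2"] == 4

    def test_non_candidate_mirna_scores_zero(self):
        catalog_pairs = [("m1", "l1"), ("m2", "l1")]
        catalog, score_df, cands = self.make(catalog_pairs, [("m1", "l1")], {("m1", "l1"): 1.0})
        table = pn.activity_scores(cands, score_df, catalog).set_index("mirna")
        assert table.loc["m2", "activity"] == 0.0

    def test_fully_candidate_mirna_reaches_c1(self):
        """When every catalog pair is a perfect candidate, activity == C1."""
        catalog_pairs = [("m1", "l1"), ("m1", "l2")]
        scores = {("m1", "l1"): 1.0, ("m1", "l2"): 1.0}
        catalog, score_df, cands = self.make(catalog_pairs, catalog_pairs, scores)
        table = pn.activity_scores(cands, score_df, catalog).set_index("mirna")
        assert table.loc["m1", "activity"] == 2.0 == table.loc["m1", "c1"]

    def test_activity_bounded_by_c1_on_shared_mirna_cohort(self):
        cfg = pn.SyntheticConfig(
            n_edges=40, n_planted=10, n_ref=40, n_tumor=30, seed=9,
            mode="shared_mirna", edges_per_mirna=4,
        )
        panel, catalog, _ = pn.generate(cfg)
        ref = pn.build_reference(panel, catalog)
        dt = pn.delta_matrix(ref, panel, "tumor")
        cut = pn.fit_cutoff(dt, alpha=0.05)
        scores = pn.scores_from_delta(dt, cut, catalog)
        cands = pn.select_candidates(scores, threshold=0.05)
        table = pn.activity_scores(cands, scores, catalog)
        assert (table["activity"] <= table["c1"] + 1e-12).all()
        assert (table["c1"] <= table["c2"]).all()


class TestDeBaseline:
    def test_identical_groups_are_not_de(self):
        """Tumor and control share the same values: lfc exactly 0, not DE."""
        base = np.array([2.0, 5.0, 7.0, 11.0])
        samples = [f"t{i}" for i in range(4)] + [f"c{i}" for i in range(4)]
        mirna = pd.DataFrame([np.concatenate([base, base])], index=["m"], columns=samples)
        lncrna = pd.DataFrame([np.ones(8)], index=["l"], columns=samples)
        pheno = pd.Series(["tumor"] * 4 + ["non_tumor"] * 4, index=samples)
        panel = pn.ExpressionPanel(mirna=mirna, lncrna=lncrna, phenotype=pheno)
        de = pn.de_baseline(panel, ["m"])
        assert de.loc[0, "log2fc"] == 0.0
        assert de.loc[0, "status"] == "not_de"

    def test_constant_rna_has_zero_lfc_and_not_de(self):
        samples = [f"s{i}" for i in range(8)]
        mirna = pd.DataFrame([[5.0] * 8], index=["m"], columns=samples)
        lncrna = pd.DataFrame([[1.0] * 8], index=["l"], columns=samples)
        pheno = pd.Series(["tumor"] * 4 + ["non_tumor"] * 4, index=samples)
        panel = pn.ExpressionPanel(mirna=mirna, lncrna=lncrna, phenotype=pheno)
        de = pn.de_baseline(panel, ["m"])
        assert de.loc[0, "log2fc"] == 0.0
        assert de.loc[0, "status"] == "not_de"

    def test_fourfold_shift_is_called_up(self):
        """Tumor = 4x control for one RNA, n=50 per group: lfc ~= 2, status up."""
        rng = np.random.default_rng(12)
        control = rng.uniform(100, 200, size=50)
        samples = [f"t{i}" for i in range(50)] + [f"c{i}" for i in range(50)]
        vals = np.concatenate([4.0 * control, control])
        mirna = pd.DataFrame([vals], index=["m"], columns=samples)
        lncrna = pd.DataFrame([np.ones(100)], index=["l"], columns=samples)
        pheno = pd.Series(["tumor"] * 50 + ["non_tumor"] * 50, index=samples)
        panel = pn.ExpressionPanel(mirna=mirna, lncrna=lncrna, phenotype=pheno)
        de = pn.de_baseline(panel, ["m"])
        assert de.loc[0, "log2fc"] == pytest.approx(2.0, abs=0.05)
        assert de.loc[0, "status"] == "up"
        # oracle: hand-computed normal-approximation rank-sum z for complete
        # separation of two groups of 50
        z = (2500 - 1250) / np.sqrt(50 * 50 * 101 / 12.0)
        assert de.loc[0, "pvalue"] == pytest.approx(
            2 * stats.norm.sf(abs(z)), rel=0.5
        )

    def test_bh_adjustment_dominates_raw_p(self, small_cohort):
        panel, _, _ = small_cohort
        rnas = list(panel.mirna.index[:15])
        de = pn.de_baseline(panel, rnas)
        assert (de["padj"] >= de["pvalue"] - 1e-15).all()

    def test_unknown_rna_is_fatal(self, tiny_panel):
        with pytest.raises(DataError, match="absent"):
            pn.de_baseline(tiny_panel, ["ghost"])


class TestNodeBaseline:
    def test_mean_shift_is_detected(self):
        cfg = pn.SyntheticConfig(
            n_edges=40, n_planted=8, n_ref=40, n_tumor=40, seed=21, mean_shift=3.0
        )
        panel, _, _ = pn.generate(cfg)
        report = nested_de_cv_auc(panel, top_n=5, folds=5, seed=21, n_trees=100)
        assert report.auc > 0.9

    def test_null_panel_scores_near_chance(self):
        cfg = pn.SyntheticConfig(n_edges=40, n_planted=8, n_ref=40, n_tumor=40, seed=22)
        panel, _, _ = pn.generate(cfg)
        report = nested_de_cv_auc(panel, top_n=5, folds=5, seed=22, n_trees=100)
        assert 0.3 <= report.auc <= 0.7
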