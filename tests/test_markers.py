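"""Risk-score modelling, ROC/Youden identities and the simple statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

import methylmark as mm
from methylmark.markers import mann_whitney_auc

from conftest import make_matrix


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end",
                                       "strand"])


class TestSummarize:
    def test_single_site_gene_equals_site_value(self):
        m = make_matrix([[10.0, 20.0], [30.0, 40.0]], positions=[100, 500])
        genes = gene_frame([("A", "chr1", 90, 110, "+")])
        gm, dropped = mm.summarize_gene_methylation(m, genes)
        assert list(gm.loc["A"]) == [10.0, 20.0] and dropped == []

    def test_mean_over_covered_sites(self):
        m = make_matrix([[0.2, 0.2], [0.4, 0.4]], platform="array450k",
                        positions=[100, 200])
        genes = gene_frame([("A", "chr1", 0, 300, "+")])
        gm, _ = mm.summarize_gene_methylation(m, genes)
        assert gm.loc["A"].tolist() == pytest.approx([0.3, 0.3])

    def test_uncovered_gene_reported(self):
        m = make_matrix([[1.0, 2.0]], positions=[100])
        genes = gene_frame([("A", "chr1", 90, 110, "+"),
                            ("B", "chr1", 5000, 6000, "+")])
        gm, dropped = mm.summarize_gene_methylation(m, genes)
        assert list(gm.index) == ["A"] and dropped == ["B"]


class TestKmeans:
    def test_k_one_single_label(self):
        gm = pd.DataFrame(np.random.default_rng(0).uniform(0, 1, (5, 4)),
                          index=[f"G{i}" for i in range(5)])
        labels = mm.kmeans_groups(gm, k=1, seed=0)
        assert set(labels) == {0}

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        blocks = [80.0, 40.0, 5.0]
        rows, names = [], []
        for b, level in enumerate(blocks):
            for i in range(6):
                rows.append(level + rng.normal(0, 0.5, 8))
                names.append(f"B{b}_{i}")
        gm = pd.DataFrame(rows, index=names)
        labels = mm.kmeans_groups(gm, k=3, seed=0)
        # labels ordered by decreasing methylation: block 0 -> 0, etc.
        for b in range(3):
            assert set(labels[[f"B{b}_{i}" for i in range(6)]]) == {b}

    def test_duplicated_rows_share_label(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 1, (6, 5))
        gm = pd.DataFrame(np.vstack([base, base[0]]),
                          index=[f"G{i}" for i in range(6)] + ["G0dup"])
        labels = mm.kmeans_groups(gm, k=3, seed=1)
        assert labels["G0"] == labels["G0dup"]

    def test_k_larger_than_genes_rejected(self):
        gm = pd.DataFrame(np.zeros((2, 3)), index=["A", "B"])
        with pytest.raises(ValueError):
            mm.kmeans_groups(gm, k=5)


class TestRiskModel:
    @staticmethod
    def toy(n=60, shift=0.3, seed=0):
        rng = np.random.default_rng(seed)
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        x = rng.normal(0.4, 0.1, n) + shift * y
        gm = pd.DataFrame([x], index=["HOX_A"],
                          columns=[f"S{i}" for i in range(n)])
        labels = pd.Series(y, index=gm.columns)
        return gm, labels

    def test_null_features_score_prevalence(self):
        gm, labels = self.toy(shift=0.0)
        gm.loc["HOX_A"] = 0.5  # identical feature everywhere
        model = mm.fit_risk_model(gm, labels)
        s = mm.score(model, gm)
        assert np.allclose(s, labels.mean(), atol=1e-6)

    def test_positive_shift_monotone_scores(self):
        gm, labels = self.toy(shift=0.3)
        model = mm.fit_risk_model(gm, labels)
        assert model.coefficients[0] > 0
        s = mm.score(model, gm)
        order = np.argsort(gm.loc["HOX_A"].to_numpy())
        assert np.all(np.diff(s.to_numpy()[order]) >= 0)

    def test_refit_deterministic(self):
        gm, labels = self.toy()
        a = mm.fit_risk_model(gm, labels)
        b = mm.fit_risk_model(gm, labels)
        assert a.intercept == b.intercept
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_separation_falls_back_to_ridge(self):
        gm = pd.DataFrame([[0.1, 0.2, 0.8, 0.9]], index=["G"],
                          columns=list("abcd"))
        labels = pd.Series([0, 0, 1, 1], index=list("abcd"))
        model = mm.fit_risk_model(gm, labels)
        assert model.ridge_penalty is not None
        assert np.isfinite(model.coefficients).all()

    def test_score_closed_form(self):
        model = mm.RiskModel(feature_genes=["G"], intercept=0.5,
                             coefficients=np.array([1.735]), n=4,
                             converged=True)
        gm = pd.DataFrame([[0.2]], index=["G"], columns=["s1"])
        # linear predictor 0.5 + 1.735*0.2 = 0.847
        assert mm.score(model, gm)["s1"] == pytest.approx(
            1 / (1 + np.exp(-0.847)))

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(11)
        n = 500
        x = rng.normal(0, 1, (n, 2))
        beta = np.array([1.2, -0.8])
        eta = 0.3 + x @ beta
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        gm = pd.DataFrame(x.T, index=["G1", "G2"],
                          columns=[f"S{i}" for i in range(n)])
        model = mm.fit_risk_model(gm, pd.Series(y.astype(int),
                                                index=gm.columns))
        assert model.stderr is not None
        est = np.r_[model.intercept, model.coefficients]
        true = np.r_[0.3, beta]
        assert np.all(np.abs(est - true) < 3 * model.stderr)


class TestRoc:
    def test_perfect_separation(self):
        roc = mm.roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_sensitivity == 1.0
        assert roc.youden_specificity == 1.0

    def test_all_tied_scores(self):
        roc = mm.roc_analysis([0.5] * 6, [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_small_worked_example(self):
        roc = mm.roc_analysis([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(0.75)  # 3 of 4 concordant pairs

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        scores = np.round(rng.uniform(0, 1, n), 2)  # force ties
        labels = rng.integers(0, 2, n)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        roc = mm.roc_analysis(scores, labels)
        assert abs(roc.auc - mann_whitney_auc(scores, labels)) < 1e-12
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores),
                                        abs=1e-12)

    def test_confusion_reproduces_sens_spec_formulas(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        roc = mm.roc_analysis(scores, labels)
        assert roc.youden_sensitivity == roc.tp / (roc.tp + roc.fn)
        assert roc.youden_specificity == roc.tn / (roc.tn + roc.fp)
        positive = scores > roc.youden_threshold
        assert roc.tp == int((positive & (labels == 1)).sum())
        assert roc.tn == int((~positive & (labels == 0)).sum())

    def test_youden_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(0, 1, 40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a = mm.roc_analysis(scores, labels)
        b = mm.roc_analysis(np.exp(3 * scores), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert (scores > a.youden_threshold).tolist() == \
            (np.exp(3 * scores) > b.youden_threshold).tolist()

    def test_delong_ci_brackets_auc(self):
        rng = np.random.default_rng(5)
        scores = np.r_[rng.normal(0.4, 0.1, 40), rng.normal(0.6, 0.1, 40)]
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        roc = mm.roc_analysis(scores, labels)
        lo, hi = roc.auc_ci_95
        assert lo < roc.auc < hi and hi - lo < 0.5


class TestSimpleStats:
    def test_single_stratum_rate_no_p(self):
        out = mm.stratified_detection_rates(
            [0.9, 0.2, 0.8], [1, 1, 1],
            pd.DataFrame({"sex": ["M", "M", "M"]}), threshold=0.5)
        assert out["rate"].iloc[0] == pytest.approx(2 / 3)
        assert np.isnan(out["p_value"].iloc[0])

    def test_equal_rates_give_p_near_one(self):
        scores = [0.9] * 30 + [0.1] * 30 + [0.9] * 30 + [0.1] * 30
        labels = [1] * 120
        cov = pd.DataFrame({"sex": ["M"] * 60 + ["F"] * 60})
        out = mm.stratified_detection_rates(scores, labels, cov, 0.5)
        assert out["p_value"].iloc[0] > 0.9

    def test_all_tumor_rate_equals_sensitivity(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 1, 30)
        labels = np.ones(30, int)
        thr = 0.5
        out = mm.stratified_detection_rates(
            scores, labels, pd.DataFrame({"all": ["x"] * 30}), thr)
        assert out["rate"].iloc[0] == (scores > thr).mean()

    def test_pearson_extremes_and_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert mm.markers.correlate_with_covariate(x, x)[0] == pytest.approx(1.0)
        assert mm.markers.correlate_with_covariate(x, -x)[0] == pytest.approx(-1.0)
        y = np.array([2.0, 1.0, 4.0, 3.0])
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / ((len(x) - 1) * x.std(ddof=1) * y.std(ddof=1)))
        assert mm.markers.correlate_with_covariate(x, y)[0] == pytest.approx(
            r_hand, rel=1e-12)

    def test_wilcoxon_exact_separated(self):
        _, p = mm.group_compare([1, 2, 3, 4, 10, 11, 12, 13],
                                ["a"] * 4 + ["b"] * 4)
        assert p == pytest.approx(2 / 70, rel=1e-12)

    def test_identical_multisets_p_one(self):
        _, p = mm.group_compare([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert p == pytest.approx(1.0)

    def test_kruskal_identical_groups_zero(self):
        stat, _ = mm.group_compare([1, 2, 3] * 3,
                                   ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert stat == pytest.approx(0.0)

    def test_group_compare_validation(self):
        with pytest.raises(ValueError):
            mm.group_compare([1, 2], ["a", "a"])
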