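"""Method-comparison statistics against independent oracles.

AUC is checked against brute-force pair counting and sklearn; the ICC
against pingouin's two-way random absolute-agreement single-measure
estimate and against known variance components; Bland-Altman against
injected bias and nominal limit coverage.
"""

import json

import numpy as np
import pandas as pd
import pytest

from rvquant.comparison import (
    MethodComparison,
    PairedSample,
    bland_altman,
    build_comparison_report,
    icc_absolute_single,
    paired_diff_summary,
    pearson_r,
    roc_auc,
    youden_cutoff,
)


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        r, p = pearson_r(PairedSample(x=x, y=2 * x + 3))
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_hand_computed_pairs(self):
        s = PairedSample(x=np.array([1.0, 2, 3, 4]), y=np.array([2.0, 1, 4, 3]))
        r, _ = pearson_r(s)
        assert r == pytest.approx(0.6)

    def test_independent_null(self, rng):
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        r, _ = pearson_r(PairedSample(x=x, y=y))
        assert abs(r) < 0.05

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(PairedSample(x=np.ones(5), y=np.arange(5.0)))


class TestBlandAltman:
    def test_identical_methods(self):
        x = np.arange(5.0)
        res = bland_altman(PairedSample(x=x, y=x))
        assert res.bias == 0.0 and res.sd == 0.0

    def test_constant_offset(self):
        x = np.arange(5.0)
        res = bland_altman(PairedSample(x=x, y=x + 5))
        assert res.bias == pytest.approx(-5.0)
        assert res.sd == pytest.approx(0.0)
        assert res.loa_low == res.loa_high == pytest.approx(-5.0)

    def test_bias_recovery(self, rng):
        n = 10_000
        x = rng.normal(100, 20, n)
        y = x - 3.0 + rng.normal(0, 2, n)
        res = bland_altman(PairedSample(x=x, y=y))
        assert abs(res.bias - 3.0) < 3 * 2 / np.sqrt(n)

    def test_limits_cover_95pct(self, rng):
        n = 10_000
        x = rng.normal(0, 1, n)
        y = x + rng.normal(0.5, 1.5, n)
        res = bland_altman(PairedSample(x=x, y=y))
        d = x - y
        cover = np.mean((d >= res.loa_low) & (d <= res.loa_high))
        assert cover == pytest.approx(0.95, abs=0.01)


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.auc == 1.0
        cut = youden_cutoff(res)
        assert cut.youden_j == pytest.approx(1.0)
        assert cut.sensitivity == cut.specificity == 100.0

    def test_hand_computed_overlap(self):
        res = roc_auc([1, 3, 2, 4], [0, 0, 1, 1])
        assert res.auc == 0.75
        cut = youden_cutoff(res)
        assert cut.youden_j == pytest.approx(0.5)
        # tie rule: maximal J, then the more sensitive operating point
        assert cut.sensitivity == 100.0 and cut.specificity == 50.0

    def test_brute_force_agreement(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 200))
            scores = rng.normal(size=n).round(1)  # rounding induces ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            res = roc_auc(scores, labels)
            assert res.auc == pytest.approx(brute_force_auc(scores, labels),
                                            abs=1e-12)

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=300)
        labels = (scores + rng.normal(size=300) > 0).astype(int)
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_permuted_labels_null(self, rng):
        scores = rng.normal(size=1000)
        labels = rng.permutation([0] * 500 + [1] * 500)
        res = roc_auc(scores, labels)
        assert abs(res.auc - 0.5) < 3 * res.se

    def test_lower_is_positive_direction(self):
        res = roc_auc([4, 3, 2, 1], [0, 0, 1, 1], direction="lower")
        assert res.auc == 1.0
        cut = youden_cutoff(res)
        assert cut.criterion.startswith("≤")

    def test_identical_scores_give_zero_j(self):
        res = roc_auc([1, 1, 1, 1], [0, 0, 1, 1])
        assert res.auc == 0.5
        assert youden_cutoff(res).youden_j == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestICC:
    def test_duplicated_rater_is_one(self, rng):
        a = rng.normal(size=30)
        res = icc_absolute_single(np.column_stack([a, a]))
        assert res.icc == pytest.approx(1.0)
        assert res.ci95 == (pytest.approx(1.0), pytest.approx(1.0))

    def test_offset_penalized_vs_consistency(self, rng):
        a = rng.normal(100, 15, 40)
        r = np.column_stack([a, a + 30.0])
        res = icc_absolute_single(r)
        # consistency-model ICC from the same ANOVA decomposition
        consistency = (res.ms_rows - res.ms_error) / (
            res.ms_rows + (res.n_raters - 1) * res.ms_error)
        assert res.icc < consistency
        assert consistency == pytest.approx(1.0)

    def test_independent_raters_null(self, rng):
        r = rng.normal(size=(1000, 2))
        res = icc_absolute_single(r)
        assert abs(res.icc) < 0.07

    def test_variance_component_recovery(self, rng):
        # subjects x raters with sigma_s=4, sigma_r=1, sigma_e=2
        n, k = 10_000, 3
        subj = rng.normal(0, 4, size=(n, 1))
        rater = rng.normal(0, 1, size=(1, k))
        err = rng.normal(0, 2, size=(n, k))
        res = icc_absolute_single(subj + rater + err)
        expected = 16 / (16 + 1 + 4)
        assert res.icc == pytest.approx(expected, abs=0.05)

    def test_pingouin_cross_check(self, rng):
        import pingouin as pg

        vals = rng.normal(50, 10, size=(25, 2)) + rng.normal(0, 3, size=(25, 1))
        res = icc_absolute_single(vals)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(25), 2),
            "rater": np.tile([0, 1], 25),
            "score": vals.ravel(),
        })
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score").set_index("Type")
        ref = table.loc["ICC(A,1)"] if "ICC(A,1)" in table.index else table.loc["ICC2"]
        ci_col = "CI95" if "CI95" in table.columns else "CI95%"
        assert res.icc == pytest.approx(ref["ICC"], abs=1e-6)
        assert res.ci95[0] == pytest.approx(ref[ci_col][0], abs=0.01)
        assert res.ci95[1] == pytest.approx(ref[ci_col][1], abs=0.01)

    def test_point_estimate_inside_ci(self, rng):
        vals = rng.normal(size=(20, 2)) + rng.normal(size=(20, 1))
        res = icc_absolute_single(vals)
        assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_missing_cells_rejected(self):
        bad = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 2.0],
                        [1.0, 1.0], [0.0, 0.5]])
        with pytest.raises(ValueError, match="missing"):
            icc_absolute_single(bad)


class TestPairedDiff:
    def test_identical(self):
        d = paired_diff_summary(PairedSample(x=np.ones(4), y=np.ones(4)))
        assert d.mean == 0.0 and d.sd == 0.0

    def test_mean_linearity_identity(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        d = paired_diff_summary(PairedSample(x=x, y=y))
        assert d.mean == pytest.approx(x.mean() - y.mean(), abs=1e-12)

    def test_direction_flip(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        a = paired_diff_summary(PairedSample(x=x, y=y), "x-y")
        b = paired_diff_summary(PairedSample(x=x, y=y), "y-x")
        assert a.mean == pytest.approx(-b.mean)
        assert a.sd == pytest.approx(b.sd)


def _results_frame(n, rng, noise=0.0):
    edvi = rng.normal(80, 20, n)
    rows = []
    for i in range(n):
        for method, eps in (("standard", 0.0), ("cpf", noise)):
            e = edvi[i] + rng.normal(0, eps) if eps else edvi[i]
            rows.append({"subject": f"S{i}", "method": method,
                         "edvi": e, "esvi": e * 0.5, "ef": 50.0 - e * 0.1,
                         "enlarged_edv": edvi[i] > 104,
                         "enlarged_esv": edvi[i] * 0.5 > 48,
                         "reduced_ef": 50.0 - edvi[i] * 0.1 < 46})
    return pd.DataFrame(rows)


class TestReportModel:
    def test_identical_methods_degenerate_null(self, rng):
        res = build_comparison_report(_results_frame(40, rng))
        row = res.agreement.loc["RV-EDV index, mL/m2"]
        assert row["diff_mean"] == pytest.approx(0.0, abs=1e-12)
        assert row["r"] == pytest.approx(1.0)
        for key in res.roc:
            assert res.roc[key] is None or res.roc[key].auc == 1.0

    def test_difference_column_is_difference_of_means(self, rng):
        res = build_comparison_report(_results_frame(60, rng, noise=5.0))
        for _, row in res.agreement.iterrows():
            assert row["diff_mean"] == pytest.approx(
                row["standard_mean"] - row["cpf_mean"], abs=1e-10)

    def test_two_subject_minimal_contract(self, rng):
        res = build_comparison_report(_results_frame(2, rng, noise=1.0))
        row = res.agreement.iloc[0]
        assert np.isfinite(row["standard_mean"]) and np.isfinite(row["diff_sd"])
        assert np.isnan(row["r"])  # inferential cell null at n = 2

    def test_missing_method_rejected(self, rng):
        df = _results_frame(10, rng)
        with pytest.raises(ValueError, match="both methods"):
            MethodComparison(df[df["method"] == "cpf"])

    def test_report_json_round_trip(self, rng):
        rel = {"RV-EDV, mL": {"intra": rng.normal(150, 40, size=(30, 2))}}
        res = build_comparison_report(_results_frame(30, rng, noise=4.0),
                                      reliability=rel)
        d = res.to_dict()
        assert json.loads(json.dumps(d)) == d

    def test_reliability_table_icc(self, rng):
        a = rng.normal(150, 40, 30)
        rel = {"RV-EDV, mL": {"intra": np.column_stack([a, a]),
                              "inter": np.column_stack([a, a + rng.normal(10, 5, 30)])}}
        res = build_comparison_report(_results_frame(30, rng, noise=4.0),
                                      reliability=rel)
        intra = res.reliability.loc[("RV-EDV, mL", "intra")]
        inter = res.reliability.loc[("RV-EDV, mL", "inter")]
        assert intra["icc"] == pytest.approx(1.0)
        assert inter["icc"] < intra["icc"]
        assert inter["diff_mean"] == pytest.approx(10.0, abs=3 * 5 / np.sqrt(30))
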