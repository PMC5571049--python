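"""Cross-validation, ROC/AUC, DeLong's test and confusion metrics."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from spntex import (
    DegenerateLabelsError,
    StratificationError,
    confusion_metrics,
    cross_validate_model,
    delong_test,
    optimal_threshold,
    roc_auc,
    selection_frequency,
    stratified_kfold,
)
from spntex.evaluate import FEATURE_SETS, CVResult, ROCCurve

from oracles import auc_pair_oracle


def _labels(n_pos, n_neg):
    return ["malignant"] * n_pos + ["benign"] * n_neg


def _synthetic_matrix(rng, n=40, informative_prefix="dPET"):
    """Tiny 177-column cohort matrix with signal in one image type."""
    from spntex.texture import COHORT_COLUMNS

    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    data = rng.standard_normal((n, 177))
    df = pd.DataFrame(data, columns=COHORT_COLUMNS)
    for col in df.columns:
        if col.startswith(informative_prefix + "_"):
            df[col] += 1.5 * y
    labels = ["malignant" if v else "benign" for v in y]
    return df, labels


class TestStratifiedKFold:
    def test_cohort_of_85_gives_equal_folds(self):
        labels = _labels(63, 22)
        folds = stratified_kfold(labels, k=5, seed=0)
        sizes = np.bincount(folds)
        assert sizes.tolist() == [17, 17, 17, 17, 17]
        benign_per_fold = np.bincount(folds[63:], minlength=5)
        assert benign_per_fold.min() >= 4 and benign_per_fold.max() <= 5

    def test_partition(self):
        labels = _labels(20, 15)
        folds = stratified_kfold(labels, k=5, seed=3)
        assert len(folds) == 35
        assert set(folds) == {0, 1, 2, 3, 4}

    def test_deterministic(self):
        labels = _labels(30, 12)
        np.testing.assert_array_equal(
            stratified_kfold(labels, seed=9), stratified_kfold(labels, seed=9)
        )

    def test_small_class_raises(self):
        with pytest.raises(StratificationError):
            stratified_kfold(_labels(20, 3), k=5)


class TestCrossValidateModel:
    def test_every_lesion_scored_once_and_cap_respected(self, rng):
        df, labels = _synthetic_matrix(rng)
        res = cross_validate_model(df, labels, FEATURE_SETS["dPET"], seed=0)
        assert np.isfinite(res.scores).all()
        assert len(res.scores) == len(labels)
        assert all(1 <= len(sel) <= 5 for sel in res.fold_selections)
        assert all(name.startswith("dPET_") for sel in res.fold_selections for name in sel)

    def test_informative_image_type_wins(self, rng):
        df, labels = _synthetic_matrix(rng, informative_prefix="dPET")
        res_d = cross_validate_model(df, labels, FEATURE_SETS["dPET"], seed=0)
        res_c = cross_validate_model(df, labels, FEATURE_SETS["eCT"], seed=0)
        assert res_d.pooled_auc > res_c.pooled_auc


class TestROC:
    def test_perfect_separation(self):
        roc = roc_auc([3.0, 2.5, 1.0, 0.5], _labels(2, 2))
        assert roc.auc == 1.0
        assert np.all(np.diff(roc.thresholds) >= 0)

    def test_independent_scores_near_half(self, rng):
        scores = rng.standard_normal(4000)
        labels = ["malignant" if v else "benign" for v in rng.integers(0, 2, 4000)]
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_matches_pair_oracle_with_ties(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 40))
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            labels = ["malignant" if v else "benign" for v in rng.integers(0, 2, n)]
            if len(set(labels)) < 2:
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                auc_pair_oracle(scores, labels), rel=1e-12
            )

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            roc_auc([1.0, 2.0], ["malignant", "malignant"])


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        s = rng.standard_normal(30)
        labels = _labels(18, 12)
        auc_a, auc_b, z, p = delong_test(s, s, labels)
        assert auc_a == auc_b
        assert z == 0.0
        assert p == 1.0

    def test_antisymmetric_z(self, rng):
        labels = _labels(25, 15)
        a = rng.standard_normal(40)
        b = rng.standard_normal(40)
        *_, z1, p1 = delong_test(a, b, labels)
        *_, z2, p2 = delong_test(b, a, labels)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_small_case_variance_by_hand(self):
        # 5 positives, 3 negatives: structural components enumerated directly.
        scores_a = np.array([3.1, 2.0, 2.5, 0.7, 1.8, 1.2, 0.5, 2.2])
        scores_b = np.array([2.9, 1.1, 2.6, 1.5, 0.9, 1.6, 0.4, 1.4])
        labels = _labels(5, 3)

        def psi(x, y):
            return 1.0 if x > y else (0.5 if x == y else 0.0)

        def components(s):
            pos, neg = s[:5], s[5:]
            v10 = np.array([np.mean([psi(p, n) for n in neg]) for p in pos])
            v01 = np.array([np.mean([psi(p, n) for p in pos]) for n in neg])
            return v10, v01, float(np.mean([psi(p, n) for p in pos for n in neg]))

        v10a, v01a, auc_a = components(scores_a)
        v10b, v01b, auc_b = components(scores_b)
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / 5 + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / 3
        expected_z = (auc_a - auc_b) / math.sqrt(var)

        got_a, got_b, z, p = delong_test(scores_a, scores_b, labels)
        assert got_a == pytest.approx(auc_a)
        assert got_b == pytest.approx(auc_b)
        assert z == pytest.approx(expected_z, rel=1e-12)

    def test_agrees_with_r_proc(self, rng, tmp_path):
        """Independent oracle: pROC's roc.test implementation of DeLong."""
        n = 60
        latent = rng.standard_normal(n)
        y = (latent + 0.4 * rng.standard_normal(n) > 0).astype(int)
        a = latent + 0.8 * rng.standard_normal(n)
        b = latent + 1.5 * rng.standard_normal(n)
        labels = ["malignant" if v else "benign" for v in y]
        csv = tmp_path / "scores.csv"
        pd.DataFrame({"y": y, "a": a, "b": b}).to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(pROC))
            d <- read.csv("{csv}")
            ra <- roc(d$y, d$a, quiet=TRUE, direction="<")
            rb <- roc(d$y, d$b, quiet=TRUE, direction="<")
            t <- roc.test(ra, rb, method="delong", paired=TRUE)
            cat(sprintf("%.12f %.12f %.12f", auc(ra), auc(rb), t$p.value))
        """)
        proc = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        r_auc_a, r_auc_b, r_p = map(float, proc.stdout.split())
        auc_a, auc_b, z, p = delong_test(a, b, labels)
        assert auc_a == pytest.approx(r_auc_a, abs=1e-9)
        assert auc_b == pytest.approx(r_auc_b, abs=1e-9)
        assert p == pytest.approx(r_p, abs=1e-9)


class TestOptimalThreshold:
    def test_perfect_separation(self):
        roc = roc_auc([4.0, 3.0, 1.0, 0.5], _labels(2, 2))
        thr, counts = optimal_threshold(roc)
        assert counts.sensitivity == 1.0
        assert counts.specificity == 1.0

    def test_distance_is_minimal(self, rng):
        scores = rng.standard_normal(50)
        labels = ["malignant" if v else "benign" for v in rng.integers(0, 2, 50)]
        roc = roc_auc(scores, labels)
        _, counts = optimal_threshold(roc)
        best = math.hypot(1 - counts.sensitivity, 1 - counts.specificity)
        all_d = np.hypot(1 - roc.sensitivity, 1 - roc.specificity)
        assert best <= all_d.min() + 1e-12

    def test_tie_resolved_to_higher_sensitivity(self):
        # Two equidistant corners: (sens .9, spec .6) and (sens .6, spec .9).
        roc = ROCCurve(
            thresholds=np.array([1.0, 2.0]),
            sensitivity=np.array([0.9, 0.6]),
            specificity=np.array([0.6, 0.9]),
            tp=np.array([9, 6]),
            fp=np.array([4, 1]),
            n_pos=10,
            n_neg=10,
            auc=0.8,
        )
        thr, counts = optimal_threshold(roc)
        assert counts.sensitivity == 0.9


class TestConfusionMetrics:
    def test_all_correct(self):
        c = confusion_metrics(tp=10, fp=0, tn=5, fn=0)
        assert (c.sensitivity, c.specificity, c.accuracy, c.ppv, c.npv) == (1, 1, 1, 1, 1)

    def test_zero_denominator_flagged_nan(self):
        c = confusion_metrics(tp=0, fp=0, tn=5, fn=5)
        assert math.isnan(c.ppv)
        assert c.specificity == 1.0

    def test_empty_rejected(self):
        with pytest.raises(Exception):
            confusion_metrics(0, 0, 0, 0)


class TestSelectionFrequency:
    def _fake_result(self, model, selections):
        n = 10
        return CVResult(
            model=model,
            fold_assignment=np.zeros(n, dtype=int),
            scores=np.zeros(n),
            labels=np.array(_labels(5, 5)),
            fold_selections=selections,
            fold_traces=[],
            fold_aucs=[0.5] * len(selections),
        )

    def test_counts_capped_at_k(self):
        res = self._fake_result("dPET", [["dPET_Busyness"]] * 5)
        table = selection_frequency([res])
        row = table[table.feature == "dPET_Busyness"].iloc[0]
        assert row["count"] == 5

    def test_never_selected_absent(self):
        res = self._fake_result("ePET", [["ePET_Mean"], ["ePET_Mean"]])
        table = selection_frequency([res])
        assert "ePET_Entropy" not in set(table.feature)

    def test_per_fold_totals_bounded(self):
        sels = [["a", "b", "c", "d", "e"], ["a", "b"], ["c"]]
        res = self._fake_result("m", sels)
        table = selection_frequency([res])
        assert table["count"].sum() == sum(len(s) for s in sels)
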