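import numpy as np
import pandas as pd
import pytest

from pafscreen.evaluation import (
    ConfusionMatrix,
    auroc,
    confusion_metrics,
    cross_validate,
    report_table,
)
from pafscreen.config import PipelineConfig
from pafscreen.features import FEATURE_NAMES


def _brute_force_auroc(scores, labels, positive="PAF"):
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_50_50_cohort_row(self):
        # a screening model catching 44/50 positives and 48/50 negatives
        rep = confusion_metrics(ConfusionMatrix(TP=44, FN=6, TN=48, FP=2))
        assert rep.accuracy == pytest.approx(0.92)
        assert rep.sensitivity == pytest.approx(0.88)
        assert rep.specificity == pytest.approx(0.96)
        assert rep.PPV == pytest.approx(0.9565, abs=5e-5)
        assert rep.NPV == pytest.approx(0.8889, abs=5e-5)
        assert rep.F1_positive == pytest.approx(0.9167, abs=5e-5)
        assert rep.F1_negative == pytest.approx(0.9231, abs=5e-5)

    def test_perfect_classifier(self):
        rep = confusion_metrics(ConfusionMatrix(TP=10, FN=0, TN=10, FP=0))
        for v in (rep.accuracy, rep.sensitivity, rep.specificity, rep.PPV,
                  rep.NPV, rep.F1_positive, rep.F1_negative):
            assert v == 1.0

    def test_zero_denominator_is_missing(self):
        rep = confusion_metrics(ConfusionMatrix(TP=0, FN=0, TN=5, FP=5))
        assert np.isnan(rep.sensitivity)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(TP=0, FN=0, TN=0, FP=0)


class TestAUROC:
    def test_perfect_and_inverted(self):
        labels = np.array(["PAF"] * 5 + ["normal"] * 5)
        assert auroc(np.r_[np.ones(5), np.zeros(5)], labels) == 1.0
        assert auroc(np.r_[np.zeros(5), np.ones(5)], labels) == 0.0

    def test_matches_brute_force_pairwise(self):
        rng = np.random.default_rng(31)
        scores = np.round(rng.uniform(size=200), 2)  # rounding makes ties
        labels = rng.choice(["PAF", "normal"], size=200)
        assert auroc(scores, labels) == pytest.approx(
            _brute_force_auroc(scores, labels), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(32)
        scores = rng.normal(size=100)
        labels = rng.choice(["PAF", "normal"], size=100)
        a = auroc(scores, labels)
        b = auroc(np.exp(3 * scores) + 7, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], ["PAF", "PAF"])


def _feature_df(n=40, separation=2.5, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = rng.normal(size=(n, 31))
    X[:half, :4] += separation
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df["label"] = ["PAF"] * half + ["normal"] * half
    df.index = [f"s{k:03d}" for k in range(n)]
    df.index.name = "subject_id"
    return df


class TestCrossValidation:
    def test_partition_and_stratification(self):
        from sklearn.model_selection import StratifiedKFold

        df = _feature_df()
        y = df["label"].to_numpy()
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        seen = np.zeros(len(df), dtype=int)
        for tr, te in skf.split(df[list(FEATURE_NAMES)], y):
            seen[te] += 1
            frac = np.mean(y[te] == "PAF")
            assert abs(frac - 0.5) <= 1 / len(te)
        assert np.all(seen == 1)

    def test_report_deterministic_under_seed(self):
        df = _feature_df(seed=1)
        cfg = PipelineConfig(n_members=10, cv_folds=5)
        r1 = cross_validate(df, "bagging", cfg, seed=4)
        r2 = cross_validate(df, "bagging", cfg, seed=4)
        assert r1.as_dict() == r2.as_dict()
        assert r1.per_fold_accuracy == r2.per_fold_accuracy

    def test_informative_features_beat_chance(self):
        df = _feature_df(seed=2)
        cfg = PipelineConfig(n_members=20, cv_folds=5)
        rep = cross_validate(df, "bagging", cfg, seed=0)
        assert rep.accuracy >= 0.7
        assert rep.AUROC >= 0.7

    def test_missing_values_are_imputed_within_folds(self):
        df = _feature_df(seed=3)
        df.iloc[::5, 3] = np.nan  # poke holes in one informative column
        cfg = PipelineConfig(n_members=10, cv_folds=5)
        rep = cross_validate(df, "bagging", cfg, seed=0)
        assert np.isfinite(rep.accuracy)

    def test_fold_count_reduced_with_warning(self):
        df = _feature_df(n=12, seed=4)
        cfg = PipelineConfig(n_members=5, cv_folds=10)
        with pytest.warns(UserWarning):
            rep = cross_validate(df, "bagging", cfg, seed=0)
        assert len(rep.per_fold_accuracy) == 6

    def test_single_class_rejected(self):
        df = _feature_df(seed=5)
        df["label"] = "PAF"
        with pytest.raises(ValueError):
            cross_validate(df, "bagging", PipelineConfig(), seed=0)


class TestReportTable:
    def test_three_rows_seven_metrics(self):
        rep = confusion_metrics(ConfusionMatrix(TP=44, FN=6, TN=48, FP=2))
        rep.AUROC = 0.9
        df = report_table({"bagging": rep, "adaboost": rep, "stacking": rep})
        assert df.shape[0] == 3
        for col in ("accuracy", "sensitivity", "specificity", "PPV", "NPV",
                    "F1", "AUROC"):
            assert col in df.columns
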