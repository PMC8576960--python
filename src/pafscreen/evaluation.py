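"""Confusion-matrix metrics, AUROC, and stratified tenfold cross-validation.

Seven indicators: accuracy, sensitivity, specificity, positive and negative
predictive value, F1 and AUROC.  F1 is reported under both class
conventions: ``F1_positive`` is the harmonic mean of PPV and sensitivity
(the standard, positive = PAF), ``F1_negative`` the harmonic mean of NPV and
specificity.  The headline ``F1`` column of the comparison table mirrors the
negative-class convention; with a 50/50 cohort and two-decimal
sensitivity/specificity the two conventions are numerically distinguishable
and reporting both avoids any ambiguity.

Cross-validation is stratified 10-fold under a fixed seed.  Missing feature
values are median-imputed with medians fitted on the training folds only.
Metrics are computed on the confusion matrix pooled across folds; AUROC on
the pooled held-out scores.  Per-fold accuracies are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig
from .ensemble import BaseLearnerSpec, predict_ensemble, train_ensemble
from .features import FEATURE_NAMES

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_metrics",
    "auroc",
    "cross_validate",
    "report_table",
]


@dataclass
class ConfusionMatrix:
    """Counts with PAF as the positive class."""

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self):
        for name in ("TP", "FN", "TN", "FP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


@dataclass
class EvaluationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    PPV: float
    NPV: float
    F1_positive: float
    F1_negative: float
    AUROC: float | None = None
    confusion: ConfusionMatrix | None = None
    per_fold_accuracy: list = field(default_factory=list)

    @property
    def F1(self) -> float:
        """Headline F1 (negative-class convention of the comparison table)."""
        return self.F1_negative

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "PPV": self.PPV,
            "NPV": self.NPV,
            "F1": self.F1_negative,
            "F1_positive": self.F1_positive,
            "AUROC": self.AUROC,
        }


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else float("nan")


def _harmonic(a: float, b: float) -> float:
    if np.isnan(a) or np.isnan(b) or (a + b) == 0:
        return float("nan")
    return 2.0 * a * b / (a + b)


def confusion_metrics(cm: ConfusionMatrix) -> EvaluationReport:
    """The seven-indicator report (AUROC left unset) from a confusion matrix."""
    acc = _safe_div(cm.TP + cm.TN, cm.total)
    sens = _safe_div(cm.TP, cm.TP + cm.FN)
    spec = _safe_div(cm.TN, cm.TN + cm.FP)
    ppv = _safe_div(cm.TP, cm.TP + cm.FP)
    npv = _safe_div(cm.TN, cm.TN + cm.FN)
    return EvaluationReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        PPV=ppv,
        NPV=npv,
        F1_positive=_harmonic(ppv, sens),
        F1_negative=_harmonic(npv, spec),
        confusion=cm,
    )


def auroc(scores, labels, positive_label: str = "PAF") -> float:
    """Area under the ROC curve (normalised Mann-Whitney U, ties get 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_label
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties with 1/2 credit
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _impute_train_medians(X_train: np.ndarray, X_test: np.ndarray):
    """Median imputation fitted on the training fold only."""
    med = np.nanmedian(X_train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    def fill(M):
        M = M.copy()
        idx = np.where(np.isnan(M))
        M[idx] = med[idx[1]]
        return M
    return fill(X_train), fill(X_test)


def cross_validate(
    features: pd.DataFrame,
    method: str,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of one ensemble method.

    ``features`` is a feature table (31 canonical columns + ``label``).
    Returns the pooled report; per-fold accuracies in ``per_fold_accuracy``.
    """
    if config is None:
        config = PipelineConfig()
    if seed is None:
        seed = config.seed
    X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = features["label"].to_numpy(dtype=object).astype(str)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("cross-validation needs both classes present")
    n_folds = int(config.cv_folds)
    min_class = int(counts.min())
    if min_class < n_folds:
        warnings.warn(
            f"reducing fold count from {n_folds} to {min_class} "
            "(too few samples per class)",
            stacklevel=2,
        )
        n_folds = min_class

    spec = BaseLearnerSpec(complexity_parameter=config.complexity_parameter)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    tp = fn = tn = fp = 0
    all_scores, all_labels = [], []
    per_fold = []
    kwargs = {}
    if method == "stacking":
        kwargs = {
            "layer1_methods": config.layer1_methods,
            "oof_folds": config.stacking_oof_folds,
            "naive": config.stacking_naive,
        }
    for k, (tr, te) in enumerate(skf.split(X, y)):
        X_tr, X_te = _impute_train_medians(X[tr], X[te])
        model = train_ensemble(
            X_tr, y[tr], method,
            n_members=config.n_members, spec=spec,
            seed=(seed * 100003 + k) % (2**31),
            retry_budget=config.retry_budget,
            **kwargs,
        )
        pred, score = predict_ensemble(model, X_te)
        pos = y[te] == model.positive_label
        ppos = pred == model.positive_label
        tp += int(np.sum(pos & ppos))
        fn += int(np.sum(pos & ~ppos))
        tn += int(np.sum(~pos & ~ppos))
        fp += int(np.sum(~pos & ppos))
        all_scores.append(score)
        all_labels.append(y[te])
        per_fold.append(float(np.mean(pred == y[te])))

    cm = ConfusionMatrix(TP=tp, FN=fn, TN=tn, FP=fp)
    report = confusion_metrics(cm)
    report.AUROC = auroc(np.concatenate(all_scores), np.concatenate(all_labels))
    report.per_fold_accuracy = per_fold
    return report


def report_table(reports: dict) -> pd.DataFrame:
    """Comparison table (one row per ensemble method, seven indicators)."""
    rows = {name: rep.as_dict() for name, rep in reports.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "model"
    return df
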