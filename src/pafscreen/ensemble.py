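"""Bagging, AdaBoost and two-layer Stacking ensembles of CART trees.

The three procedures are implemented directly from their classical step
lists rather than delegated to a library, because their acceptance
conditions are part of the method:

* **Bagging** — each of N members is trained on a bootstrap resample of the
  training set; a member whose accuracy on its own resample is not above
  0.5 is discarded and the resample redrawn (bounded retry budget).
  Prediction is an unweighted majority vote; the score is the fraction of
  members voting for the positive class.

* **AdaBoost** (AdaBoost.M1-style) — sampling weights start uniform; each
  round draws a weighted bootstrap resample, trains a member, and checks its
  weighted accuracy on the full training set; rounds with weighted accuracy
  <= 0.5 are redrawn.  With weighted error eps, correct samples' weights are
  multiplied by beta = eps / (1 - eps), weights are renormalised to sum 1,
  and the member votes with weight log(1 / beta).  A perfect member
  (eps = 0) has beta floored at 1e-10 so training can continue.

* **Stacking** — layer-1 models (by default one bagging and one adaboost
  ensemble) are trained on the full training data; a logistic-regression
  meta-model is fitted on their scores.  To avoid target leakage the meta
  training matrix is built from out-of-fold layer-1 scores (5-fold) by
  default; the naive variant (in-sample scores) is available via config.

The base learner is a CART tree with cost-complexity pruning; the
``complexity_parameter`` maps to the pruning strength (0.1 by default,
N = 100 members).  The positive class is "PAF" and ties break toward it,
favouring screening sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, TrainingError

__all__ = [
    "BaseLearnerSpec",
    "EnsembleModel",
    "train_cart",
    "bagging_train",
    "bagging_predict",
    "adaboost_train",
    "adaboost_predict",
    "stacking_train",
    "stacking_predict",
    "train_ensemble",
    "predict_ensemble",
    "save_model",
    "load_model",
]

POSITIVE_LABEL = "PAF"
BETA_FLOOR = 1e-10
DEFAULT_RETRY_BUDGET = 50


@dataclass
class BaseLearnerSpec:
    kind: str = "cart"
    complexity_parameter: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.kind != "cart":
            raise ConfigurationError(f"unsupported base learner {self.kind!r}")
        if not (self.complexity_parameter > 0):
            raise ConfigurationError("complexity_parameter must be positive")


@dataclass
class EnsembleModel:
    method: str                       # bagging | adaboost | stacking
    members: list                     # trained base learners (or layer-1 models)
    n_members: int
    positive_label: str = POSITIVE_LABEL
    negative_label: str = "normal"
    member_weights: np.ndarray | None = None   # adaboost vote weights
    meta_model: LogisticRegression | None = None  # stacking
    layer1_methods: tuple = ()
    diagnostics: dict = field(default_factory=dict)


def _check_labels(y):
    y = np.asarray(y)
    if np.unique(y).size < 2:
        warnings.warn("single-class training labels: degenerate model", stacklevel=2)
    return y


def _negative_label(y) -> str:
    others = [str(v) for v in np.unique(y) if v != POSITIVE_LABEL]
    return others[0] if others else "normal"


def train_cart(X, y, spec: BaseLearnerSpec | None = None, sample_weight=None):
    """Grow a CART tree with cost-complexity pruning at the given strength."""
    if spec is None:
        spec = BaseLearnerSpec()
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    tree = DecisionTreeClassifier(
        ccp_alpha=spec.complexity_parameter, random_state=spec.seed
    )
    tree.fit(X, y, sample_weight=sample_weight)
    return tree


def _positive_score(clf, X):
    """Probability of the positive class, robust to single-class trees."""
    proba = clf.predict_proba(X)
    classes = list(clf.classes_)
    if POSITIVE_LABEL in classes:
        return proba[:, classes.index(POSITIVE_LABEL)]
    return np.zeros(X.shape[0])


def bagging_train(
    X, y, n_members: int = 100, spec: BaseLearnerSpec | None = None,
    seed: int = 0, retry_budget: int = DEFAULT_RETRY_BUDGET,
) -> EnsembleModel:
    """Train a bagging ensemble of CART trees."""
    if n_members < 1:
        raise ConfigurationError("n_members must be >= 1")
    if spec is None:
        spec = BaseLearnerSpec()
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    members, accs = [], []
    for _ in range(n_members):
        for attempt in range(retry_budget):
            idx = rng.integers(0, n, size=n)
            if np.unique(y[idx]).size < 2:
                continue  # single-class resample cannot yield a useful member
            tree = train_cart(X[idx], y[idx], spec)
            acc = float(np.mean(tree.predict(X[idx]) == y[idx]))
            if acc > 0.5:
                members.append(tree)
                accs.append(acc)
                break
        else:
            raise TrainingError(
                f"bagging: no resample yielded training accuracy > 0.5 "
                f"within {retry_budget} redraws"
            )
    return EnsembleModel(
        method="bagging",
        members=members,
        n_members=n_members,
        negative_label=_negative_label(y),
        diagnostics={"member_train_accuracy": np.array(accs)},
    )


def bagging_predict(model: EnsembleModel, X):
    """Majority vote; score = fraction of members voting positive."""
    X = np.asarray(X, dtype=float)
    votes = np.stack([m.predict(X) == model.positive_label for m in model.members])
    score = votes.mean(axis=0)
    labels = np.where(score >= 0.5, model.positive_label, model.negative_label)
    return labels, score


def _update_weights(w: np.ndarray, correct: np.ndarray, eps: float):
    """One AdaBoost weight update: multiply correct samples by beta, renormalise.

    Returns ``(new_weights, beta)`` with ``beta = eps / (1 - eps)`` floored
    at ``BETA_FLOOR``.
    """
    beta = max(eps / (1.0 - eps), BETA_FLOOR)
    w = w.copy()
    w[correct] *= beta
    w /= w.sum()
    return w, beta


def adaboost_train(
    X, y, n_members: int = 100, spec: BaseLearnerSpec | None = None,
    seed: int = 0, retry_budget: int = DEFAULT_RETRY_BUDGET,
) -> EnsembleModel:
    """Train an AdaBoost ensemble by the weighted-bootstrap step list."""
    if n_members < 1:
        raise ConfigurationError("n_members must be >= 1")
    if spec is None:
        spec = BaseLearnerSpec()
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    w = np.full(n, 1.0 / n)
    members, alphas, eps_hist, weight_sums, acc_hist = [], [], [], [], []
    n_resets = 0
    for _ in range(n_members):
        found = False
        # when the weight distribution becomes so adversarial that no
        # resample beats 0.5 within the budget, reset the weights to uniform
        # and retry once (the standard resampling-boosting fallback); only a
        # second exhaustion is a training error
        for _round in range(2):
            for attempt in range(retry_budget):
                idx = rng.choice(n, size=n, replace=True, p=w)
                if np.unique(y[idx]).size < 2:
                    continue  # single-class resample cannot yield a useful member
                tree = train_cart(X[idx], y[idx], spec)
                correct = tree.predict(X) == y
                acc = float(np.sum(w[correct]))
                if acc > 0.5:
                    found = True
                    break
            if found:
                break
            w = np.full(n, 1.0 / n)
            n_resets += 1
        if not found:
            raise TrainingError(
                f"adaboost: weighted accuracy never exceeded 0.5 in "
                f"{retry_budget} redraws, even after a uniform weight reset"
            )
        eps = 1.0 - acc
        w, beta = _update_weights(w, correct, eps)
        members.append(tree)
        alphas.append(float(np.log(1.0 / beta)))
        eps_hist.append(eps)
        weight_sums.append(float(w.sum()))
        acc_hist.append(acc)
    return EnsembleModel(
        method="adaboost",
        members=members,
        n_members=n_members,
        negative_label=_negative_label(y),
        member_weights=np.array(alphas),
        diagnostics={
            "eps": np.array(eps_hist),
            "weight_sums": np.array(weight_sums),
            "member_weighted_accuracy": np.array(acc_hist),
            "n_weight_resets": n_resets,
        },
    )


def adaboost_predict(model: EnsembleModel, X):
    """Weighted vote; score = positive-class share of the total vote weight."""
    X = np.asarray(X, dtype=float)
    votes = np.stack([m.predict(X) == model.positive_label for m in model.members])
    alphas = model.member_weights
    score = (alphas[:, None] * votes).sum(axis=0) / alphas.sum()
    labels = np.where(score >= 0.5, model.positive_label, model.negative_label)
    return labels, score


_LAYER1_TRAINERS = {"bagging": bagging_train, "adaboost": adaboost_train}
_LAYER1_PREDICTORS = {"bagging": bagging_predict, "adaboost": adaboost_predict}


def stacking_train(
    X, y, layer1_methods=("bagging", "adaboost"), n_members: int = 100,
    spec: BaseLearnerSpec | None = None, seed: int = 0,
    oof_folds: int = 5, naive: bool = False,
    retry_budget: int = DEFAULT_RETRY_BUDGET,
) -> EnsembleModel:
    """Two-layer stacking: layer-1 ensembles feeding a logistic meta-model."""
    if len(layer1_methods) < 2:
        raise ConfigurationError("stacking needs at least 2 layer-1 models")
    for m in layer1_methods:
        if m not in _LAYER1_TRAINERS:
            raise ConfigurationError(f"unknown layer-1 method {m!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(layer1_methods) + 1)]

    # meta-feature matrix: one column of layer-1 scores per layer-1 model
    meta_X = np.zeros((n, len(layer1_methods)))
    if naive:
        for j, m in enumerate(layer1_methods):
            mod = _LAYER1_TRAINERS[m](X, y, n_members=n_members, spec=spec,
                                      seed=seeds[j], retry_budget=retry_budget)
            meta_X[:, j] = _LAYER1_PREDICTORS[m](mod, X)[1]
    else:
        skf = StratifiedKFold(n_splits=oof_folds, shuffle=True, random_state=seeds[-1])
        for tr, te in skf.split(X, y):
            for j, m in enumerate(layer1_methods):
                mod = _LAYER1_TRAINERS[m](X[tr], y[tr], n_members=n_members, spec=spec,
                                          seed=seeds[j], retry_budget=retry_budget)
                meta_X[te, j] = _LAYER1_PREDICTORS[m](mod, X[te])[1]

    meta = LogisticRegression(random_state=0)
    meta.fit(meta_X, y)

    # final layer-1 models trained on all training data
    finals = [
        _LAYER1_TRAINERS[m](X, y, n_members=n_members, spec=spec,
                            seed=seeds[j], retry_budget=retry_budget)
        for j, m in enumerate(layer1_methods)
    ]
    return EnsembleModel(
        method="stacking",
        members=finals,
        n_members=len(finals),
        negative_label=_negative_label(y),
        meta_model=meta,
        layer1_methods=tuple(layer1_methods),
        diagnostics={"meta_X": meta_X},
    )


def stacking_predict(model: EnsembleModel, X):
    """Layer-1 scores through the logistic meta-model; tie (p = 0.5) -> positive."""
    X = np.asarray(X, dtype=float)
    meta_X = np.column_stack(
        [_LAYER1_PREDICTORS[m](mod, X)[1]
         for m, mod in zip(model.layer1_methods, model.members)]
    )
    classes = list(model.meta_model.classes_)
    p = model.meta_model.predict_proba(meta_X)[:, classes.index(model.positive_label)]
    labels = np.where(p >= 0.5, model.positive_label, model.negative_label)
    return labels, p


def train_ensemble(X, y, method: str, n_members: int = 100,
                   spec: BaseLearnerSpec | None = None, seed: int = 0,
                   **kw) -> EnsembleModel:
    """Dispatch to the requested ensemble trainer."""
    if method == "bagging":
        return bagging_train(X, y, n_members=n_members, spec=spec, seed=seed, **kw)
    if method == "adaboost":
        return adaboost_train(X, y, n_members=n_members, spec=spec, seed=seed, **kw)
    if method == "stacking":
        return stacking_train(X, y, n_members=n_members, spec=spec, seed=seed, **kw)
    raise ConfigurationError(f"unknown ensemble method {method!r}")


def predict_ensemble(model: EnsembleModel, X):
    return {
        "bagging": bagging_predict,
        "adaboost": adaboost_predict,
        "stacking": stacking_predict,
    }[model.method](model, X)


def save_model(model: EnsembleModel, path: str) -> None:
    """Serialise a trained ensemble (joblib bundle)."""
    joblib.dump(model, path)


def load_model(path: str) -> EnsembleModel:
    return joblib.load(path)
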