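"""Supervised m1A prediction from signature feature vectors.

The classifier sees seven numeric features per adenosine — arrest rate ``a``,
mismatch rate ``m``, ``m/a``, the three mismatch-composition shares and the
context-sensitive arrest rate (CSA).  The identity of the +1 base, although
it shapes the misincorporation pattern, is deliberately excluded to avoid
sequence-context overfitting.

Validation regimes:

* setting (i)   — balanced positives vs uniformly random negatives;
* setting (ii)  — negatives restricted to "confusable" sites with a minimum
                  m1A-signature resemblance;
* setting (iii) — train on tRNA instances, test on rRNA instances only.

Performance is summarized by sensitivity/specificity over 10 repetitions of a
stratified five-fold cross-validation with a 500-tree Random Forest, plus
leave-one-out, leave-feature-out, a kNN baseline and ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

from .signatures import FEATURE_COLUMNS, is_confusable_negative

POSITIVE, NEGATIVE = "m1A", "non_m1A"


class M1ASignatureClassifier(ClassifierMixin, BaseEstimator):
    """Random-Forest site classifier with a conservative decision rule.

    A thin sklearn estimator around a 500-tree Random Forest: a site is
    called m1A only when strictly more than half of the tree votes favor it,
    so an exact tie is resolved toward non-m1A.  ``predict_proba`` exposes
    the positive vote fraction used for ROC analysis.
    """

    def __init__(self, n_trees: int = 500, random_state: Optional[int] = None,
                 threshold: float = 0.5):
        self.n_trees = n_trees
        self.random_state = random_state
        self.threshold = threshold

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification expected")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state)
        self.forest_.fit(X, y)
        self.feature_importances_ = self.forest_.feature_importances_
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.forest_.predict_proba(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        pos_idx = int(np.where(self.forest_.classes_ == POSITIVE)[0][0]) \
            if POSITIVE in self.forest_.classes_ else 1
        return np.where(proba[:, pos_idx] > self.threshold,
                        self.forest_.classes_[pos_idx],
                        self.forest_.classes_[1 - pos_idx])


@dataclass
class Dataset:
    """Labeled feature matrix for one validation setting."""

    X: pd.DataFrame
    y: np.ndarray            # labels in {m1A, non_m1A}
    ids: pd.DataFrame        # ref_id, pos per row
    setting: str = "i"
    test: Optional["Dataset"] = None  # held-out set (setting iii)

    @property
    def n_pos(self) -> int:
        return int((self.y == POSITIVE).sum())

    @property
    def n_neg(self) -> int:
        return int((self.y == NEGATIVE).sum())


@dataclass
class CVReport:
    """Per-repetition, per-fold performance with configuration echo."""

    folds_table: pd.DataFrame         # repetition, fold, sensitivity, specificity
    config: Dict = field(default_factory=dict)
    roc_points: Optional[pd.DataFrame] = None
    roc_auc: Optional[float] = None
    feature_importances: Optional[pd.Series] = None

    @property
    def sensitivity(self) -> float:
        return float(self.folds_table["sensitivity"].mean())

    @property
    def specificity(self) -> float:
        return float(self.folds_table["specificity"].mean())

    @property
    def sensitivity_sd(self) -> float:
        return float(self.folds_table.groupby("repetition")["sensitivity"].mean().std(ddof=1))

    @property
    def specificity_sd(self) -> float:
        return float(self.folds_table.groupby("repetition")["specificity"].mean().std(ddof=1))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "sensitivity": self.sensitivity, "sensitivity_sd": self.sensitivity_sd,
            "specificity": self.specificity, "specificity_sd": self.specificity_sd,
            **{k: v for k, v in self.config.items() if np.isscalar(v)},
        }])


def _features(signatures: pd.DataFrame, features: Sequence[str]) -> pd.DataFrame:
    missing = [f for f in features if f not in signatures.columns]
    if missing:
        raise ValueError(f"signature table lacks feature columns {missing}")
    return signatures[list(features)].astype(float)


def make_dataset(signatures: pd.DataFrame, setting: str = "i",
                 n_negatives: Optional[int] = None, seed: int = 0,
                 features: Sequence[str] = tuple(FEATURE_COLUMNS)) -> Dataset:
    """Assemble a balanced labeled dataset under one validation setting.

    Requires ``label`` in {m1A, non_m1A, unknown}; setting (iii) additionally
    needs an ``rna_class`` column with tRNA/rRNA tags.  Negatives are sampled
    with the given seed; insufficient negatives raise with the counts.
    """
    rng = np.random.default_rng(seed)
    pos = signatures[signatures["label"] == POSITIVE]
    neg_pool = signatures[signatures["label"] == NEGATIVE]
    if setting in ("i", "ii"):
        if setting == "ii":
            mask = neg_pool.apply(is_confusable_negative, axis=1)
            neg_pool = neg_pool[mask]
        n_need = n_negatives if n_negatives is not None else len(pos)
        if len(pos) == 0:
            raise ValueError("no m1A-labeled instances available")
        if len(neg_pool) < n_need:
            raise ValueError(
                f"setting ({setting}): need {n_need} negatives but only "
                f"{len(neg_pool)} available")
        take = rng.choice(len(neg_pool), size=n_need, replace=False)
        neg = neg_pool.iloc[np.sort(take)]
        data = pd.concat([pos, neg], ignore_index=True)
        return Dataset(X=_features(data, features),
                       y=data["label"].to_numpy(),
                       ids=data[["ref_id", "pos"]].reset_index(drop=True),
                       setting=setting)
    if setting == "iii":
        if "rna_class" not in signatures.columns:
            raise ValueError("setting (iii) requires an rna_class column")
        tr = signatures[signatures["rna_class"] == "tRNA"]
        rr = signatures[signatures["rna_class"] == "rRNA"]
        train = _balanced_subset(tr, rng, "train/tRNA")
        test = _balanced_subset(rr, rng, "test/rRNA")
        train.test = Dataset(X=test.X, y=test.y, ids=test.ids, setting="iii-test")
        train.setting = "iii"
        return train
    raise ValueError(f"unknown setting {setting!r}")


def _balanced_subset(sig: pd.DataFrame, rng: np.random.Generator, what: str,
                     features: Sequence[str] = tuple(FEATURE_COLUMNS)) -> Dataset:
    pos = sig[sig["label"] == POSITIVE]
    neg_pool = sig[sig["label"] == NEGATIVE]
    if len(pos) == 0 or len(neg_pool) < len(pos):
        raise ValueError(f"{what}: {len(pos)} positives vs {len(neg_pool)} negatives available")
    take = rng.choice(len(neg_pool), size=len(pos), replace=False)
    data = pd.concat([pos, neg_pool.iloc[np.sort(take)]], ignore_index=True)
    return Dataset(X=_features(data, features), y=data["label"].to_numpy(),
                   ids=data[["ref_id", "pos"]].reset_index(drop=True))


def _sens_spec(y_true: np.ndarray, y_pred: np.ndarray) -> Tuple[float, float]:
    pos = y_true == POSITIVE
    neg = ~pos
    sens = float((y_pred[pos] == POSITIVE).mean()) if pos.any() else np.nan
    spec = float((y_pred[neg] == NEGATIVE).mean()) if neg.any() else np.nan
    return sens, spec


def cross_validate(dataset: Dataset, folds: int = 5, repetitions: int = 10,
                   model: Optional[BaseEstimator] = None, seed: int = 0,
                   collect_roc: bool = True) -> CVReport:
    """Repeated stratified k-fold CV; deterministic given the seed.

    Each repetition re-shuffles the stratified partition; the model (a fresh
    clone per fold) is trained on k-1 folds and scored on the left-out fold.
    Out-of-fold positive vote fractions feed the pooled ROC curve.
    """
    if model is None:
        model = M1ASignatureClassifier()
    if min(dataset.n_pos, dataset.n_neg) < folds:
        raise ValueError(f"need at least {folds} instances per class for {folds}-fold CV")
    X = dataset.X.to_numpy()
    y = dataset.y
    ss = np.random.SeedSequence(seed)
    rows = []
    scores = np.full(len(y), np.nan)
    importances = []
    for rep, rep_seed in enumerate(ss.spawn(repetitions)):
        rep_rng = np.random.default_rng(rep_seed)
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rep_rng.integers(2**31)))
        for fold, (itr, ite) in enumerate(skf.split(X, y)):
            est = clone(model)
            if "random_state" in est.get_params():
                est.set_params(random_state=int(rep_rng.integers(2**31)))
            est.fit(X[itr], y[itr])
            y_pred = est.predict(X[ite])
            sens, spec = _sens_spec(y[ite], y_pred)
            rows.append({"repetition": rep, "fold": fold,
                         "sensitivity": sens, "specificity": spec})
            if collect_roc and hasattr(est, "predict_proba"):
                proba = est.predict_proba(X[ite])
                pos_idx = list(getattr(est, "classes_", [NEGATIVE, POSITIVE])).index(POSITIVE)
                if rep == 0:
                    scores[ite] = proba[:, pos_idx]
            if hasattr(est, "feature_importances_"):
                importances.append(est.feature_importances_)
    report = CVReport(
        folds_table=pd.DataFrame(rows),
        config={"setting": dataset.setting, "folds": folds, "repetitions": repetitions,
                "model": type(model).__name__, "seed": seed,
                **{k: v for k, v in model.get_params().items()
                   if k in ("n_trees", "n_neighbors", "threshold")}},
    )
    if collect_roc and not np.isnan(scores).any():
        fpr, tpr, thr = roc_curve(y, scores, pos_label=POSITIVE)
        report.roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
        report.roc_auc = float(auc(fpr, tpr))
    if importances:
        report.feature_importances = pd.Series(
            np.mean(importances, axis=0), index=list(dataset.X.columns))
    return report


def evaluate_holdout(dataset: Dataset, model: Optional[BaseEstimator] = None,
                     seed: int = 0) -> pd.DataFrame:
    """Train on the dataset, score its held-out test set (setting iii)."""
    if dataset.test is None:
        raise ValueError("dataset carries no held-out test set")
    if model is None:
        model = M1ASignatureClassifier(random_state=seed)
    est = clone(model)
    if "random_state" in est.get_params():
        est.set_params(random_state=seed)
    est.fit(dataset.X.to_numpy(), dataset.y)
    y_pred = est.predict(dataset.test.X.to_numpy())
    sens, spec = _sens_spec(dataset.test.y, y_pred)
    return pd.DataFrame([{"sensitivity": sens, "specificity": spec,
                          "n_train": len(dataset.y), "n_test": len(dataset.test.y)}])


def leave_one_out(dataset: Dataset, model: Optional[BaseEstimator] = None,
                  seed: int = 0) -> pd.DataFrame:
    """Paired leave-one-out: each round holds out one positive + one negative.

    Rounds = min(n_pos, n_neg) with a seeded pairing; every instance is tested
    at most once (exactly once when the dataset is balanced).  Returns the
    per-class accuracies.
    """
    if dataset.n_pos != dataset.n_neg:
        raise ValueError(f"leave-one-out expects a balanced dataset "
                         f"({dataset.n_pos} vs {dataset.n_neg})")
    if model is None:
        model = M1ASignatureClassifier()
    rng = np.random.default_rng(seed)
    X = dataset.X.to_numpy()
    y = dataset.y
    pos_idx = rng.permutation(np.flatnonzero(y == POSITIVE))
    neg_idx = rng.permutation(np.flatnonzero(y == NEGATIVE))
    rounds = min(len(pos_idx), len(neg_idx))
    correct_pos = correct_neg = 0
    for r in range(rounds):
        ite = np.array([pos_idx[r], neg_idx[r]])
        itr = np.setdiff1d(np.arange(len(y)), ite)
        est = clone(model)
        if "random_state" in est.get_params():
            est.set_params(random_state=int(rng.integers(2**31)))
        est.fit(X[itr], y[itr])
        y_pred = est.predict(X[ite])
        correct_pos += int(y_pred[0] == POSITIVE)
        correct_neg += int(y_pred[1] == NEGATIVE)
    return pd.DataFrame([{"rounds": rounds,
                          "sensitivity": correct_pos / rounds,
                          "specificity": correct_neg / rounds}])


#: feature groupings probed by the subset mode of leave-feature-out
FEATURE_GROUPS = {
    "full": list(FEATURE_COLUMNS),
    "arrest_only": ["a", "csa"],
    "mismatch_only": ["m", "comp_G", "comp_T", "comp_C"],
}


def leave_feature_out(dataset: Dataset, mode: str = "single",
                      model: Optional[BaseEstimator] = None, seed: int = 0,
                      folds: int = 5, repetitions: int = 10) -> pd.DataFrame:
    """Performance of incomplete feature combinations.

    ``single`` drops one feature at a time (one row per feature);
    ``subsets`` evaluates the full set against arrest-only {a, csa} and
    mismatch-only {m, comp_G, comp_T, comp_C} groupings.
    """
    all_feats = list(dataset.X.columns)
    if len(all_feats) < 2:
        raise ValueError("need at least two features")
    if mode == "single":
        combos = {f"drop_{f}": [g for g in all_feats if g != f] for f in all_feats}
    elif mode == "subsets":
        combos = {name: [f for f in feats if f in all_feats]
                  for name, feats in FEATURE_GROUPS.items()}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for name, feats in combos.items():
        sub = Dataset(X=dataset.X[feats], y=dataset.y, ids=dataset.ids,
                      setting=dataset.setting)
        rep = cross_validate(sub, folds=folds, repetitions=repetitions,
                             model=model, seed=seed, collect_roc=False)
        rows.append({"feature_set": name, "features": ",".join(feats),
                     "sensitivity": rep.sensitivity, "specificity": rep.specificity,
                     "sensitivity_sd": rep.sensitivity_sd,
                     "specificity_sd": rep.specificity_sd})
    return pd.DataFrame(rows)


def knn_baseline(dataset: Dataset, k: int = 3, folds: int = 5,
                 repetitions: int = 10, seed: int = 0) -> CVReport:
    """Same CV harness with a plain Euclidean k-nearest-neighbor classifier."""
    n_train = len(dataset.y) - len(dataset.y) // folds
    if k >= n_train:
        raise ValueError(f"k={k} is not below the training-fold size {n_train}")
    model = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    return cross_validate(dataset, folds=folds, repetitions=repetitions,
                          model=model, seed=seed, collect_roc=True)


def roc_analysis(dataset: Dataset, model: Optional[BaseEstimator] = None,
                 seed: int = 0, folds: int = 5) -> Tuple[pd.DataFrame, float]:
    """ROC curve + trapezoid area from out-of-fold positive vote fractions."""
    report = cross_validate(dataset, folds=folds, repetitions=1, model=model,
                            seed=seed, collect_roc=True)
    if report.roc_points is None:
        raise ValueError("model does not expose class probabilities")
    return report.roc_points, float(report.roc_auc)
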