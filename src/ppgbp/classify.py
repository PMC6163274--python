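"""Binary blood-pressure-category classification trials.

The experimental design is a 3 x 3 x 4 grid: three binary trials
(normotension vs prehypertension, normotension vs hypertension, and
normo+prehypertension vs hypertension), three feature sets (PAT only, the
ten PPG morphology features, and their union), and four classifier families
(AdaBoost with depth-1 trees, L2 logistic regression, k-nearest neighbours,
and bagged trees).  Each cell uses a stratified 70/30 train/test split,
10-fold cross-validation on the training portion (logged), a refit on the
full training set, and test-set sensitivity / specificity / precision / F1.

Features are standardized with statistics estimated on the training portion
only.  Because a single split of ~100 subjects is high-variance, the grid
can be repeated over several seeds and summarized as mean +/- SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .labeling import HYPERTENSION, NORMOTENSION, PREHYPERTENSION

TRIALS = {
    "N_vs_P": ((NORMOTENSION,), (PREHYPERTENSION,)),
    "N_vs_H": ((NORMOTENSION,), (HYPERTENSION,)),
    "NP_vs_H": ((NORMOTENSION, PREHYPERTENSION), (HYPERTENSION,)),
}

FEATURE_SETS = {
    "PAT": ["pat"],
    "PPG10": [f"f{i}" for i in range(1, 11)],
    "PAT+PPG10": ["pat"] + [f"f{i}" for i in range(1, 11)],
}

CLASSIFIERS = ("adaboost_tree", "logistic", "knn", "bagged_tree")


@dataclass
class Metrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    f1: float


def make_classifier(name: str, seed: int = 0, *, knn_k: int = 5,
                    adaboost_n: int = 50, bagged_n: int = 100,
                    logistic_c: float = 1.0) -> Pipeline:
    """A standardize-then-classify pipeline for one of the four families."""
    if name == "adaboost_tree":
        clf = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=adaboost_n,
            random_state=seed,
        )
    elif name == "logistic":
        clf = LogisticRegression(C=logistic_c, max_iter=2000)
    elif name == "knn":
        clf = KNeighborsClassifier(n_neighbors=knn_k)
    elif name == "bagged_tree":
        clf = BaggingClassifier(
            estimator=DecisionTreeClassifier(),
            n_estimators=bagged_n,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown classifier family {name!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def trial_dataset(
    table: pd.DataFrame, trial_id: str, feature_set: str
) -> tuple[np.ndarray, np.ndarray]:
    """Subset the per-subject feature table for one trial.

    Returns (X, y) with y = 1 for the trial's positive class (the higher BP
    category).  Raises if a requested feature column is absent.
    """
    if trial_id not in TRIALS:
        raise ValueError(f"unknown trial {trial_id!r}")
    neg, pos = TRIALS[trial_id]
    cols = FEATURE_SETS[feature_set]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    mask = table["label"].isin(neg + pos)
    sub = table.loc[mask]
    X = sub[cols].to_numpy(dtype=float)
    y = sub["label"].isin(pos).to_numpy(dtype=int)
    return X, y


def split_train_test(
    X: np.ndarray, y: np.ndarray, seed: int, test_size: float = 0.3
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified 70/30 split, reproducible by seed."""
    if len(y) < 10:
        raise ValueError("need at least 10 subjects to split")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members to stratify")
    return train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )


def train_with_cv(
    X_train: np.ndarray,
    y_train: np.ndarray,
    classifier: str,
    seed: int,
    cv_folds: int = 10,
    **clf_kwargs,
) -> tuple[Pipeline, np.ndarray]:
    """Cross-validate on the training portion, then refit on all of it.

    Returns the refit pipeline and the per-fold CV F1 scores.  The fold
    count is reduced (to the smallest class count) when 10 folds cannot be
    stratified.
    """
    model = make_classifier(classifier, seed=seed, **clf_kwargs)
    _, counts = np.unique(y_train, return_counts=True)
    folds = int(min(cv_folds, counts.min()))
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scores = cross_val_score(model, X_train, y_train, cv=cv, scoring="f1")
    else:
        scores = np.array([])
    model.fit(X_train, y_train)
    return model, scores


def evaluate(predictions, truth, positive_class=1) -> Metrics:
    """Confusion counts and SE/SP/precision/F1 from the printed formulas.

    F1 = 2·Recall·Precision/(Recall+Precision), with the convention F1 = 0
    when there are no true positives.
    """
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    if not predictions:
        raise ValueError("empty input")
    tp = fp = tn = fn = 0
    for p, t in zip(predictions, truth):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    if tp == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * sensitivity * precision / (sensitivity + precision)
    return Metrics(tp, fp, tn, fn, sensitivity, specificity, precision, f1)


def run_cell(
    table: pd.DataFrame,
    trial_id: str,
    feature_set: str,
    classifier: str,
    seed: int,
    **clf_kwargs,
) -> Metrics:
    """One (trial, feature set, classifier) cell at one split seed."""
    X, y = trial_dataset(table, trial_id, feature_set)
    X_tr, X_te, y_tr, y_te = split_train_test(X, y, seed)
    model, _ = train_with_cv(X_tr, y_tr, classifier, seed, **clf_kwargs)
    pred = model.predict(X_te)
    return evaluate(pred, y_te, positive_class=1)


def run_trials(
    table: pd.DataFrame,
    seeds: list[int],
    trials=tuple(TRIALS),
    feature_sets=tuple(FEATURE_SETS),
    classifiers=CLASSIFIERS,
    **clf_kwargs,
) -> pd.DataFrame:
    """The full trial grid, one row per cell per seed.

    Columns: trial, feature_set, classifier, seed, SE, SP, precision, F1.
    """
    rows = []
    for trial_id in trials:
        for feature_set in feature_sets:
            for classifier in classifiers:
                for seed in seeds:
                    m = run_cell(
                        table, trial_id, feature_set, classifier, seed, **clf_kwargs
                    )
                    rows.append(
                        {
                            "trial": trial_id,
                            "feature_set": feature_set,
                            "classifier": classifier,
                            "seed": seed,
                            "SE": m.sensitivity,
                            "SP": m.specificity,
                            "precision": m.precision,
                            "F1": m.f1,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_trials(results: pd.DataFrame) -> pd.DataFrame:
    """Across-seed mean and SD per grid cell."""
    return (
        results.groupby(["trial", "feature_set", "classifier"])[
            ["SE", "SP", "precision", "F1"]
        ]
        .agg(["mean", "std"])
        .reset_index()
    )
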