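"""BD-vs-HC classification benchmark.

Six classical classifiers (AdaBoost on decision trees with 100 learners,
KNN with k=5, Gaussian naive Bayes, random forest with 100 trees, linear SVM
with C=0.25, and a CART decision tree) are evaluated per paradigm with
repeated stratified k-fold cross-validation.  Splits are subject-level: every
row of one subject lands in the same fold, so epoch-level features cannot
leak across folds.  Features are z-scored inside each training fold only
(scikit-learn pipeline).  Accuracy and the F1 score of the BD (positive,
minority) class are reported as percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_FAMILIES

CLASSIFIER_NAMES: tuple[str, ...] = (
    "ensemble_adaboost", "knn", "naive_bayes",
    "random_forest", "svm_linear", "decision_tree",
)

POSITIVE_CLASS = "BD"


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier with its fixed hyperparameters."""

    name: str
    seed: int = 0

    def __post_init__(self):
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")

    def build(self) -> Pipeline:
        seed = self.seed
        estimators = {
            # AdaBoost.M1 with decision-tree (stump) weak learners, 100 rounds
            "ensemble_adaboost": lambda: AdaBoostClassifier(
                n_estimators=100, random_state=seed),
            "knn": lambda: KNeighborsClassifier(n_neighbors=5),
            "naive_bayes": lambda: GaussianNB(),
            "random_forest": lambda: RandomForestClassifier(
                n_estimators=100, max_features="sqrt", random_state=seed),
            "svm_linear": lambda: SVC(kernel="linear", C=0.25, random_state=seed),
            "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        }
        return Pipeline([("scale", StandardScaler()),
                         ("clf", estimators[self.name]())])


def default_specs(seed: int = 0) -> list[ClassifierSpec]:
    return [ClassifierSpec(name, seed=seed) for name in CLASSIFIER_NAMES]


@dataclass
class CVScheme:
    """Repeated stratified k-fold with subject-level splitting."""

    n_splits: int = 5
    n_repeats: int = 10
    unit: str = "subject"       # or "epoch": rows grouped by subject_id

    def describe(self) -> str:
        return f"stratified {self.n_splits}-fold x {self.n_repeats}, {self.unit}-level"


def _feature_columns(fm: pd.DataFrame) -> list[str]:
    prefixes = tuple(f"{fam}__" for fam in FEATURE_FAMILIES)
    return [c for c in fm.columns if c.startswith(prefixes)]


def _subject_folds(subjects, labels, scheme: CVScheme, seed: int):
    """Yield (train_row_idx, test_row_idx) with whole subjects per fold.

    Fold assignment is computed on the unique subjects (sorted, so epoch/row
    order never changes membership), stratified by group.
    """
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    subj_label = np.array([labels[subjects == s][0] for s in uniq])
    counts = pd.Series(subj_label).value_counts()
    if counts.min() < scheme.n_splits:
        raise ValueError(
            f"smallest class has {counts.min()} subjects < {scheme.n_splits} folds")
    for rep in range(scheme.n_repeats):
        skf = StratifiedKFold(n_splits=scheme.n_splits, shuffle=True,
                              random_state=seed + rep)
        for tr, te in skf.split(uniq, subj_label):
            tr_subj, te_subj = set(uniq[tr]), set(uniq[te])
            tr_rows = np.flatnonzero([s in tr_subj for s in subjects])
            te_rows = np.flatnonzero([s in te_subj for s in subjects])
            yield tr_rows, te_rows


def cross_validate(fm: pd.DataFrame, spec: ClassifierSpec,
                   scheme: Optional[CVScheme] = None, seed: int = 0) -> dict:
    """One classifier on one paradigm's feature matrix.

    Returns a report row with mean/SD accuracy and BD-class F1 (percent),
    the majority-class baseline, and fold-level values.
    """
    scheme = scheme or CVScheme()
    cols = _feature_columns(fm)
    if not cols:
        raise ValueError("no feature columns in matrix")
    X = fm[cols].to_numpy(float)
    y = fm["group"].to_numpy()
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    subjects = (fm.index.to_numpy() if fm.index.name == "subject_id"
                else fm["subject_id"].to_numpy())

    accs, f1s = [], []
    model = spec.build()
    for tr, te in _subject_folds(subjects, y, scheme, seed):
        est = clone(model)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        accs.append(accuracy_score(y[te], pred))
        f1s.append(f1_score(y[te], pred, pos_label=POSITIVE_CLASS, zero_division=0))
    accs, f1s = np.array(accs), np.array(f1s)
    majority = pd.Series(y).value_counts(normalize=True).max()
    return {
        "classifier": spec.name,
        "acc_mean": 100 * accs.mean(), "acc_sd": 100 * accs.std(),
        "f1_mean": 100 * f1s.mean(), "f1_sd": 100 * f1s.std(),
        "majority_baseline": 100 * majority,
        "n_subjects": int(len(np.unique(subjects))),
        "scheme": scheme.describe(), "seed": seed,
        "fold_acc": accs, "fold_f1": f1s,
    }


def run_benchmark(features_by_paradigm: dict[str, pd.DataFrame],
                  specs: Optional[Sequence[ClassifierSpec]] = None,
                  scheme: Optional[CVScheme] = None, seed: int = 0) -> pd.DataFrame:
    """Full grid of classifiers x paradigms plus a paradigm ranking.

    The ranking orders paradigms by their best-classifier mean accuracy; it is
    stored in ``DataFrame.attrs["ranking"]``.  A single available paradigm
    degenerates to a trivial ranking with a warning.
    """
    specs = list(specs) if specs is not None else default_specs(seed)
    rows = []
    for paradigm, fm in features_by_paradigm.items():
        if fm is None or len(fm) == 0:
            warnings.warn(f"paradigm {paradigm}: no features, skipped")
            continue
        for spec in specs:
            row = cross_validate(fm, spec, scheme=scheme, seed=seed)
            row.pop("fold_acc"), row.pop("fold_f1")
            row["paradigm"] = paradigm
            rows.append(row)
    if not rows:
        raise ValueError("no usable paradigms")
    report = pd.DataFrame(rows)
    best = report.groupby("paradigm")["acc_mean"].max().sort_values(ascending=False)
    if len(best) == 1:
        warnings.warn("single paradigm: ranking is degenerate")
    report.attrs["ranking"] = list(best.index)
    front = ["paradigm", "classifier", "acc_mean", "acc_sd", "f1_mean", "f1_sd",
             "majority_baseline", "n_subjects", "scheme", "seed"]
    return report[front]
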