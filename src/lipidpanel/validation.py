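"""Holdout segregation, hyperparameter tuning, and panel validation.

Validation asks one question: does a feature set carry enough information to
classify *unseen subjects* better than guessing?  Subjects (never individual
samples) are segregated into a 20% holdout before any selection or tuning.
Each of the 100 validation runs refits the tuned classifiers on a
subject-grouped 80% subsample of the training partition restricted to the
feature set under test, and evaluates on a random 80% subsample of the
holdout; medians and nonparametric 95% CIs (2.5th/97.5th percentiles) of
balanced accuracy and ROC-AUC summarize the runs.  Re-running with class
labels permuted in every training subsample is the overfitting control: an
honest pipeline must fall to balanced accuracy ~0.5 there.

Classifier families follow the study conventions: sigmoid-kernel SVM,
random forest (up to 1200 trees, depth 10), and newton-cg logistic
regression; grids are small and exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .data import ClassLabeling, LipidomicsDataset
from .errors import (
    MetricError,
    ParameterError,
    SchemaError,
    SplitError,
)

FAMILIES = ("svm", "rf", "logreg")

#: search grids per family; the study's tuned settings are members
GRIDS = {
    "svm": {"kernel": ["linear", "sigmoid"]},
    "rf": {"n_estimators": [200, 600, 1200], "max_depth": [5, 10, None]},
    "logreg": {"C": [0.1, 1.0, 10.0]},
}

#: pre-seeded defaults reproducing the study's tuned configurations
DEFAULT_SPECS = {
    "timepoint": {
        "svm": {"kernel": "sigmoid"},
        "rf": {"n_estimators": 1200, "max_depth": 10},
        "logreg": {"C": 1.0},
    },
    "neuropathy": {
        "svm": {"kernel": "sigmoid"},
        "rf": {"n_estimators": 200, "max_depth": 10},
        "logreg": {"C": 1.0},
    },
}


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    params: tuple = ()  # sorted (key, value) pairs
    tuned: bool = False

    @property
    def param_dict(self) -> dict:
        return dict(self.params)


def make_spec(family: str, params: dict, tuned: bool = False) -> ClassifierSpec:
    if family not in FAMILIES:
        raise ParameterError(f"unknown family {family!r}")
    return ClassifierSpec(family, tuple(sorted(params.items())), tuned)


def default_specs(task: str = "timepoint") -> list[ClassifierSpec]:
    base = DEFAULT_SPECS.get(task, DEFAULT_SPECS["timepoint"])
    return [make_spec(f, p) for f, p in base.items()]


def build_classifier(spec: ClassifierSpec, seed: int):
    p = spec.param_dict
    if spec.family == "svm":
        return SVC(kernel=p.get("kernel", "sigmoid"), C=p.get("C", 1.0),
                   random_state=seed)
    if spec.family == "rf":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 1200),
            max_depth=p.get("max_depth", 10),
            random_state=seed,
            n_jobs=1,
        )
    if spec.family == "logreg":
        # ridge (L2) penalized by default; newton-cg solver
        return LogisticRegression(
            C=p.get("C", 1.0), solver="newton-cg", max_iter=500, random_state=seed,
        )
    raise ParameterError(f"unknown family {spec.family!r}")


def _score_samples(fitted, X: np.ndarray) -> np.ndarray:
    """Continuous class score: margin (SVM), positive-class probability or
    vote fraction otherwise."""
    if hasattr(fitted, "decision_function"):
        return np.ravel(fitted.decision_function(X))
    return fitted.predict_proba(X)[:, 1]


# ---------------------------------------------------------------- metrics
def balanced_accuracy(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Mean of per-class recall."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise MetricError("length mismatch")
    classes = np.unique(y_true)
    if classes.size < 2:
        raise MetricError("y_true contains a single class")
    recalls = [
        float(np.mean(y_pred[y_true == c] == c)) for c in classes
    ]
    return float(np.mean(recalls))


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative; ties 1/2
    (Mann-Whitney formulation)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size < 2:
        raise MetricError("y_true contains a single class")
    from scipy.stats import rankdata

    pos = y_true == np.max(y_true)
    ranks = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# ------------------------------------------------------------------ split
def split_holdout(
    ds: LipidomicsDataset,
    labeling: ClassLabeling,
    fraction: float = 0.2,
    seed: int = 0,
    min_subjects_per_class: int = 5,
) -> tuple[LipidomicsDataset, LipidomicsDataset]:
    """Reserve a subject-grouped, class-proportional holdout.

    Subjects are stratified by the set of class labels their samples carry
    (paired subjects contribute to both timepoint classes and stay together);
    ``fraction`` of each stratum's subjects moves to the holdout with every
    one of their samples.
    """
    if not 0 < fraction < 1:
        raise ParameterError("fraction must be in (0, 1)")
    labeling = labeling.restrict(ds.sample_ids)
    subj = ds.subject_ids.loc[labeling.included_samples]
    strata: dict[str, list] = {}
    for s in pd.unique(subj):
        key = "+".join(sorted(set(labeling.labels[subj == s])))
        strata.setdefault(key, []).append(s)
    for cls in pd.unique(labeling.labels):
        n_subjects = len(pd.unique(subj[labeling.labels == cls]))
        if n_subjects < min_subjects_per_class:
            raise SplitError(
                f"class {cls!r} has {n_subjects} subjects; "
                f"need >= {min_subjects_per_class}"
            )
    rng = np.random.default_rng(seed)
    holdout_subjects: set = set()
    for key in sorted(strata):
        members = sorted(strata[key])
        k = max(1, int(round(fraction * len(members))))
        holdout_subjects.update(rng.choice(members, size=k, replace=False))
    in_holdout = ds.subject_ids.isin(holdout_subjects)
    train = ds.subset_samples(ds.sample_ids[~in_holdout])
    holdout = ds.subset_samples(ds.sample_ids[in_holdout])
    return train, holdout


# ------------------------------------------------------------------- tune
def tune(
    train: LipidomicsDataset,
    labeling: ClassLabeling,
    family: str,
    seed: int = 0,
    feature_set: Optional[Sequence[str]] = None,
    grid: Optional[dict] = None,
) -> ClassifierSpec:
    """5-fold grid search maximizing balanced accuracy; returns the winner."""
    labeling = labeling.restrict(train.sample_ids)
    cols = list(feature_set) if feature_set is not None else list(train.feature_names)
    X = train.values.loc[labeling.included_samples, cols].to_numpy()
    y = labeling.y
    grid = grid if grid is not None else GRIDS[family]
    base = build_classifier(make_spec(family, {}), seed)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    search = GridSearchCV(base, grid, scoring="balanced_accuracy", cv=cv, n_jobs=1)
    search.fit(X, y)
    return make_spec(family, search.best_params_, tuned=True)


# --------------------------------------------------------------- validate
@dataclass
class ValidationReport:
    """Per-run metrics and summaries for one feature set.

    ``runs`` has one row per (run, family) with balanced accuracy and
    ROC-AUC; ``summary`` one row per family with medians, percentile CIs and
    the chance-separation flag (CI excluding 0.5).
    """

    feature_set: list[str]
    permuted: bool
    runs: pd.DataFrame
    summary: pd.DataFrame

    def median(self, family: str, metric: str = "balanced_accuracy") -> float:
        return float(self.summary.loc[family, f"{metric}_median"])

    def ci(self, family: str, metric: str = "balanced_accuracy") -> tuple[float, float]:
        return (
            float(self.summary.loc[family, f"{metric}_lo"]),
            float(self.summary.loc[family, f"{metric}_hi"]),
        )

    def separated_from_chance(self, family: str) -> bool:
        return bool(self.summary.loc[family, "separated_from_chance"])


def _subject_grouped_subsample(
    labeling: ClassLabeling, subjects: pd.Series, fraction: float, rng
) -> pd.Index:
    """Class-proportional 80% subject draw; returns included sample ids."""
    strata: dict[str, list] = {}
    for s in pd.unique(subjects):
        key = "+".join(sorted(set(labeling.labels[subjects == s])))
        strata.setdefault(key, []).append(s)
    chosen: set = set()
    for key in sorted(strata):
        members = sorted(strata[key])
        k = max(1, int(round(fraction * len(members))))
        chosen.update(rng.choice(members, size=k, replace=False))
    return subjects.index[subjects.isin(chosen)]


def _summarize(runs: pd.DataFrame, feature_set, permuted) -> ValidationReport:
    rows = []
    for family, block in runs.groupby("family", sort=False):
        row = {"family": family}
        for metric in ("balanced_accuracy", "roc_auc"):
            vals = block[metric].to_numpy()
            row[f"{metric}_median"] = float(np.median(vals))
            row[f"{metric}_lo"] = float(np.percentile(vals, 2.5))
            row[f"{metric}_hi"] = float(np.percentile(vals, 97.5))
        row["separated_from_chance"] = (
            row["balanced_accuracy_lo"] > 0.5 or row["balanced_accuracy_hi"] < 0.5
        )
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("family")
    return ValidationReport(
        feature_set=list(feature_set), permuted=permuted, runs=runs, summary=summary
    )


def validate(
    train: LipidomicsDataset,
    holdout: LipidomicsDataset,
    labeling: ClassLabeling,
    feature_set: Sequence[str],
    specs: Optional[Sequence[ClassifierSpec]] = None,
    n_splits: int = 5,
    n_repeats: int = 20,
    seed: int = 0,
    permute: bool = False,
    train_fraction: float = 0.8,
    holdout_fraction: float = 0.8,
) -> ValidationReport:
    """100 (= n_splits x n_repeats) train-subsample/holdout-subsample runs.

    Each run draws a class-proportional subject-grouped ``train_fraction``
    subset of the training partition, fits every classifier family on the
    ``feature_set`` columns, and evaluates on a random sample-wise
    ``holdout_fraction`` subset of the holdout.  With ``permute=True`` the
    training labels of each run's subset are shuffled before fitting — the
    chance-level overfitting control.
    """
    feature_set = list(feature_set)
    if not feature_set:
        raise ParameterError("feature_set must be nonempty")
    for part, name in ((train, "train"), (holdout, "holdout")):
        missing = set(feature_set) - set(part.feature_names)
        if missing:
            raise SchemaError(f"{name} partition misses {sorted(missing)[:5]}")
    specs = list(specs) if specs is not None else default_specs(labeling.task)

    lab_train = labeling.restrict(train.sample_ids)
    lab_hold = labeling.restrict(holdout.sample_ids)
    subj_train = train.subject_ids.loc[lab_train.included_samples]
    X_train_all = train.values.loc[lab_train.included_samples, feature_set]
    X_hold_all = holdout.values.loc[lab_hold.included_samples, feature_set]
    y_hold_all = pd.Series(lab_hold.y, index=lab_hold.included_samples)

    rng = np.random.default_rng(seed)
    records = []
    n_runs = n_splits * n_repeats
    for run in range(n_runs):
        tr_ids = _subject_grouped_subsample(lab_train, subj_train, train_fraction, rng)
        Xtr = X_train_all.loc[tr_ids].to_numpy()
        ytr = lab_train.restrict(tr_ids).y
        if permute:
            ytr = rng.permutation(ytr)
        n_h = max(2, int(round(holdout_fraction * len(y_hold_all))))
        hold_ids = rng.choice(y_hold_all.index, size=n_h, replace=False)
        yte = y_hold_all.loc[hold_ids].to_numpy()
        if np.unique(yte).size < 2 or np.unique(ytr).size < 2:
            continue  # degenerate draw; metrics undefined
        Xte = X_hold_all.loc[hold_ids].to_numpy()
        run_seed = int(rng.integers(2**31))
        for spec in specs:
            clf = build_classifier(spec, run_seed)
            clf.fit(Xtr, ytr)
            pred = clf.predict(Xte)
            records.append(
                {
                    "run": run,
                    "family": spec.family,
                    "balanced_accuracy": balanced_accuracy(yte, pred),
                    "roc_auc": roc_auc(yte, _score_samples(clf, Xte)),
                }
            )
    runs = pd.DataFrame.from_records(records)
    return _summarize(runs, feature_set, permute)


# ----------------------------------------------------------------- frozen
def fit_frozen(
    train: LipidomicsDataset,
    labeling: ClassLabeling,
    feature_set: Sequence[str],
    specs: Optional[Sequence[ClassifierSpec]] = None,
    seed: int = 0,
    permute: bool = False,
) -> dict[str, object]:
    """Fit one classifier per family on the full training partition; the
    frozen models are what gets applied to an external cohort."""
    feature_set = list(feature_set)
    specs = list(specs) if specs is not None else default_specs(labeling.task)
    lab = labeling.restrict(train.sample_ids)
    X = train.values.loc[lab.included_samples, feature_set].to_numpy()
    y = lab.y
    rng = np.random.default_rng(seed)
    if permute:
        y = rng.permutation(y)
    frozen = {}
    for spec in specs:
        clf = build_classifier(spec, int(rng.integers(2**31)))
        clf.fit(X, y)
        frozen[spec.family] = clf
    return frozen


def external_apply(
    frozen_models: dict[str, object],
    external: LipidomicsDataset,
    labeling: ClassLabeling,
    feature_set: Sequence[str],
    n_splits: int = 5,
    n_repeats: int = 20,
    seed: int = 0,
    subsample_fraction: float = 0.8,
) -> ValidationReport:
    """Apply frozen classifiers to an external cohort without refitting.

    CIs come from repeated 80% sample-wise subsampling of the external cohort.
    """
    feature_set = list(feature_set)
    missing = set(feature_set) - set(external.feature_names)
    if missing:
        raise SchemaError(f"external cohort misses features {sorted(missing)[:5]}")
    lab = labeling.restrict(external.sample_ids)
    X_all = external.values.loc[lab.included_samples, feature_set]
    y_all = pd.Series(lab.y, index=lab.included_samples)
    rng = np.random.default_rng(seed)
    records = []
    for run in range(n_splits * n_repeats):
        n_h = max(2, int(round(subsample_fraction * len(y_all))))
        ids = rng.choice(y_all.index, size=n_h, replace=False)
        y = y_all.loc[ids].to_numpy()
        if np.unique(y).size < 2:
            continue
        X = X_all.loc[ids].to_numpy()
        for family, clf in frozen_models.items():
            records.append(
                {
                    "run": run,
                    "family": family,
                    "balanced_accuracy": balanced_accuracy(y, clf.predict(X)),
                    "roc_auc": roc_auc(y, _score_samples(clf, X)),
                }
            )
    runs = pd.DataFrame.from_records(records)
    return _summarize(runs, feature_set, permuted=False)
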