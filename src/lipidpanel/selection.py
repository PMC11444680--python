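"""Mixture-of-experts consensus feature selection.

Thirteen selectors — PCA variable importance, Cohen's d effect size, three
univariate F-test rules (per-test false-positive rate, Bonferroni family-wise
error rate, k-best), and SelectFromModel / recursive feature elimination /
k-best paired with each of three classifier families (linear SVM, random
forest, logistic regression) — each run on the training side of every fold of
a subject-grouped 5-fold x 20-repeat stratified cross-validation.  Selection
counts per method are condensed by computed ABC analysis into a per-method
category-A set; the consensus sum score of a feature is the number of methods
whose A set contains it (0..13).  cABC of the sum score yields the *reduced*
panel; nested cABC yields the *sparse* panel (sparse is always a subset of
reduced).

The holdout partition must be removed before calling :func:`run_moe`; nothing
here ever sees it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import LinearSVC

from .cabc import cabc_categorize, nested_cabc
from .data import ClassLabeling, LipidomicsDataset
from .errors import DegenerateTaskError, ParameterError
from .structure import pca_structure

logger = logging.getLogger(__name__)

MODELS = ("svm", "rf", "logreg")

#: fraction of the feature count eliminated per RFE round (floored to 1
#: feature for small panels, so toy problems eliminate one at a time)
RFE_STEP = 0.1

#: panel sizes scanned when tuning k for k-best / RFE
K_GRID = tuple(range(1, 19))


@dataclass(frozen=True)
class SelectorSpec:
    """One member of the selection ensemble."""

    id: str
    kind: str  # pca_importance | cohens_d | fpr | fwe | kbest | sfm | rfe
    model: Optional[str] = None  # svm | rf | logreg, for kbest/sfm/rfe
    alpha: float = 0.05


def default_ensemble() -> list[SelectorSpec]:
    """The 13-method ensemble: 4 univariate/PCA + 3 models x {kbest, sfm, rfe}."""
    specs = [
        SelectorSpec("pca_importance", "pca_importance"),
        SelectorSpec("cohens_d", "cohens_d"),
        SelectorSpec("fpr", "fpr"),
        SelectorSpec("fwe", "fwe"),
    ]
    for kind in ("kbest", "sfm", "rfe"):
        for model in MODELS:
            specs.append(SelectorSpec(f"{kind}_{model}", kind, model=model))
    return specs


@dataclass
class SelectionTally:
    """Per-method selection counts and the consensus feature sets."""

    counts: pd.DataFrame  # method x feature, 0..n_runs
    n_runs: int
    per_method_A: dict[str, list[str]]
    sum_score: pd.Series  # feature -> number of methods whose A contains it
    reduced_set: list[str]
    sparse_set: list[str]
    tuned_k: dict[str, int] = field(default_factory=dict)
    failures: list[str] = field(default_factory=list)


# ------------------------------------------------------------------ scores
def cohens_d_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Absolute two-sample Cohen's d per feature (pooled-variance SD).

    Features with zero pooled SD score 0.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateTaskError("Cohen's d needs exactly two classes")
    a, b = X[y == classes[0]], X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("both classes need at least 2 samples")
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.abs(a.mean(axis=0) - b.mean(axis=0)) / pooled
    d[~np.isfinite(d)] = 0.0
    return d


def _f_scores(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = f_classif(X, y)
    f = np.where(np.isfinite(f), f, 0.0)  # constant features: F treated as 0
    p = np.where(np.isfinite(p), p, 1.0)
    return f, p


def univariate_f_selection(
    X: np.ndarray,
    y: np.ndarray,
    mode: str,
    alpha: float = 0.05,
    k: Optional[int] = None,
) -> np.ndarray:
    """Univariate F-statistic selection; returns selected column indices.

    ``fpr``: p < alpha per test.  ``fwe``: p < alpha / d (Bonferroni).
    ``kbest``: top-k by F, ties resolved toward the smaller column index.
    """
    if np.unique(y).size != 2:
        raise DegenerateTaskError("univariate selection needs two classes")
    f, p = _f_scores(X, y)
    d = X.shape[1]
    if mode == "fpr":
        return np.flatnonzero(p < alpha)
    if mode == "fwe":
        return np.flatnonzero(p < alpha / d)
    if mode == "kbest":
        if k is None or not 1 <= k <= d:
            raise ParameterError(f"k={k} outside [1, {d}]")
        order = np.lexsort((np.arange(d), -f))  # stable: ties -> smaller index
        return np.sort(order[:k])
    raise ParameterError(f"unknown mode {mode!r}")


# ------------------------------------------------------------- model stock
def build_selection_model(model: str, seed: int, penalty: str = "l2"):
    """Selection-stage estimator: linear, light-weight, importance-exposing."""
    if model == "svm":
        return LinearSVC(penalty=penalty, dual=False, C=1.0, max_iter=5000,
                         random_state=seed)
    if model == "logreg":
        # default ridge (L2) regularization; newton-cg solver
        return LogisticRegression(solver="newton-cg", max_iter=200,
                                  random_state=seed)
    if model == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    raise ParameterError(f"unknown model {model!r}")


def _importances(fitted) -> np.ndarray:
    if hasattr(fitted, "coef_"):
        return np.abs(np.ravel(fitted.coef_))
    return fitted.feature_importances_


def tune_k(
    X: np.ndarray,
    y: np.ndarray,
    model: str,
    seed: int,
    k_grid: Sequence[int] = K_GRID,
    n_splits: int = 5,
) -> int:
    """Pick the k-best panel size by inner-CV balanced accuracy of the paired
    model, scanning the grid; ties go to the smaller (sparser) k."""
    k_grid = [k for k in k_grid if k <= X.shape[1]]
    if not k_grid:
        raise ParameterError("k grid empty after clipping to feature count")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    best_k, best_score = k_grid[0], -np.inf
    for k in k_grid:
        scores = []
        for tr, te in cv.split(X, y):
            cols = univariate_f_selection(X[tr], y[tr], "kbest", k=k)
            est = build_selection_model(model, seed)
            est.fit(X[tr][:, cols], y[tr])
            scores.append(balanced_accuracy_score(y[te], est.predict(X[te][:, cols])))
        mean = float(np.mean(scores))
        if mean > best_score + 1e-12:
            best_k, best_score = k, mean
    return best_k


# ----------------------------------------------------------- one selector
def selector_round(
    selector: SelectorSpec,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    tuned_k: Optional[dict[str, int]] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Run one selector on one training fold; returns selected column indices."""
    kind = selector.kind
    if kind == "cohens_d":
        d_scores = cohens_d_scores(X, y)
        if not (d_scores > 0).any():
            return np.array([], dtype=int)
        return cabc_categorize(d_scores).a_items
    if kind == "pca_importance":
        from .data import LipidomicsDataset  # local: avoid cycle at import time

        names = (
            list(feature_names)
            if feature_names is not None
            else [f"f{j}" for j in range(X.shape[1])]
        )
        ds = LipidomicsDataset(
            values=pd.DataFrame(X, index=[f"s{i}" for i in range(len(X))],
                                columns=names),
            subject_ids=[f"s{i}" for i in range(len(X))],
            timepoint=["day1"] * len(X),
            neuropathy=["unknown"] * len(X),
            log_transformed=True,
            standardized=True,
        )
        res = pca_structure(ds)
        name_ix = {nm: j for j, nm in enumerate(names)}
        return np.array(sorted(name_ix[nm] for nm in res.important_features), dtype=int)
    if kind in ("fpr", "fwe"):
        return univariate_f_selection(X, y, kind, alpha=selector.alpha)
    if kind == "kbest":
        k = (tuned_k or {}).get(selector.id, min(10, X.shape[1]))
        return univariate_f_selection(X, y, "kbest", k=k)
    if kind == "sfm":
        est = build_selection_model(selector.model, seed)
        est.fit(X, y)
        imp = _importances(est)
        if not np.isfinite(imp).all() or imp.sum() == 0:
            return np.array([], dtype=int)
        return np.flatnonzero(imp >= imp.mean())
    if kind == "rfe":
        k = (tuned_k or {}).get(selector.id, min(10, X.shape[1]))
        k = min(k, X.shape[1])
        est = build_selection_model(selector.model, seed)
        rfe = RFE(est, n_features_to_select=k, step=RFE_STEP)
        rfe.fit(X, y)
        return np.flatnonzero(rfe.support_)
    raise ParameterError(f"unknown selector kind {kind!r}")


# ------------------------------------------------------------- consensus
def grouped_stratified_folds(
    y: np.ndarray,
    groups: np.ndarray,
    n_splits: int,
    n_repeats: int,
    seed: int,
):
    """Repeated stratified k-fold with subjects never split across a fold."""
    rng = np.random.default_rng(seed)
    for _ in range(n_repeats):
        cv = StratifiedGroupKFold(
            n_splits=n_splits, shuffle=True, random_state=int(rng.integers(2**31))
        )
        yield from cv.split(np.zeros_like(y), y, groups)


def run_moe(
    ds: LipidomicsDataset,
    labeling: ClassLabeling,
    ensemble: Optional[Sequence[SelectorSpec]] = None,
    n_splits: int = 5,
    n_repeats: int = 20,
    seed: int = 0,
) -> SelectionTally:
    """Run the consensus ensemble over 5 x 20 subject-grouped CV folds.

    ``ds`` must be the (preprocessed, standardized) training partition only.
    Raises :class:`~lipidpanel.errors.ParameterError` when a class has fewer
    subjects than ``n_splits``.
    """
    ensemble = list(ensemble) if ensemble is not None else default_ensemble()
    labeling = labeling.restrict(ds.sample_ids)
    ids = labeling.included_samples
    X = ds.values.loc[ids].to_numpy()
    y = labeling.y
    groups = ds.subject_ids.loc[ids].to_numpy()
    features = list(ds.feature_names)

    for cls in np.unique(y):
        n_subj = len(np.unique(groups[y == cls]))
        if n_subj < n_splits:
            raise ParameterError(
                f"class {cls} has {n_subj} subjects; need >= {n_splits} for folds"
            )

    rng = np.random.default_rng(seed)
    tuned_k: dict[str, int] = {}
    for sel in ensemble:
        if sel.kind in ("kbest", "rfe"):
            key = f"kbest_{sel.model}"
            if key not in tuned_k:
                tuned_k[key] = tune_k(X, y, sel.model, seed=int(rng.integers(2**31)))
            tuned_k[sel.id] = tuned_k[key]

    counts = pd.DataFrame(
        0, index=[s.id for s in ensemble], columns=features, dtype=int
    )
    failures: list[str] = []
    n_runs = 0
    for tr, _ in grouped_stratified_folds(
        y, groups, n_splits, n_repeats, int(rng.integers(2**31))
    ):
        n_runs += 1
        fold_seed = int(rng.integers(2**31))
        for sel in ensemble:
            try:
                cols = selector_round(
                    sel, X[tr], y[tr], seed=fold_seed, tuned_k=tuned_k,
                    feature_names=features,
                )
            except Exception as exc:  # a failed selector skips this run only
                failures.append(f"run {n_runs} {sel.id}: {exc}")
                logger.warning("selector %s failed on run %d: %s", sel.id, n_runs, exc)
                continue
            counts.iloc[counts.index.get_loc(sel.id), cols] += 1

    per_method_A: dict[str, list[str]] = {}
    for sel_id in counts.index:
        row = counts.loc[sel_id].to_numpy(dtype=float)
        if not (row > 0).any():
            per_method_A[sel_id] = []
            continue
        res = cabc_categorize(row)
        per_method_A[sel_id] = [] if res.degenerate else [
            features[i] for i in res.a_items
        ]

    sum_score = pd.Series(0, index=features, dtype=int)
    for members in per_method_A.values():
        sum_score.loc[members] += 1

    if (sum_score > 0).any():
        reduced_res = cabc_categorize(sum_score.to_numpy(dtype=float))
        reduced = [features[i] for i in reduced_res.a_items]
        sparse_res = nested_cabc(sum_score.to_numpy(dtype=float), depth=2)
        sparse = [features[i] for i in sparse_res.a_items]
    else:
        reduced, sparse = [], []

    return SelectionTally(
        counts=counts,
        n_runs=n_runs,
        per_method_A=per_method_A,
        sum_score=sum_score,
        reduced_set=reduced,
        sparse_set=sparse,
        tuned_k=tuned_k,
        failures=failures,
    )


def univariate_ensemble() -> list[SelectorSpec]:
    """Fallback ensemble used when multivariate selection is not validated:
    effect size, per-test FPR, and family-wise-error univariate rules."""
    return [
        SelectorSpec("cohens_d", "cohens_d"),
        SelectorSpec("fpr", "fpr"),
        SelectorSpec("fwe", "fwe"),
    ]
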