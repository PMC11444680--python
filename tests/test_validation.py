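"""Metrics, holdout segregation, tuning, and panel validation runs."""

import numpy as np
import pytest

from lipidpanel import (
    balanced_accuracy,
    external_apply,
    fit_frozen,
    generate,
    log_transform,
    make_labeling,
    roc_auc,
    split_holdout,
    tune,
    validate,
    z_standardize,
)
from lipidpanel.errors import MetricError, ParameterError, SchemaError, SplitError
from lipidpanel.validation import make_spec

from conftest import make_dataset


# ---------------------------------------------------------------- metrics
def test_balanced_accuracy_perfect_and_constant():
    y = np.array([0, 0, 1, 1, 1])
    assert balanced_accuracy(y, y) == pytest.approx(1.0)
    assert balanced_accuracy(y, np.ones_like(y)) == pytest.approx(0.5)


def test_balanced_accuracy_hand_value():
    # sensitivity 3/4, specificity 2/4 -> 0.625
    y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    y_pred = np.array([1, 1, 1, 0, 0, 0, 1, 1])
    assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.625)


def test_balanced_accuracy_single_class_rejected():
    with pytest.raises(MetricError):
        balanced_accuracy([1, 1], [1, 0])


def test_roc_auc_perfect_ties_and_enumeration():
    assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(1.0)
    assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == pytest.approx(0.5)
    # pairwise enumeration: pairs (0.9>0.8), (0.9>0.2), (0.3<0.8), (0.3>0.2)
    assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.2]) == pytest.approx(0.75)


# ------------------------------------------------------------------ split
def test_split_keeps_subjects_together(default_dataset):
    ds, _ = default_dataset
    labeling = make_labeling(ds, "timepoint")
    train, hold = split_holdout(ds, labeling, seed=0)
    assert set(train.subject_ids).isdisjoint(hold.subject_ids)
    assert train.n_samples + hold.n_samples == ds.n_samples


def test_split_fraction_arithmetic():
    rng = np.random.default_rng(0)
    n = 40
    subjects = [f"p{i}" for i in range(n)]
    tp = ["day1"] * 20 + ["day2"] * 20
    npth = ["unknown"] * 20 + ["no"] * 20
    ds = make_dataset(rng.lognormal(size=(n, 4)), subjects=subjects,
                      timepoint=tp, neuropathy=npth)
    labeling = make_labeling(ds, "timepoint")
    train, hold = split_holdout(ds, labeling, fraction=0.2, seed=1)
    # 20 unpaired subjects per class -> 4 holdout subjects per class
    assert (hold.timepoint == "day1").sum() == 4
    assert (hold.timepoint == "day2").sum() == 4


def test_split_deterministic(default_dataset):
    ds, _ = default_dataset
    labeling = make_labeling(ds, "timepoint")
    a = split_holdout(ds, labeling, seed=5)[1].sample_ids
    b = split_holdout(ds, labeling, seed=5)[1].sample_ids
    assert list(a) == list(b)


def test_split_small_class_rejected():
    rng = np.random.default_rng(2)
    subjects = [f"p{i}" for i in range(6)]
    ds = make_dataset(rng.lognormal(size=(6, 3)), subjects=subjects,
                      timepoint=["day1"] * 3 + ["day2"] * 3,
                      neuropathy=["unknown"] * 3 + ["no", "no", "yes"])
    with pytest.raises(SplitError):
        split_holdout(ds, make_labeling(ds, "timepoint"), seed=0)


# ------------------------------------------------------------------- tune
def _separable_dataset(seed=3, n_per=20, d=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, d))
    X[n_per:, 0] += 6.0
    subjects = [f"p{i}" for i in range(2 * n_per)]
    tp = ["day1"] * n_per + ["day2"] * n_per
    npth = ["unknown"] * n_per + ["no"] * n_per
    return make_dataset(X, subjects=subjects, timepoint=tp, neuropathy=npth,
                        log_transformed=True, standardized=True)


def test_tune_single_point_grid_returns_it():
    ds = _separable_dataset()
    labeling = make_labeling(ds, "timepoint")
    spec = tune(ds, labeling, "svm", grid={"kernel": ["linear"]})
    assert spec.param_dict == {"kernel": "linear"}
    assert spec.tuned


def test_tune_matches_exhaustive_grid_oracle():
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    ds = _separable_dataset(seed=4)
    labeling = make_labeling(ds, "timepoint")
    grid = {"C": [0.1, 1.0, 10.0]}
    spec = tune(ds, labeling, "logreg", seed=7, grid=grid)
    from lipidpanel.validation import build_classifier

    X = ds.values.to_numpy()
    y = labeling.y
    scores = {}
    for c in grid["C"]:
        est = build_classifier(make_spec("logreg", {"C": c}), 7)
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=7)
        scores[c] = cross_val_score(est, X, y, scoring="balanced_accuracy",
                                    cv=cv).mean()
    best = max(scores, key=lambda c: scores[c])
    assert spec.param_dict["C"] == best


# --------------------------------------------------------------- validate
def _split_separable(seed=5):
    ds = _separable_dataset(seed=seed, n_per=30)
    labeling = make_labeling(ds, "timepoint")
    train, hold = split_holdout(ds, labeling, seed=seed)
    return ds, labeling, train, hold


FAST_SPECS = [
    make_spec("svm", {"kernel": "linear"}),
    make_spec("rf", {"n_estimators": 60, "max_depth": 5}),
    make_spec("logreg", {"C": 1.0}),
]


def test_validate_separable_feature_is_perfect():
    _, labeling, train, hold = _split_separable()
    rep = validate(train, hold, labeling, ["f0"], specs=FAST_SPECS,
                   n_repeats=4, seed=0)
    for fam in ("svm", "rf", "logreg"):
        assert rep.median(fam) == pytest.approx(1.0)
        assert rep.separated_from_chance(fam)


def test_validate_permuted_training_falls_to_chance():
    # noisy informative cohort (a perfectly separable toy would give a
    # bimodal 0/1 permuted distribution with an unstable median)
    from lipidpanel import SyntheticSpec, generate

    spec = SyntheticSpec(n_subjects=30, n_day1_only=8, n_features=20,
                         n_informative_time=4, effect_size_time=1.5,
                         missing_rate=0.0, seed=37)
    ds, truth = generate(spec)
    ds = log_transform(ds)
    labeling = make_labeling(ds, "timepoint")
    train, hold = split_holdout(ds, labeling, seed=6)
    dz = z_standardize(ds, fit_on=train.sample_ids)
    train = dz.subset_samples(train.sample_ids)
    hold = dz.subset_samples(hold.sample_ids)
    rep = validate(train, hold, labeling, truth.time_features, specs=FAST_SPECS,
                   n_repeats=10, seed=1, permute=True)
    pooled = rep.runs["balanced_accuracy"].to_numpy()
    assert 0.4 <= float(np.mean(pooled)) <= 0.6
    for fam in ("svm", "rf", "logreg"):
        lo, hi = rep.ci(fam)
        assert lo <= 0.5 <= hi
        assert 0.35 <= rep.median(fam) <= 0.65


def test_validate_pure_noise_not_separated_from_chance():
    rng = np.random.default_rng(7)
    n = 60
    X = rng.normal(size=(n, 5))
    subjects = [f"p{i}" for i in range(n)]
    tp = ["day1"] * (n // 2) + ["day2"] * (n // 2)
    npth = ["unknown"] * (n // 2) + ["no"] * (n // 2)
    ds = make_dataset(X, subjects=subjects, timepoint=tp, neuropathy=npth,
                      log_transformed=True, standardized=True)
    labeling = make_labeling(ds, "timepoint")
    train, hold = split_holdout(ds, labeling, seed=2)
    rep = validate(train, hold, labeling, list(ds.feature_names),
                   specs=FAST_SPECS, n_repeats=10, seed=2)
    assert not any(rep.separated_from_chance(f) for f in ("svm", "rf", "logreg"))


def test_validate_empty_feature_set_rejected():
    _, labeling, train, hold = _split_separable(seed=8)
    with pytest.raises(ParameterError):
        validate(train, hold, labeling, [], specs=FAST_SPECS)


# ----------------------------------------------------------- external
def test_external_apply_on_holdout_matches_validate():
    _, labeling, train, hold = _split_separable(seed=9)
    frozen = fit_frozen(train, labeling, ["f0"], specs=FAST_SPECS, seed=3)
    rep = external_apply(frozen, hold, labeling, ["f0"], n_repeats=4, seed=3)
    for fam in ("svm", "rf", "logreg"):
        assert rep.median(fam) == pytest.approx(1.0)


def test_external_apply_missing_feature_schema_error():
    _, labeling, train, hold = _split_separable(seed=10)
    frozen = fit_frozen(train, labeling, ["f0"], specs=FAST_SPECS, seed=4)
    hold_small = hold.subset_features(["f1", "f2", "f3"])
    with pytest.raises(SchemaError):
        external_apply(frozen, hold_small, labeling, ["f0"])


def test_external_attenuated_cohort_between_chance_and_primary():
    from lipidpanel import SyntheticSpec, generate_second_cohort

    spec = SyntheticSpec(missing_rate=0.0, seed=19)
    ds, truth = generate(spec)
    ds = log_transform(ds)
    labeling = make_labeling(ds, "timepoint")
    train, hold = split_holdout(ds, labeling, seed=4)
    dz = z_standardize(ds, fit_on=train.sample_ids)
    train_z = dz.subset_samples(train.sample_ids)
    hold_z = dz.subset_samples(hold.sample_ids)
    feats = truth.time_features
    frozen = fit_frozen(train_z, labeling, feats, specs=FAST_SPECS, seed=5)

    ext = generate_second_cohort(spec, truth, attenuation=0.4)
    ext = log_transform(ext)
    # external cohort standardized with its own statistics (its site, its scale)
    ext = z_standardize(ext)
    lab_ext = make_labeling(ext, "timepoint")
    rep_ext = external_apply(frozen, ext, lab_ext, feats, n_repeats=6, seed=5)
    rep_hold = external_apply(frozen, hold_z, labeling, feats, n_repeats=6, seed=5)
    for fam in ("svm", "logreg"):
        assert rep_ext.median(fam) < rep_hold.median(fam) + 0.05
    assert max(rep_ext.median(f) for f in ("svm", "rf", "logreg")) > 0.5


def test_permuted_frozen_models_are_chance_on_external():
    from lipidpanel import SyntheticSpec, generate_second_cohort

    spec = SyntheticSpec(missing_rate=0.0, seed=29)
    ds, truth = generate(spec)
    ds = z_standardize(log_transform(ds))
    labeling = make_labeling(ds, "timepoint")
    frozen = fit_frozen(ds, labeling, truth.time_features, specs=FAST_SPECS,
                        seed=6, permute=True)
    ext = z_standardize(log_transform(
        generate_second_cohort(spec, truth, attenuation=0.4)))
    lab_ext = make_labeling(ext, "timepoint")
    rep = external_apply(frozen, ext, lab_ext, truth.time_features,
                         n_repeats=10, seed=6)
    for fam in ("svm", "rf", "logreg"):
        assert 0.3 <= rep.median(fam) <= 0.7
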