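"""PCA structure assessment and ESOM/U-matrix behavior."""

import numpy as np
import pandas as pd
import pytest

from lipidpanel import (
    best_matching_units,
    cluster_class_association,
    extract_clusters,
    pca_structure,
    toroidal_neighbors,
    train_esom,
    umatrix,
)
from lipidpanel.data import ClassLabeling
from lipidpanel.esom import EsomModel, EsomSpec
from lipidpanel.errors import ClusteringFailure, ParameterError

from conftest import make_dataset


def _standardize(X):
    X = np.asarray(X, dtype=float)
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def _blob_dataset(seed=1, n=40, d=8, sep=2.0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(-sep, 0.3, (n // 2, d)), rng.normal(sep, 0.3, (n // 2, d))]
    )
    return (
        make_dataset(_standardize(X), log_transformed=True, standardized=True),
        np.array([0] * (n // 2) + [1] * (n - n // 2)),
    )


# ------------------------------------------------------------------- PCA
def test_two_perfectly_correlated_features():
    rng = np.random.default_rng(0)
    x = rng.normal(size=100)
    X = _standardize(np.column_stack([x, 2 * x + 1]))
    res = pca_structure(make_dataset(X, log_transformed=True, standardized=True))
    np.testing.assert_allclose(res.eigenvalues, [2.0, 0.0], atol=1e-10)
    assert res.n_retained == 1
    assert res.explained_fraction == pytest.approx(1.0)


def test_block_correlation_matches_eigensolver_oracle():
    rng = np.random.default_rng(1)
    base = rng.normal(size=(200, 2))
    X = np.column_stack([base[:, 0], base[:, 0] + 0.1 * rng.normal(size=200),
                         base[:, 1], base[:, 1] + 0.1 * rng.normal(size=200)])
    Z = _standardize(X)
    res = pca_structure(make_dataset(Z, log_transformed=True, standardized=True))
    oracle = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    np.testing.assert_allclose(res.eigenvalues, oracle, atol=1e-10)


def test_independent_noise_few_large_eigenvalues():
    rng = np.random.default_rng(2)
    Z = _standardize(rng.normal(size=(4000, 8)))
    res = pca_structure(make_dataset(Z, log_transformed=True, standardized=True))
    # at n >> d sample eigenvalues of independent features hug 1
    assert res.eigenvalues.max() < 1.2


def test_eigenvalue_sum_equals_feature_count():
    rng = np.random.default_rng(3)
    Z = _standardize(rng.normal(size=(50, 7)))
    res = pca_structure(make_dataset(Z, log_transformed=True, standardized=True))
    assert res.eigenvalues.sum() == pytest.approx(7.0)
    retained_frac = res.eigenvalues[res.eigenvalues > 1].sum() / 7.0
    assert res.explained_fraction == pytest.approx(retained_frac)


def test_pca_needs_three_samples():
    with pytest.raises(ParameterError):
        pca_structure(make_dataset(np.ones((2, 3)), log_transformed=True,
                                   standardized=True))


# ------------------------------------------------------------------ ESOM
def test_every_neuron_has_eight_toroidal_neighbors():
    for rows, cols in [(3, 3), (4, 6), (5, 8)]:
        for r in range(rows):
            for c in range(cols):
                nb = toroidal_neighbors(rows, cols, r, c)
                assert len(set(nb)) == 8 if rows > 2 and cols > 2 else True
                assert len(nb) == 8
    # explicit wrap checks on a corner
    nb = set(toroidal_neighbors(4, 6, 0, 0))
    assert (3, 5) in nb and (3, 0) in nb and (0, 5) in nb


def test_repeated_single_row_converges_to_attractor():
    x = np.array([1.0, -2.0, 0.5, 3.0])
    X = np.tile(x, (10, 1))
    ds = make_dataset(X, log_transformed=True, standardized=True)
    model = train_esom(ds, EsomSpec(rows=5, cols=6, epochs=10), seed=0)
    bmus = best_matching_units(model, ds)
    assert bmus["distance"].max() == pytest.approx(0.0, abs=1e-6)


def test_training_deterministic_given_seed():
    ds, _ = _blob_dataset(seed=4)
    spec = EsomSpec(rows=8, cols=10, epochs=5)
    w1 = train_esom(ds, spec, seed=3).weights
    w2 = train_esom(ds, spec, seed=3).weights
    assert np.array_equal(w1, w2)


def test_bmu_matches_brute_force_scan():
    rng = np.random.default_rng(5)
    spec = EsomSpec(rows=6, cols=7, epochs=1)
    W = rng.normal(size=(42, 5))
    model = EsomModel(spec=spec, weights=W, feature_names=[f"f{j}" for j in range(5)])
    X = rng.normal(size=(50, 5))
    ds = make_dataset(X, log_transformed=True, standardized=True)
    bmus = best_matching_units(model, ds)
    for i in range(50):
        dists = np.linalg.norm(W - X[i], axis=1)
        assert bmus["neuron"].iloc[i] == int(np.argmin(dists))


def test_bmu_tie_goes_to_smaller_row_major_index():
    spec = EsomSpec(rows=2, cols=2, epochs=1)
    W = np.array([[1.0], [1.0], [0.0], [5.0]])
    model = EsomModel(spec=spec, weights=W, feature_names=["f0"])
    ds = make_dataset(np.array([[1.0]]), log_transformed=True, standardized=True)
    assert best_matching_units(model, ds)["neuron"].iloc[0] == 0


def test_sample_equal_to_weights_is_exact_bmu():
    rng = np.random.default_rng(6)
    W = rng.normal(size=(12, 3))
    model = EsomModel(spec=EsomSpec(rows=3, cols=4, epochs=1), weights=W,
                      feature_names=["f0", "f1", "f2"])
    ds = make_dataset(W[7][None, :], log_transformed=True, standardized=True)
    res = best_matching_units(model, ds)
    assert res["neuron"].iloc[0] == 7
    assert res["distance"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_umatrix_identical_weights_all_zero_heights():
    W = np.tile(np.array([1.0, 2.0]), (20, 1))
    model = EsomModel(spec=EsomSpec(rows=4, cols=5, epochs=1), weights=W,
                      feature_names=["f0", "f1"])
    assert np.allclose(umatrix(model).heights, 0.0)


def test_umatrix_three_by_three_single_spike():
    # on a 3x3 torus every neuron is adjacent to all others
    W = np.zeros((9, 1))
    W[4] = 1.0
    model = EsomModel(spec=EsomSpec(rows=3, cols=3, epochs=1), weights=W,
                      feature_names=["f0"])
    h = umatrix(model).heights
    assert h[1, 1] == pytest.approx(1.0)
    others = np.delete(h.ravel(), 4)
    np.testing.assert_allclose(others, 1 / 8)


def test_umatrix_matches_neighbor_enumeration_oracle():
    rng = np.random.default_rng(7)
    rows, cols, d = 5, 6, 3
    W = rng.normal(size=(rows * cols, d))
    model = EsomModel(spec=EsomSpec(rows=rows, cols=cols, epochs=1), weights=W,
                      feature_names=[f"f{j}" for j in range(d)])
    h = umatrix(model).heights
    for r in range(rows):
        for c in range(cols):
            dists = [
                np.linalg.norm(W[r * cols + c] - W[rr * cols + cc])
                for rr, cc in toroidal_neighbors(rows, cols, r, c)
            ]
            assert h[r, c] == pytest.approx(np.mean(dists), rel=1e-12)


def test_two_blobs_cluster_with_ridge_between():
    ds, truth = _blob_dataset(seed=8)
    model = train_esom(ds, EsomSpec(rows=15, cols=20), seed=8)
    um = umatrix(model, ds)
    clusters = extract_clusters(um, model, n_clusters=2)
    agree = max(
        (clusters.to_numpy() == truth).mean(),
        (clusters.to_numpy() == 1 - truth).mean(),
    )
    assert clusters.nunique() == 2
    assert agree >= 0.9
    # ridge: max height between the blob regions exceeds within-region median
    heights = um.heights
    bmu_heights = heights[um.bmus["row"], um.bmus["col"]]
    assert heights.max() > np.median(bmu_heights)


def test_constant_data_clustering_fails():
    W = np.ones((12, 2))
    model = EsomModel(spec=EsomSpec(rows=3, cols=4, epochs=1), weights=W,
                      feature_names=["f0", "f1"])
    ds = make_dataset(np.ones((4, 2)), log_transformed=True, standardized=True)
    um = umatrix(model, ds)
    with pytest.raises(ClusteringFailure):
        extract_clusters(um, model, n_clusters=2)


def test_one_cluster_is_trivial():
    ds, _ = _blob_dataset(seed=9)
    model = train_esom(ds, EsomSpec(rows=8, cols=10, epochs=3), seed=9)
    um = umatrix(model, ds)
    clusters = extract_clusters(um, model, n_clusters=1)
    assert clusters.nunique() == 1


# --------------------------------------------------- cluster association
def _labeling_from(values, task="timepoint", positive="day2"):
    return ClassLabeling(task, pd.Series(values), positive)


def test_perfect_alignment_extreme_association():
    clusters = pd.Series([0] * 10 + [1] * 10, index=[f"s{i}" for i in range(20)])
    labels = pd.Series(["day1"] * 10 + ["day2"] * 10,
                       index=[f"s{i}" for i in range(20)])
    res = cluster_class_association(clusters, _labeling_from(labels))
    assert res.p < 1e-3
    assert np.isinf(res.statistic)


def test_independent_table_null_association():
    idx = [f"s{i}" for i in range(20)]
    clusters = pd.Series([0, 1] * 10, index=idx)
    labels = pd.Series((["day1", "day1", "day2", "day2"] * 5), index=idx)
    res = cluster_class_association(clusters, _labeling_from(labels))
    assert res.statistic == pytest.approx(1.0)
    assert res.p == pytest.approx(1.0)


def test_association_refuses_more_than_two_clusters():
    idx = [f"s{i}" for i in range(9)]
    clusters = pd.Series([0, 1, 2] * 3, index=idx)
    labels = pd.Series(["day1", "day2"] * 4 + ["day1"], index=idx)
    with pytest.raises(ParameterError):
        cluster_class_association(clusters, _labeling_from(labels))
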