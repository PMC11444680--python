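"""Preprocessing: transformation choice, missingness filtering, imputation,
standardization.

The stage mirrors common omics practice: scan Tukey's ladder of powers for the
transform that makes the most features pass a D'Agostino-Pearson normality
test (log-normal concentrations select the log), drop features and then
samples whose missing fraction exceeds 20%, impute remaining gaps with an
iterative random-forest scheme, and z-standardize per feature with statistics
estimated on the fitting partition only (so holdout samples never leak into
the scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .data import LipidomicsDataset
from .errors import (
    ConstantFeatureError,
    DomainError,
    EmptyDatasetError,
    ImputationError,
    ParameterError,
    SampleSizeError,
)

#: Tukey ladder exponents scanned by default; 0 stands for the natural log.
DEFAULT_LADDER = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)

_MIN_N_NORMALTEST = 20  # kurtosis normalization is unreliable below this


@dataclass
class TransformReport:
    candidate_powers: tuple[float, ...]
    #: per-candidate DataFrame with K2 statistic and p per feature
    normality: dict[float, pd.DataFrame]
    normal_counts: dict[float, int]
    chosen_power: float


@dataclass
class PreprocessReport:
    dropped_features: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)
    imputed_cells: list[tuple[str, str]] = field(default_factory=list)
    standardization_means: Optional[pd.Series] = None
    standardization_sds: Optional[pd.Series] = None


def dagostino_pearson(values: Sequence[float]) -> tuple[float, float]:
    """Omnibus normality test K2 = Z(skew)^2 + Z(kurtosis)^2, chi^2(2) p-value.

    Missing entries are dropped first; fewer than 20 observations raise
    :class:`~lipidpanel.errors.SampleSizeError` because the kurtosis
    normalizing transform is undefined for tiny samples.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < _MIN_N_NORMALTEST:
        raise SampleSizeError(
            f"normality test needs >= {_MIN_N_NORMALTEST} observations, got {x.size}"
        )
    k2, p = stats.normaltest(x)
    return float(k2), float(p)


def tukey_transform(x: np.ndarray, power: float) -> np.ndarray:
    """Apply one rung of Tukey's ladder (power 0 -> natural log)."""
    if power == 0.0:
        return np.log(x)
    return np.power(x, power)


def scan_tukey_ladder(
    ds: LipidomicsDataset,
    powers: Sequence[float] = DEFAULT_LADDER,
    alpha: float = 0.05,
) -> TransformReport:
    """Pick the ladder exponent that maximizes the count of normal features.

    For each candidate power, every feature is transformed and tested with the
    D'Agostino-Pearson omnibus test; the chosen power maximizes the number of
    features with p > ``alpha``, ties resolved toward the power closest to 1
    (mildest transformation).
    """
    powers = tuple(powers)
    normality: dict[float, pd.DataFrame] = {}
    counts: dict[float, int] = {}
    X = ds.values.to_numpy()
    for lam in powers:
        if lam <= 0:
            bad = np.nanmin(X, axis=0) <= 0
            if bad.any():
                name = ds.feature_names[int(np.argmax(bad))]
                raise DomainError(
                    f"feature {name!r} has nonpositive values; power {lam} undefined"
                )
        rows = []
        n_ok = 0
        for j, feat in enumerate(ds.feature_names):
            col = X[:, j]
            col = col[~np.isnan(col)]
            k2, p = dagostino_pearson(tukey_transform(col, lam))
            rows.append((feat, k2, p))
            n_ok += p > alpha
        normality[lam] = pd.DataFrame(rows, columns=["feature", "K2", "p"]).set_index(
            "feature"
        )
        counts[lam] = n_ok
    best = max(counts.values())
    chosen = min(
        (lam for lam in powers if counts[lam] == best), key=lambda lam: abs(lam - 1)
    )
    return TransformReport(powers, normality, counts, chosen)


def log_transform(ds: LipidomicsDataset) -> LipidomicsDataset:
    """Natural-log transform all concentrations (rung 0 of the ladder)."""
    if ds.log_transformed:
        return ds
    if np.nanmin(ds.values.to_numpy()) <= 0:
        raise DomainError("log transform requires strictly positive values")
    return replace(ds, values=np.log(ds.values), log_transformed=True)


def filter_missing(
    ds: LipidomicsDataset, threshold: float = 0.2
) -> tuple[LipidomicsDataset, PreprocessReport]:
    """Drop features, then samples, whose missing fraction exceeds ``threshold``.

    Cells exactly at the threshold are retained (drop only if strictly
    greater).  Features go first so that a handful of badly measured analytes
    cannot disqualify patients.
    """
    if not 0 < threshold < 1:
        raise ParameterError("threshold must be in (0, 1)")
    miss = ds.values.isna()
    feat_frac = miss.mean(axis=0)
    keep_feats = ds.feature_names[feat_frac.to_numpy() <= threshold]
    if len(keep_feats) == 0:
        raise EmptyDatasetError("every feature exceeds the missingness threshold")
    reduced = ds.subset_features(keep_feats)
    samp_frac = reduced.values.isna().mean(axis=1)
    keep_samps = reduced.sample_ids[samp_frac.to_numpy() <= threshold]
    if len(keep_samps) == 0:
        raise EmptyDatasetError("every sample exceeds the missingness threshold")
    out = reduced.subset_samples(keep_samps)
    report = PreprocessReport(
        dropped_features=[f for f in ds.feature_names if f not in set(keep_feats)],
        dropped_samples=[s for s in ds.sample_ids if s not in set(keep_samps)],
    )
    return out, report


def rf_impute(
    ds: LipidomicsDataset,
    seed: int,
    max_iter: int = 10,
    tol: float = 1e-3,
    n_estimators: int = 100,
) -> tuple[LipidomicsDataset, PreprocessReport]:
    """Iterative random-forest imputation (missForest-style).

    Missing cells are initialized with feature medians; features are then
    revisited in order of increasing missingness, each regressed on all others
    with a random forest (mtry = sqrt(p), the usual forest-imputation default)
    and its missing cells overwritten with the forest's predictions.  Sweeps
    stop when the normalized change of the imputed values falls below ``tol``,
    starts increasing again (the standard divergence criterion), or
    ``max_iter`` is reached.  Observed cells are never touched.  Deterministic
    given ``seed``.
    """
    X = ds.values.to_numpy(copy=True)
    miss = np.isnan(X)
    if not miss.any():
        return ds.copy(), PreprocessReport()
    n_obs = (~miss).sum(axis=0)
    if (n_obs < 2).any():
        j = int(np.argmax(n_obs < 2))
        raise ImputationError(
            f"feature {ds.feature_names[j]!r} has fewer than 2 observed values"
        )
    medians = np.nanmedian(X, axis=0)
    filled = X.copy()
    for j in range(X.shape[1]):
        filled[miss[:, j], j] = medians[j]

    order = np.argsort(miss.sum(axis=0))
    order = [j for j in order if miss[:, j].any()]
    rng = np.random.default_rng(seed)
    prev_delta = np.inf
    best = filled.copy()
    for _ in range(max_iter):
        prev = filled.copy()
        for j in order:
            rows_miss = miss[:, j]
            others = np.delete(filled, j, axis=1)
            forest = RandomForestRegressor(
                n_estimators=n_estimators,
                max_features="sqrt",
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            forest.fit(others[~rows_miss], filled[~rows_miss, j])
            filled[rows_miss, j] = forest.predict(others[rows_miss])
        num = float(np.sum((filled[miss] - prev[miss]) ** 2))
        den = float(np.sum(filled[miss] ** 2))
        delta = np.inf if den == 0 else num / den
        if delta < tol:
            best = filled
            break
        if delta >= prev_delta:  # diverging: keep the previous sweep's state
            best = prev
            break
        best = filled.copy()
        prev_delta = delta
    filled = best

    values = pd.DataFrame(filled, index=ds.sample_ids, columns=ds.feature_names)
    report = PreprocessReport(
        imputed_cells=[
            (ds.sample_ids[i], ds.feature_names[j]) for i, j in zip(*np.nonzero(miss))
        ]
    )
    return replace(ds, values=values), report


def z_standardize(
    ds: LipidomicsDataset, fit_on: Optional[Sequence] = None
) -> LipidomicsDataset:
    """Per-feature z-score with mean/SD estimated on ``fit_on`` rows only.

    ``fit_on`` defaults to all samples; inside cross-validation it must be the
    training partition so holdout statistics never leak into the scaling.
    """
    if not ds.log_transformed:
        raise ParameterError("standardize after log transformation")
    fit_ids = ds.sample_ids if fit_on is None else pd.Index(fit_on)
    if len(fit_ids) == 0:
        raise ParameterError("fit_on must be nonempty")
    fit_vals = ds.values.loc[fit_ids]
    means = fit_vals.mean(axis=0)
    sds = fit_vals.std(axis=0, ddof=1)
    zero = sds <= 0
    if zero.any():
        raise ConstantFeatureError(
            f"constant feature(s) on fitting partition: "
            f"{list(sds.index[zero])[:5]}"
        )
    values = (ds.values - means) / sds
    return replace(
        ds,
        values=values,
        standardized=True,
        standardization_means=means,
        standardization_sds=sds,
    )
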