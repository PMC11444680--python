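"""PCA-based structure assessment with cABC variable contributions.

The Kaiser criterion retains principal components of the feature correlation
matrix whose eigenvalue exceeds 1 (a component must explain more than one
original variable's worth of variance).  A feature's importance is its
variance contribution to the retained components: the squared loading on each
retained component weighted by that component's explained-variance fraction,
summed.  Computed ABC analysis of the importance vector yields the
"important few" features that drive the retained structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cabc import cabc_categorize
from .data import ClassLabeling, LipidomicsDataset
from .errors import ParameterError
from .stats import TestResult, fisher_exact


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # nonincreasing
    n_retained: int  # Kaiser: eigenvalue strictly > 1
    explained_fraction: float  # cumulative variance share of retained set
    loadings: pd.DataFrame  # feature x component, loading = eigvec * sqrt(eig)
    importance: pd.Series  # per-feature weighted contribution
    important_features: list[str]  # cABC category A of the importance vector


def pca_structure(ds: LipidomicsDataset) -> PcaResult:
    """Eigen-decompose the feature correlation matrix; Kaiser retention.

    Requires standardized data and at least 3 samples.  The correlation-matrix
    trace equals the number of features, so eigenvalue fractions are
    eigenvalue / d.
    """
    if ds.n_samples < 3:
        raise ParameterError("PCA needs at least 3 samples")
    if not ds.standardized:
        raise ParameterError("PCA operates on standardized data")
    X = ds.values.to_numpy()
    corr = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]

    retained = eigval > 1.0
    n_ret = int(retained.sum())
    d = ds.n_features
    explained = float(eigval[retained].sum() / eigval.sum())

    loadings = eigvec * np.sqrt(eigval)[None, :]
    frac = eigval / d
    importance = (loadings[:, retained] ** 2 * frac[retained][None, :]).sum(axis=1)
    importance = pd.Series(importance, index=ds.feature_names)
    abc = cabc_categorize(importance.to_numpy())
    important = [ds.feature_names[i] for i in abc.a_items]

    comp_names = [f"PC{k + 1}" for k in range(d)]
    return PcaResult(
        eigenvalues=eigval,
        n_retained=n_ret,
        explained_fraction=explained,
        loadings=pd.DataFrame(loadings, index=ds.feature_names, columns=comp_names),
        importance=importance,
        important_features=important,
    )


def cluster_class_association(
    clusters: pd.Series, labeling: ClassLabeling
) -> TestResult:
    """Fisher's exact test of the 2x2 cluster x class contingency table.

    Refuses anything but exactly two clusters and two classes, matching the
    two-cluster U-matrix reading the pipeline targets.
    """
    common = clusters.index.intersection(labeling.included_samples)
    cl = clusters.loc[common]
    la = labeling.labels.loc[common]
    cl_levels = sorted(pd.unique(cl))
    la_levels = sorted(pd.unique(la))
    if len(cl_levels) != 2:
        raise ParameterError(f"need exactly 2 clusters, got {len(cl_levels)}")
    if len(la_levels) != 2:
        raise ParameterError(f"need exactly 2 classes, got {len(la_levels)}")
    table = np.array(
        [
            [int(((cl == c) & (la == l)).sum()) for l in la_levels]
            for c in cl_levels
        ]
    )
    return fisher_exact(table)
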