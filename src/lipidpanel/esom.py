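"""Emergent self-organizing map (ESOM) with U-matrix clustering.

An ESOM is a self-organizing map with far more neurons (thousands) than
expected clusters, arranged on a toroidal grid so the map has no edges.  After
training, each sample's best matching unit (BMU) is the neuron whose weight
vector is nearest; emergent structure is read from the U-matrix, the
per-neuron mean high-dimensional distance to its eight immediate toroidal
neighbors.  Low U-heights form "valleys" (dense regions); ridges of high
U-height mark cluster borders, which :func:`extract_clusters` reads by
thresholding the height field and taking connected components of the valleys.

Default geometry is a 50 x 80 toroid (4000 neurons) trained for 20 online
epochs; weights are initialized by sampling data rows with replacement, and
learning rate / Gaussian neighborhood radius decay linearly over the updates
from (0.5, max(rows, cols)/2) to (0.01, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data import LipidomicsDataset
from .errors import ClusteringFailure, ParameterError


@dataclass(frozen=True)
class EsomSpec:
    rows: int = 50
    cols: int = 80
    epochs: int = 20
    lr_start: float = 0.5
    lr_end: float = 0.01
    radius_start: Optional[float] = None  # default max(rows, cols) / 2
    radius_end: float = 1.0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ParameterError("grid must be at least 2x2")
        if self.epochs < 1:
            raise ParameterError("need at least one epoch")


@dataclass
class EsomModel:
    spec: EsomSpec
    weights: np.ndarray  # (rows * cols, n_features), row-major neuron order
    feature_names: list[str]

    @property
    def rows(self) -> int:
        return self.spec.rows

    @property
    def cols(self) -> int:
        return self.spec.cols

    def neuron_coords(self, index: np.ndarray) -> np.ndarray:
        """Row-major neuron index -> (row, col) coordinates."""
        return np.column_stack(np.divmod(index, self.cols))


@dataclass
class UMatrix:
    heights: np.ndarray  # (rows, cols) mean distance to 8 toroidal neighbors
    bmus: pd.DataFrame  # per sample: row, col, neuron index
    clusters: Optional[pd.Series] = None  # per-sample cluster id


def toroidal_neighbors(rows: int, cols: int, r: int, c: int) -> list[tuple[int, int]]:
    """The 8 immediate neighbors of (r, c) with wrap-around."""
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            out.append(((r + dr) % rows, (c + dc) % cols))
    return out


def _grid_dist2(rows: int, cols: int) -> np.ndarray:
    """Squared toroidal grid distance between all neuron pairs, (N, N)."""
    r = np.arange(rows * cols) // cols
    c = np.arange(rows * cols) % cols
    dr = np.abs(r[:, None] - r[None, :])
    dr = np.minimum(dr, rows - dr)
    dc = np.abs(c[:, None] - c[None, :])
    dc = np.minimum(dc, cols - dc)
    return (dr**2 + dc**2).astype(float)


def train_esom(
    ds: LipidomicsDataset, spec: EsomSpec = EsomSpec(), seed: int = 0
) -> EsomModel:
    """Fit a toroidal SOM to the (standardized) dataset rows.

    Online updates: per step, the BMU of one sample is found and every
    neuron's weights move toward the sample proportionally to a Gaussian of
    its toroidal grid distance to the BMU.  Sample order is reshuffled each
    epoch; deterministic given ``seed``.
    """
    X = ds.values.to_numpy()
    n, d = X.shape
    if n < 2:
        raise ParameterError("need at least 2 samples")
    if np.isnan(X).any():
        raise ParameterError("impute missing values before training")
    rng = np.random.default_rng(seed)
    n_neurons = spec.rows * spec.cols
    weights = X[rng.integers(0, n, size=n_neurons)].astype(float).copy()
    dist2 = _grid_dist2(spec.rows, spec.cols)

    radius_start = spec.radius_start
    if radius_start is None:
        radius_start = max(spec.rows, spec.cols) / 2.0
    total_steps = spec.epochs * n
    step = 0
    for _ in range(spec.epochs):
        for i in rng.permutation(n):
            frac = step / max(total_steps - 1, 1)
            lr = spec.lr_start + frac * (spec.lr_end - spec.lr_start)
            radius = radius_start + frac * (spec.radius_end - radius_start)
            x = X[i]
            diff = weights - x[None, :]
            bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            h = lr * np.exp(-dist2[bmu] / (2.0 * radius**2))
            weights -= h[:, None] * diff
            step += 1
    return EsomModel(spec=spec, weights=weights, feature_names=list(ds.feature_names))


def best_matching_units(model: EsomModel, ds: LipidomicsDataset) -> pd.DataFrame:
    """Per-sample BMU: neuron minimizing Euclidean distance (ties -> smallest
    row-major index).  Returns a DataFrame with row, col, neuron, distance."""
    if not set(model.feature_names) <= set(ds.feature_names):
        raise ParameterError("dataset features do not match the trained map")
    X = ds.values[model.feature_names].to_numpy()
    d2 = (
        np.einsum("ij,ij->i", X, X)[:, None]
        - 2.0 * X @ model.weights.T
        + np.einsum("ij,ij->i", model.weights, model.weights)[None, :]
    )
    bmu = np.argmin(d2, axis=1)  # argmin returns the first (smallest) index
    coords = model.neuron_coords(bmu)
    # recompute the winning distances directly; the expanded form above is
    # fast for the argmin but loses precision near zero
    exact = np.linalg.norm(X - model.weights[bmu], axis=1)
    return pd.DataFrame(
        {
            "row": coords[:, 0],
            "col": coords[:, 1],
            "neuron": bmu,
            "distance": exact,
        },
        index=ds.sample_ids,
    )


def umatrix(model: EsomModel, ds: Optional[LipidomicsDataset] = None) -> UMatrix:
    """U-matrix heights: per neuron, the mean weight-space distance to its 8
    toroidal neighbors.  BMUs are attached when a dataset is given."""
    rows, cols = model.rows, model.cols
    W = model.weights.reshape(rows, cols, -1)
    heights = np.zeros((rows, cols))
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(np.roll(W, dr, axis=0), dc, axis=1)
            heights += np.linalg.norm(W - shifted, axis=2)
    heights /= 8.0
    bmus = (
        best_matching_units(model, ds)
        if ds is not None
        else pd.DataFrame(columns=["row", "col", "neuron", "distance"])
    )
    return UMatrix(heights=heights, bmus=bmus)


def _components(mask: np.ndarray) -> np.ndarray:
    """Label 8-connected toroidal components of a boolean grid (-1 = off)."""
    rows, cols = mask.shape
    labels = np.full(mask.shape, -1, dtype=int)
    current = 0
    for r0 in range(rows):
        for c0 in range(cols):
            if not mask[r0, c0] or labels[r0, c0] >= 0:
                continue
            stack = [(r0, c0)]
            labels[r0, c0] = current
            while stack:
                r, c = stack.pop()
                for rr, cc in toroidal_neighbors(rows, cols, r, c):
                    if mask[rr, cc] and labels[rr, cc] < 0:
                        labels[rr, cc] = current
                        stack.append((rr, cc))
            current += 1
    return labels


def _toroidal_dist2(rows: int, cols: int, a: tuple[int, int], b: np.ndarray) -> np.ndarray:
    dr = np.abs(a[0] - b[:, 0])
    dr = np.minimum(dr, rows - dr)
    dc = np.abs(a[1] - b[:, 1])
    dc = np.minimum(dc, cols - dc)
    return dr**2 + dc**2


def extract_clusters(
    um: UMatrix, model: EsomModel, n_clusters: int = 2
) -> pd.Series:
    """Cluster samples by thresholding the U-matrix valleys.

    Scans height quantiles from high to low and stops at the first (largest)
    threshold at which the below-threshold neurons form at least
    ``n_clusters`` 8-connected toroidal components that contain BMUs — the
    threshold just under the separating ridge, where the valley floor first
    splits.  Samples inherit their BMU's component; BMUs sitting above the
    threshold (on a ridge) join the component nearest by toroidal grid
    distance.  Raises :class:`~lipidpanel.errors.ClusteringFailure` when no
    threshold works (e.g. a flat height field).
    """
    if um.bmus.empty:
        raise ParameterError("compute BMUs before clustering")
    if n_clusters < 1:
        raise ParameterError("n_clusters must be >= 1")
    if n_clusters == 1:
        return pd.Series(0, index=um.bmus.index, name="cluster")
    heights = um.heights
    if np.allclose(heights, heights.flat[0]):
        raise ClusteringFailure("flat U-matrix: no ridge to split on")
    bmu_coords = um.bmus[["row", "col"]].to_numpy()
    rows, cols = heights.shape
    for q in np.linspace(0.95, 0.05, 19):
        thr = np.quantile(heights, q)
        labels = _components(heights <= thr)
        bmu_labels = labels[bmu_coords[:, 0], bmu_coords[:, 1]]
        used = np.unique(bmu_labels[bmu_labels >= 0])
        if used.size >= n_clusters:
            # attach ridge-top BMUs to the nearest used component
            comp_cells = {
                comp: np.argwhere(labels == comp) for comp in used
            }
            out = np.empty(len(bmu_labels), dtype=int)
            for i, lab in enumerate(bmu_labels):
                if lab in comp_cells:
                    out[i] = int(np.flatnonzero(used == lab)[0])
                else:
                    cell = (int(bmu_coords[i, 0]), int(bmu_coords[i, 1]))
                    dists = [
                        _toroidal_dist2(rows, cols, cell, comp_cells[comp]).min()
                        for comp in used
                    ]
                    out[i] = int(np.argmin(dists))
            return pd.Series(out, index=um.bmus.index, name="cluster")
    raise ClusteringFailure(
        f"no threshold yields {n_clusters} BMU-bearing components"
    )


def plot_umatrix(um: UMatrix, ax=None):
    """Render the U-matrix as a topographic map with BMU markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(um.heights, cmap="terrain", origin="lower")
    if not um.bmus.empty:
        ax.scatter(um.bmus["col"], um.bmus["row"], c="k", s=12)
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.figure.colorbar(im, ax=ax, label="U-height")
    return ax
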