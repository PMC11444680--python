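"""Dataset container and tabular I/O.

The whole pipeline works on a single in-memory object, :class:`LipidomicsDataset`:
a samples x lipid-mediators concentration matrix together with the sample
metadata (subject pairing, sampling timepoint, neuropathy outcome) and optional
per-feature lipid-class annotations.  The container enforces the invariants the
downstream stages rely on:

* sample ids and feature names are unique;
* a subject contributes at most one sample per timepoint (pre/post design);
* the neuropathy outcome is defined only on post-therapy (day-2) samples —
  pre-therapy rows carry ``"unknown"`` and receive the subject's eventual label
  only through an explicit subject join, never as a day-1 class.

Missing concentrations are stored as NaN.  On disk the accepted missing tokens
are the empty cell and ``NA`` (case-insensitive); any other non-numeric cell is
a hard :class:`~lipidpanel.errors.FormatError`, so silent data loss cannot
happen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DegenerateTaskError,
    FormatError,
    JoinError,
)

TIMEPOINTS = ("day1", "day2")
NEUROPATHY_LEVELS = ("yes", "no", "unknown")
_MISSING_TOKENS = {"", "na"}


@dataclass
class LipidomicsDataset:
    """Samples x lipid-mediators matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per lipid mediator.
        NaN encodes a missing concentration.
    subject_ids
        Subject id per sample (aligned with ``values.index``); pairs the
        pre- and post-therapy samples of one patient.
    timepoint
        ``"day1"`` (before therapy) or ``"day2"`` (after) per sample.
    neuropathy
        ``"yes"``/``"no"`` on day-2 samples, ``"unknown"`` elsewhere.
    feature_class
        Optional lipid-class label per feature (e.g. ``"sphingolipid"``),
        indexed by feature name.
    """

    values: pd.DataFrame
    subject_ids: pd.Series
    timepoint: pd.Series
    neuropathy: pd.Series
    feature_class: Optional[pd.Series] = None
    log_transformed: bool = False
    standardized: bool = False
    standardization_means: Optional[pd.Series] = None
    standardization_sds: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        idx = self.values.index
        for name, series in (
            ("subject_ids", self.subject_ids),
            ("timepoint", self.timepoint),
            ("neuropathy", self.neuropathy),
        ):
            if len(series) != len(idx):
                raise ConsistencyError(
                    f"{name} has {len(series)} entries for {len(idx)} samples"
                )
            setattr(self, name, pd.Series(np.asarray(series, dtype=object), index=idx))
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ConsistencyError(f"duplicated sample id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ConsistencyError(f"duplicated feature name {dup!r}")
        bad_tp = set(self.timepoint) - set(TIMEPOINTS)
        if bad_tp:
            raise ConsistencyError(f"invalid timepoint labels {sorted(bad_tp)}")
        bad_np = set(self.neuropathy) - set(NEUROPATHY_LEVELS)
        if bad_np:
            raise ConsistencyError(f"invalid neuropathy labels {sorted(bad_np)}")
        # one sample per subject per timepoint
        pairs = pd.MultiIndex.from_arrays([self.subject_ids, self.timepoint])
        if pairs.duplicated().any():
            subj, tp = pairs[pairs.duplicated()][0]
            raise ConsistencyError(f"subject {subj!r} has two {tp} samples")
        day1 = self.timepoint == "day1"
        if (self.neuropathy[day1] != "unknown").any():
            raise ConsistencyError(
                "neuropathy labels must be 'unknown' on day-1 samples"
            )
        if self.feature_class is not None:
            self.feature_class = pd.Series(self.feature_class)
            missing = self.values.columns.difference(self.feature_class.index)
            if len(missing):
                raise ConsistencyError(
                    f"features without class annotation: {list(missing)[:5]}"
                )
            self.feature_class = self.feature_class.reindex(self.values.columns)

    # ------------------------------------------------------------------ views
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence) -> "LipidomicsDataset":
        ids = pd.Index(sample_ids)
        return replace(
            self,
            values=self.values.loc[ids],
            subject_ids=self.subject_ids.loc[ids],
            timepoint=self.timepoint.loc[ids],
            neuropathy=self.neuropathy.loc[ids],
        )

    def subset_features(self, feature_names: Sequence) -> "LipidomicsDataset":
        cols = pd.Index(feature_names)
        fc = self.feature_class.loc[cols] if self.feature_class is not None else None
        return replace(self, values=self.values[cols], feature_class=fc)

    def copy(self) -> "LipidomicsDataset":
        return replace(self, values=self.values.copy())


@dataclass
class ClassLabeling:
    """Binary classification task on a subset of samples.

    ``task`` is either ``"timepoint"`` (all samples, day1 vs day2) or
    ``"neuropathy"`` (day-2 samples only, yes vs no).  ``labels`` maps each
    included sample id to its class string; ``y`` is the 0/1 encoding with
    ``positive_class`` mapped to 1.
    """

    task: str
    labels: pd.Series
    positive_class: str

    def __post_init__(self) -> None:
        classes = set(self.labels)
        if len(classes) != 2:
            raise DegenerateTaskError(
                f"task {self.task!r} has classes {sorted(classes)}; need exactly 2"
            )
        if self.positive_class not in classes:
            raise DegenerateTaskError(
                f"positive class {self.positive_class!r} absent from labels"
            )

    @property
    def included_samples(self) -> pd.Index:
        return self.labels.index

    @property
    def y(self) -> np.ndarray:
        return (self.labels == self.positive_class).to_numpy(dtype=int)

    def restrict(self, sample_ids: Iterable) -> "ClassLabeling":
        ids = self.labels.index.intersection(pd.Index(sample_ids))
        return ClassLabeling(self.task, self.labels.loc[ids], self.positive_class)


def make_labeling(ds: LipidomicsDataset, task: str) -> ClassLabeling:
    """Build the binary labeling for one of the two study tasks.

    ``timepoint`` labels every sample day1/day2; ``neuropathy`` includes only
    day-2 samples, labeled yes/no.  Raises
    :class:`~lipidpanel.errors.DegenerateTaskError` when fewer than two classes
    are present.
    """
    if task == "timepoint":
        return ClassLabeling("timepoint", ds.timepoint.copy(), positive_class="day2")
    if task == "neuropathy":
        day2 = ds.timepoint == "day2"
        labels = ds.neuropathy[day2]
        return ClassLabeling("neuropathy", labels, positive_class="yes")
    raise DegenerateTaskError(f"unknown task {task!r}")


# ---------------------------------------------------------------------- I/O
def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _parse_numeric(raw: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Parse string cells to float, accepting only ''/'NA' as missing."""
    out = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        cells = raw[col].to_numpy()
        for i, cell in enumerate(cells):
            token = cell.strip()
            if token.lower() in _MISSING_TOKENS:
                out[i, j] = np.nan
                continue
            try:
                out[i, j] = float(token)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row {raw.index[i]!r}, "
                    f"column {col!r}"
                ) from None
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def read_dataset(
    values_path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path | None = None,
) -> LipidomicsDataset:
    """Read a dataset from delimited tables.

    The values table's first column is the sample id; the metadata table needs
    columns ``sample_id, subject_id, timepoint, neuropathy``; the optional
    annotation table needs ``feature_name, feature_class``.  Delimiter is
    chosen from the file extension (``.tsv`` -> tab, otherwise comma).
    """
    values_path, metadata_path = Path(values_path), Path(metadata_path)
    raw = _read_table(values_path)
    if raw.shape[1] < 2:
        raise FormatError(f"{values_path}: expected sample_id column plus features")
    raw = raw.set_index(raw.columns[0])
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{values_path}: duplicated sample id {dup!r}")
    values = _parse_numeric(raw, values_path)

    meta = _read_table(metadata_path)
    required = {"sample_id", "subject_id", "timepoint", "neuropathy"}
    if not required.issubset(meta.columns):
        raise FormatError(
            f"{metadata_path}: missing columns {sorted(required - set(meta.columns))}"
        )
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()][0]
        raise FormatError(f"{metadata_path}: duplicated sample id {dup!r}")
    if set(values.index) != set(meta.index):
        odd = set(values.index).symmetric_difference(meta.index)
        raise JoinError(
            f"sample ids disagree between values and metadata: {sorted(odd)[:5]}"
        )
    meta = meta.loc[values.index]
    neuropathy = meta["neuropathy"].str.strip().str.lower()
    neuropathy = neuropathy.replace({"": "unknown", "na": "unknown"})

    feature_class = None
    if annotation_path is not None:
        ann = _read_table(Path(annotation_path))
        if not {"feature_name", "feature_class"}.issubset(ann.columns):
            raise FormatError(
                f"{annotation_path}: need columns feature_name, feature_class"
            )
        feature_class = ann.set_index("feature_name")["feature_class"]

    return LipidomicsDataset(
        values=values,
        subject_ids=meta["subject_id"],
        timepoint=meta["timepoint"].str.strip(),
        neuropathy=neuropathy,
        feature_class=feature_class,
    )


def write_dataset(ds: LipidomicsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write values/metadata(/annotations) CSVs; floats round-trip exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    values = ds.values.copy()
    values.index.name = "sample_id"
    paths["values"] = out_dir / "values.csv"
    # repr() of a Python float round-trips bit-identically
    values.map(lambda v: "" if pd.isna(v) else repr(float(v))).to_csv(paths["values"])
    meta = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "subject_id": ds.subject_ids.to_numpy(),
            "timepoint": ds.timepoint.to_numpy(),
            "neuropathy": ds.neuropathy.to_numpy(),
        }
    )
    paths["metadata"] = out_dir / "metadata.csv"
    meta.to_csv(paths["metadata"], index=False)
    if ds.feature_class is not None:
        ann = pd.DataFrame(
            {"feature_name": ds.feature_names, "feature_class": ds.feature_class.to_numpy()}
        )
        paths["annotations"] = out_dir / "annotations.csv"
        ann.to_csv(paths["annotations"], index=False)
    return paths
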