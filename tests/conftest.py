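import numpy as np
import pandas as pd
import pytest

from lipidpanel import LipidomicsDataset, SyntheticSpec, generate


def make_dataset(X, subjects=None, timepoint=None, neuropathy=None,
                 feature_class=None, **flags):
    """Build a LipidomicsDataset from a raw matrix with minimal metadata."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    ids = [f"s{i}" for i in range(n)]
    values = pd.DataFrame(X, index=ids, columns=[f"f{j}" for j in range(d)])
    return LipidomicsDataset(
        values=values,
        subject_ids=subjects if subjects is not None else ids,
        timepoint=timepoint if timepoint is not None else ["day1"] * n,
        neuropathy=neuropathy if neuropathy is not None else ["unknown"] * n,
        feature_class=feature_class,
        **flags,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic cohort: 79 x 255, 48 day-1 / 31 day-2."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def small_spec():
    """A small cohort spec for fast end-to-end style tests."""
    return SyntheticSpec(
        n_subjects=24,
        n_day1_only=6,
        n_features=40,
        n_informative_time=5,
        n_informative_neuropathy=2,
        effect_size_time=2.0,
        n_blocks=5,
        missing_rate=0.0,
        neuropathy_prevalence=0.5,
        seed=11,
    )
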