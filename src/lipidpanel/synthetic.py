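"""Synthetic lipidomics generator with known ground truth.

The study design this emulates: plasma drawn from breast-cancer patients
before (day 1) and after (day 2) paclitaxel chemotherapy, quantified over a
few hundred lipid mediators.  Some patients contribute only a pre-therapy
sample; roughly half of the post-therapy patients develop peripheral
neuropathy.  The default :class:`SyntheticSpec` reproduces that shape exactly:
48 day-1 + 31 day-2 samples over 255 features (a 79 x 255 matrix), with 17 of
the 31 day-2 subjects neuropathy-positive.

Concentrations are log-normal: on the log scale each cell is the sum of a
per-feature base abundance, a subject random effect (shared between the two
samples of a paired subject, which is what makes subject-grouped splitting
necessary downstream), a block factor shared by features of the same
correlated block (mimicking co-regulated lipid classes), residual noise, and
the class shifts that constitute the ground truth.  Missingness is injected
MCAR after exponentiation.

Class shifts are expressed in units of the within-class log-scale standard
deviation sqrt(subject_sd^2 + noise_sd^2), so ``effect_size_time = 1.5`` means
a 1.5-SD separation per informative feature.  Shift signs alternate per
feature (lipids go up or down after therapy).  A fraction
``enriched_class_fraction`` of the informative features is drawn from the
first annotated lipid class ("sphingolipid"), so class over-representation
among top hits is a recoverable property.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .data import LipidomicsDataset
from .errors import ParameterError

#: lipid-class labels used for the annotation table; the first one is the
#: enrichment target and covers ~18% of features (the sphingolipid share of
#: the emulated panel).
LIPID_CLASSES = (
    "sphingolipid",
    "eicosanoid",
    "lysophospholipid",
    "endocannabinoid",
    "fatty_acid",
    "phospholipid",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator; defaults emulate the study conditions."""

    n_subjects: int = 48
    n_day1_only: int = 17
    n_features: int = 255
    n_informative_time: int = 10
    n_informative_neuropathy: int = 3
    effect_size_time: float = 1.5
    effect_size_neuropathy: float = 1.0
    subject_sd: float = 0.5
    noise_sd: float = 0.5
    base_log_mean_range: tuple[float, float] = (0.0, 4.0)
    n_blocks: int = 10
    block_rho: float = 0.4
    missing_rate: float = 0.05
    neuropathy_prevalence: float = 17 / 31
    enriched_class_fraction: float = 0.6
    class_share: float = 46 / 255  # fraction of features in the enriched class
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_day1_only >= self.n_subjects:
            raise ParameterError("need at least one paired subject")
        if max(self.n_informative_time, self.n_informative_neuropathy) > self.n_features:
            raise ParameterError("more informative features than features")
        if not 0 <= self.missing_rate < 1:
            raise ParameterError("missing_rate must be in [0, 1)")
        if not 0 <= self.block_rho < 1:
            raise ParameterError("block_rho must be in [0, 1)")
        if self.effect_size_time < 0 or self.effect_size_neuropathy < 0:
            raise ParameterError("effect sizes must be nonnegative")
        if not 0 < self.neuropathy_prevalence < 1:
            raise ParameterError("neuropathy_prevalence must be in (0, 1)")

    @property
    def n_paired(self) -> int:
        return self.n_subjects - self.n_day1_only

    @property
    def within_class_sd(self) -> float:
        return float(np.hypot(self.subject_sd, self.noise_sd))


@dataclass
class GroundTruth:
    """Names of the truly informative features per task, plus shift signs."""

    time_features: list[str]
    neuropathy_features: list[str]
    time_signs: dict[str, int] = field(default_factory=dict)
    neuropathy_signs: dict[str, int] = field(default_factory=dict)


def _feature_annotations(spec: SyntheticSpec) -> pd.Series:
    names = [f"lipid_{j:03d}" for j in range(spec.n_features)]
    n_class1 = int(round(spec.class_share * spec.n_features))
    classes = []
    others = LIPID_CLASSES[1:]
    for j in range(spec.n_features):
        if j < n_class1:
            classes.append(LIPID_CLASSES[0])
        else:
            classes.append(others[(j - n_class1) % len(others)])
    return pd.Series(classes, index=pd.Index(names, name="feature_name"))


def _pick_informative(
    spec: SyntheticSpec, annotations: pd.Series, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Informative sets for the two tasks: disjoint, class-enriched for time."""
    in_class = list(annotations.index[annotations == LIPID_CLASSES[0]])
    out_class = list(annotations.index[annotations != LIPID_CLASSES[0]])
    k_in = min(int(round(spec.enriched_class_fraction * spec.n_informative_time)),
               len(in_class))
    k_out = spec.n_informative_time - k_in
    time_feats = [str(f) for f in rng.choice(in_class, size=k_in, replace=False)]
    time_feats += [str(f) for f in rng.choice(out_class, size=k_out, replace=False)]
    remaining = [f for f in annotations.index if f not in set(time_feats)]
    neuro_feats = [
        str(f)
        for f in rng.choice(remaining, size=spec.n_informative_neuropathy,
                            replace=False)
    ]
    return time_feats, neuro_feats


def _build_dataset(
    spec: SyntheticSpec,
    truth: GroundTruth,
    annotations: pd.Series,
    rng: np.random.Generator,
    attenuation: float = 1.0,
    cohort_tag: str = "",
) -> LipidomicsDataset:
    names = list(annotations.index)
    d = len(names)
    col_ix = {name: j for j, name in enumerate(names)}

    subjects = [f"subj{cohort_tag}_{s:03d}" for s in range(spec.n_subjects)]
    paired = subjects[: spec.n_paired]
    day1_only = subjects[spec.n_paired:]
    sample_subject, sample_tp, sample_ids = [], [], []
    for s in paired + day1_only:
        sample_subject.append(s)
        sample_tp.append("day1")
        sample_ids.append(f"{s}_d1")
    for s in paired:
        sample_subject.append(s)
        sample_tp.append("day2")
        sample_ids.append(f"{s}_d2")
    n = len(sample_ids)

    n_pos = int(round(spec.neuropathy_prevalence * spec.n_paired))
    pos_subjects = set(rng.choice(paired, size=n_pos, replace=False))
    neuropathy = [
        ("yes" if subj in pos_subjects else "no") if tp == "day2" else "unknown"
        for subj, tp in zip(sample_subject, sample_tp)
    ]

    base = rng.uniform(*spec.base_log_mean_range, size=d)
    subj_eff = rng.normal(0.0, spec.subject_sd, size=(spec.n_subjects, d))
    subj_ix = {s: i for i, s in enumerate(subjects)}
    block_of = np.array([j % spec.n_blocks for j in range(d)])
    block_factor = rng.normal(size=(n, spec.n_blocks))
    eps = rng.normal(size=(n, d))
    resid = spec.noise_sd * (
        np.sqrt(spec.block_rho) * block_factor[:, block_of]
        + np.sqrt(1.0 - spec.block_rho) * eps
    )

    log_vals = base[None, :] + resid
    for i, subj in enumerate(sample_subject):
        log_vals[i] += subj_eff[subj_ix[subj]]

    sd = spec.within_class_sd
    day2_rows = np.array([tp == "day2" for tp in sample_tp])
    for feat in truth.time_features:
        j = col_ix[feat]
        shift = truth.time_signs[feat] * spec.effect_size_time * attenuation * sd
        log_vals[day2_rows, j] += shift
    neuro_rows = np.array([lab == "yes" for lab in neuropathy])
    for feat in truth.neuropathy_features:
        j = col_ix[feat]
        shift = (
            truth.neuropathy_signs[feat]
            * spec.effect_size_neuropathy
            * attenuation
            * sd
        )
        log_vals[neuro_rows, j] += shift

    conc = np.exp(log_vals)
    if spec.missing_rate > 0:
        mask = rng.random(size=conc.shape) < spec.missing_rate
        conc = np.where(mask, np.nan, conc)

    values = pd.DataFrame(conc, index=pd.Index(sample_ids, name="sample_id"),
                          columns=names)
    return LipidomicsDataset(
        values=values,
        subject_ids=pd.Series(sample_subject, index=values.index),
        timepoint=pd.Series(sample_tp, index=values.index),
        neuropathy=pd.Series(neuropathy, index=values.index),
        feature_class=annotations.copy(),
    )


def generate(spec: SyntheticSpec) -> tuple[LipidomicsDataset, GroundTruth]:
    """Generate a primary cohort; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    annotations = _feature_annotations(spec)
    time_feats, neuro_feats = _pick_informative(spec, annotations, rng)
    truth = GroundTruth(
        time_features=time_feats,
        neuropathy_features=neuro_feats,
        time_signs={f: int(s) for f, s in
                    zip(time_feats, rng.choice([-1, 1], size=len(time_feats)))},
        neuropathy_signs={f: int(s) for f, s in
                          zip(neuro_feats, rng.choice([-1, 1], size=len(neuro_feats)))},
    )
    ds = _build_dataset(spec, truth, annotations, rng)
    return ds, truth


def decoy_features(ds: LipidomicsDataset, truth: GroundTruth) -> list[str]:
    """Features informative for neither task; selector hits here are errors."""
    informative = set(truth.time_features) | set(truth.neuropathy_features)
    return [f for f in ds.feature_names if f not in informative]


def generate_second_cohort(
    spec: SyntheticSpec,
    truth: GroundTruth,
    n_paired_subjects: int = 26,
    n_features_dropped: int = 16,
    attenuation: float = 0.5,
    neuropathy_prevalence: float = 0.25,
    seed_offset: int = 1,
) -> LipidomicsDataset:
    """Generate an external cohort sharing the primary cohort's ground truth.

    All subjects are paired (two samples each), the panel loses
    ``n_features_dropped`` uninformative features (emulating a smaller
    quantified panel at the second site: default 52 samples x 239 mediators),
    and effect sizes are multiplied by ``attenuation`` in (0, 1] to emulate the
    weaker signal of an externally collected cohort.
    """
    if not 0 < attenuation <= 1:
        raise ParameterError("attenuation must be in (0, 1]")
    annotations = _feature_annotations(spec)
    informative = set(truth.time_features) | set(truth.neuropathy_features)
    droppable = [f for f in annotations.index if f not in informative]
    if n_features_dropped > len(droppable):
        raise ParameterError("cannot drop that many features and keep the truth")
    rng = np.random.default_rng(spec.seed + seed_offset)
    dropped = set(rng.choice(droppable, size=n_features_dropped, replace=False))
    annotations2 = annotations[~annotations.index.isin(dropped)]
    spec2 = replace(
        spec,
        n_subjects=n_paired_subjects,
        n_day1_only=0,
        n_features=len(annotations2),
        neuropathy_prevalence=neuropathy_prevalence,
    )
    return _build_dataset(spec2, truth, annotations2, rng,
                          attenuation=attenuation, cohort_tag="B")
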