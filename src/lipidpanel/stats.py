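"""Classical statistics used across the pipeline.

Kruskal-Wallis rank tests compare marker concentrations across groups,
Benjamini-Hochberg (default) or Bonferroni-Holm correction handles
multiplicity, and Fisher's exact test with a conditional-maximum-likelihood
odds ratio and exact confidence interval quantifies 2x2 associations —
cluster vs class membership, and lipid-class enrichment of a selected panel
against its annotated background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTableError, DomainError, ParameterError


@dataclass
class TestResult:
    statistic: float  # H for Kruskal-Wallis; odds ratio for Fisher
    p: float
    method: str
    p_adjusted: Optional[float] = None
    ci: Optional[tuple[float, float]] = None


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square (g-1 df) p-value."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ParameterError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ParameterError("every group must be nonempty")
    if sum(a.size for a in arrays) < 3:
        raise ParameterError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # all observations tied: no evidence against equality
        return TestResult(statistic=0.0, p=1.0, method="kruskal-wallis")
    h, p = sps.kruskal(*arrays)
    return TestResult(statistic=float(h), p=float(p), method="kruskal-wallis")


def adjust_p(pvals: Iterable[float], method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment: Benjamini-Hochberg step-up FDR (default) or
    Bonferroni-Holm step-down FWER (``method="holm"``)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DomainError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "holm": "holm"}.get(method)
    if key is None:
        raise ParameterError(f"unknown correction method {method!r}")
    return multipletests(p, method=key)[1]


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    p sums hypergeometric probabilities <= the observed table's; the odds
    ratio is the conditional maximum-likelihood estimate with its 95% CI from
    inverting the exact conditional test.  A zero cell yields OR 0 or inf with
    the corresponding one-sided CI bound.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t_float = np.asarray(table, dtype=float)
        if (t_float < 0).any() or not np.allclose(t_float, np.round(t_float)):
            raise DomainError("table entries must be nonnegative integers")
        t = np.round(t_float).astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("a table margin is zero")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    res = _odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    return TestResult(
        statistic=float(res.statistic),
        p=float(p),
        method="fisher-exact",
        ci=(float(ci.low), float(ci.high)),
    )


def class_enrichment(
    selected: Iterable[str],
    background_classes: pd.Series,
    class_label: str,
) -> TestResult:
    """Fisher test of class over-representation in a selected feature set.

    The 2x2 table crosses membership in ``selected`` with membership in
    ``class_label`` over the annotated feature universe
    (``background_classes``: feature name -> class).
    """
    selected = set(selected)
    universe = set(background_classes.index)
    missing = selected - universe
    if missing:
        raise ParameterError(
            f"selected features without annotation: {sorted(missing)[:5]}"
        )
    in_class = set(background_classes.index[background_classes == class_label])
    a = len(selected & in_class)
    b = len(selected - in_class)
    c = len(in_class - selected)
    d = len(universe - in_class - selected)
    return fisher_exact([[a, b], [c, d]])
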