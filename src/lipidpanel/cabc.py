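"""Computed ABC analysis.

ABC analysis partitions a nonnegative "importance" vector into category A (the
important few), B, and C (the trivial many) from the geometry of its ABC
curve: items are sorted descending, and the curve plots cumulative effort
fraction x_i = i/n against cumulative yield fraction y_i = (sum of the i
largest values) / total.

The computed (data-driven) set limits used here:

* **A|B** — the curve point closest (Euclidean) to the ideal point (0, 1),
  i.e. maximal yield for minimal effort;
* **B|C** — the break-even point: the last point before the slope of the
  piecewise-linear curve drops below 1.  On the uniform x-grid the slope of
  segment i is value_i / mean(values), so B ends with the last item at or
  above the mean.  If break-even precedes A|B, B is empty.

An all-equal input carries no concentration-of-importance signal: every item
is returned as category C with the ``degenerate`` flag set.

``nested_cabc`` re-applies the analysis to the previous category A, distilling
a sparser "important few" set — the mechanism behind the reduced -> sparse
panel shrinkage in the feature-selection stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, ParameterError


@dataclass
class ABCResult:
    """Outcome of one (possibly nested) computed ABC analysis.

    ``item_order`` holds original indices sorted by value descending (stable:
    equal values keep original order).  ``ab_index``/``bc_index`` are counts
    along that order: the first ``ab_index`` items are A, the next
    ``bc_index - ab_index`` are B, the rest C.  ``categories`` maps each
    original index to its category letter.
    """

    item_order: np.ndarray
    curve: np.ndarray  # (n, 2): columns x, y
    ab_index: int
    bc_index: int
    categories: np.ndarray  # per original index: 'A' | 'B' | 'C'
    degenerate: bool = False

    def members(self, category: str) -> np.ndarray:
        return np.flatnonzero(self.categories == category)

    @property
    def a_items(self) -> np.ndarray:
        return self.members("A")


def _check_values(values: Sequence[float]) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ParameterError("values must be a nonempty 1-d vector")
    if np.isnan(v).any():
        raise DomainError("values must not contain NaN")
    if (v < 0).any():
        raise DomainError("values must be nonnegative")
    if not (v > 0).any():
        raise DomainError("degenerate input: all values are zero")
    return v


def abc_curve(values: Sequence[float]) -> np.ndarray:
    """ABC curve of a nonnegative vector: points (i/n, cum-yield fraction)."""
    v = _check_values(values)
    order = np.argsort(-v, kind="stable")
    n = v.size
    x = np.arange(1, n + 1) / n
    y = np.cumsum(v[order]) / v.sum()
    return np.column_stack([x, y])


def cabc_categorize(values: Sequence[float]) -> ABCResult:
    """Partition items into computed ABC categories A, B, C."""
    v = _check_values(values)
    n = v.size
    order = np.argsort(-v, kind="stable")
    curve = abc_curve(v)
    x, y = curve[:, 0], curve[:, 1]

    if n > 1 and np.all(v == v[0]):
        return ABCResult(
            item_order=order,
            curve=curve,
            ab_index=0,
            bc_index=0,
            categories=np.full(n, "C"),
            degenerate=True,
        )

    dist2 = x**2 + (1.0 - y) ** 2
    # exact rational ties are possible (e.g. equal distances at neighboring
    # points); take the earliest point within rounding error of the minimum
    ab = int(np.flatnonzero(dist2 <= dist2.min() + 1e-12)[0]) + 1  # |A|

    # slope of segment i (1-based) on the uniform grid = value_i / mean
    sorted_v = v[order]
    slopes = sorted_v / v.mean()
    above = np.flatnonzero(slopes >= 1.0 - 1e-12)
    bc = int(above[-1]) + 1 if above.size else 0
    if bc < ab:
        bc = ab

    categories = np.empty(n, dtype=object)
    categories[order[:ab]] = "A"
    categories[order[ab:bc]] = "B"
    categories[order[bc:]] = "C"

    for boundary in (ab, bc):
        if 0 < boundary < n and sorted_v[boundary - 1] == sorted_v[boundary]:
            warnings.warn(
                "tied values straddle an ABC boundary; stable original order "
                "decides membership",
                stacklevel=2,
            )
            break

    return ABCResult(
        item_order=order,
        curve=curve,
        ab_index=ab,
        bc_index=bc,
        categories=categories.astype(str),
    )


def nested_cabc(values: Sequence[float], depth: int = 2) -> ABCResult:
    """Repeated cABC: re-analyze category A of the previous pass.

    Stops early when A stops shrinking.  Items removed at any stage keep the
    category they received at that stage; the surviving items form the final A.
    The returned ``curve``/``item_order`` are those of the first pass;
    ``ab_index`` counts the final A along that order.
    """
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    v = _check_values(values)
    first = cabc_categorize(v)
    if first.degenerate or depth == 1:
        return first

    categories = first.categories.copy()
    active = first.a_items
    for _ in range(depth - 1):
        if active.size <= 1:
            break
        sub = cabc_categorize(v[active])
        if sub.degenerate or sub.a_items.size == active.size:
            break
        for letter in ("B", "C"):
            categories[active[sub.members(letter)]] = letter
        active = active[sub.a_items]

    order = first.item_order
    in_a = np.isin(order, active)
    ab = int(in_a.sum())
    bc_letters = categories[order]
    bc = int((bc_letters != "C").sum())
    return ABCResult(
        item_order=order,
        curve=first.curve,
        ab_index=ab,
        bc_index=max(bc, ab),
        categories=categories,
    )
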