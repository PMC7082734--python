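"""Psychometric statistics implemented from first principles.

Cronbach's alpha (internal-consistency reliability of a multi-item scale),
Spearman's rank correlation with mid-rank tie handling, and standard System
Usability Scale (SUS) scoring.  These are deliberately self-contained: the
heavy-duty statistics libraries serve only as independent cross-checks in the
test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ItemMatrix",
    "cronbach_alpha",
    "midranks",
    "spearman_rho",
    "spearman_pvalue",
    "sus_score",
]


@dataclass(frozen=True)
class ItemMatrix:
    """A complete respondents-by-items score grid.

    Parameters
    ----------
    values : array-like of shape (n_respondents, n_items)
        Numeric item scores; no missing cells allowed.
    item_ids : list of str, optional
        Column labels; generated as ``item_0..item_{k-1}`` when omitted.
    """

    values: np.ndarray
    item_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("ItemMatrix requires a 2-D grid")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(
                f"ItemMatrix requires >=2 respondents and >=2 items, got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("ItemMatrix does not allow missing or non-finite cells")
        ids = self.item_ids or tuple(f"item_{j}" for j in range(arr.shape[1]))
        if len(ids) != arr.shape[1]:
            raise ValueError("item_ids length must equal the number of columns")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "item_ids", tuple(ids))

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


def cronbach_alpha(m: ItemMatrix | np.ndarray) -> float:
    """Cronbach's alpha of an item matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total scores),
    with sample variances (denominator n-1).  Returns NaN with a warning when
    the total score has zero variance (alpha is undefined there).
    """
    if not isinstance(m, ItemMatrix):
        m = ItemMatrix(np.asarray(m, dtype=float))
    x = m.values
    k = m.n_items
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0.0:
        warnings.warn(
            "total-score variance is zero; Cronbach alpha is undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def midranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with tied values assigned the mean of their rank block."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        # ranks i+1 .. j+1 share the block mean
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Returns NaN with a warning when either vector is constant (the
    correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman_rho requires two equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("spearman_rho requires at least 3 observations")
    rx, ry = midranks(x), midranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        warnings.warn(
            "constant input vector; Spearman correlation is undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    r = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    # numerical guard: keep inside [-1, 1]
    return max(-1.0, min(1.0, r))


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value for a Spearman correlation via the t approximation.

    Annotation-only: used to decorate synthetic correlation-table reports,
    not for any selection decision in the engine.
    """
    if math.isnan(rho) or n < 4:
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    from scipy import stats

    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def sus_score(answers) -> float:
    """Standard SUS score of a 10-item response on 1..5 codes.

    Odd-numbered (positively worded) items contribute ``code - 1``;
    even-numbered items contribute ``5 - code``.  The sum is scaled by 2.5
    onto 0-100, where scores above 70 are conventionally considered passable.
    """
    a = list(answers)
    if len(a) != 10:
        raise ValueError(f"SUS requires exactly 10 answers, got {len(a)}")
    for i, code in enumerate(a, start=1):
        if not (isinstance(code, (int, np.integer)) and 1 <= int(code) <= 5):
            raise ValueError(f"SUS item {i}: answer code {code!r} not in 1..5")
    contributions = [
        (code - 1) if i % 2 == 1 else (5 - code) for i, code in enumerate(a, start=1)
    ]
    return float(sum(contributions) * 2.5)
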