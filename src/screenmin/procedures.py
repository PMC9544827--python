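"""Functional interface to the decision procedures.

Thin wrappers over the estimators in :mod:`screenmin.estimators`; every
function accepts a :class:`~screenmin.PValueTable`, a DataFrame with
``p1``/``p2`` columns, or an (m, 2) array.
"""

from __future__ import annotations

import numpy as np

from ._table import PValueTable, SelectionResult, TestDecision, as_pvalue_table
from .estimators import (
    AdaptiveScreenMin,
    MaxPBonferroni,
    PferScreenMin,
    ScreenMin,
    single_threshold,
)

__all__ = [
    "screen",
    "screenmin_adjust",
    "adaptive_threshold",
    "adaptive_procedure",
    "pfer_estimate",
    "pfer_procedure",
    "bonferroni_maxp",
]


def screen(table, c: float) -> SelectionResult:
    """Select the pairs whose minimum p-value is ≤ c."""
    table = as_pvalue_table(table)
    if not 0.0 < c <= 1.0:
        raise ValueError(f"screening threshold c must lie in (0, 1], got {c}")
    return SelectionResult(
        threshold=float(c), selected=table.pmin <= c, ids=table.ids
    )


def screenmin_adjust(table, c: float, alpha: float = 0.05) -> TestDecision:
    """Fixed-threshold two-stage test: screen at c, test max-p at α/|S|."""
    return ScreenMin(alpha=alpha, c=c).fit(table).decision_


def adaptive_threshold(table, alpha: float = 0.05) -> float:
    """γ = max{c ∈ {α/m, …, α/2, α} : c·|S(c)| ≤ α}."""
    table = as_pvalue_table(table)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return single_threshold(table.pmin, alpha)


def adaptive_procedure(table, alpha: float = 0.05) -> TestDecision:
    """Single-threshold procedure: select and reject at the adaptive γ."""
    return AdaptiveScreenMin(alpha=alpha).fit(table).decision_


def pfer_estimate(selection: SelectionResult) -> float:
    """Estimate of the expected number of false rejections: |S(c)|·c.

    Valid (unbiased or upward biased) when the screening threshold was
    chosen independently of the data.
    """
    return selection.n_selected * selection.threshold


def pfer_procedure(table, k: float = 1.0) -> TestDecision:
    """Single-threshold procedure bounding the per-family error rate by k."""
    return PferScreenMin(k=k).fit(table).decision_


def bonferroni_maxp(table, alpha: float = 0.05) -> TestDecision:
    """One-stage Bonferroni on the maximum p-values (reject iff pmax ≤ α/m)."""
    return MaxPBonferroni(alpha=alpha).fit(table).decision_
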