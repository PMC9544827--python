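"""Decision procedures as scikit-learn style estimators.

Each estimator consumes an m×2 table of component p-values — a
:class:`~screenmin.PValueTable`, a DataFrame with ``p1``/``p2`` columns, or
an (m, 2) array — via ``fit``, and exposes the decisions through fitted
attributes (``selected_``, ``rejected_``, ``adjusted_pvalues_``,
``screen_threshold_``, ``test_threshold_`` ...).  ``get_params`` /
``set_params`` come from :class:`sklearn.base.BaseEstimator`, so the
procedures compose with scikit-learn model-selection utilities.

Procedures
----------
:class:`ScreenMin`
    Fixed-threshold two-stage test: screen pairs whose minimum p-value is
    ≤ c (default c = α/m), Bonferroni-test the maximum p-value of the
    survivors at α/|S|.
:class:`AdaptiveScreenMin`
    Single data-dependent threshold γ = max{c ∈ {α/m, …, α} : c·|S(c)| ≤ α},
    used for both screening and testing.
:class:`PferScreenMin`
    Same single-threshold construction with budget k on the expected number
    of false rejections (per-family error rate) instead of a level α.
:class:`MaxPBonferroni`
    One-stage baseline: Bonferroni on the m maximum p-values.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._table import PValueTable, SelectionResult, TestDecision, as_pvalue_table

__all__ = [
    "ScreenMin",
    "AdaptiveScreenMin",
    "PferScreenMin",
    "MaxPBonferroni",
]


def _check_level(alpha: float, name: str = "alpha") -> float:
    alpha = float(alpha)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"{name} must lie in (0, 1), got {alpha}")
    return alpha


def single_threshold(pmin: np.ndarray, budget: float) -> float:
    """Largest c in {budget/j : j = m..1} (capped at 1) with c·|S(c)| ≤ budget.

    The grid point c = budget/j is feasible iff |S(budget/j)| ≤ j, which for
    j < m is equivalent to the (j+1)-th order statistic of pmin exceeding
    budget/j; j = m is always feasible, so the maximum is well defined.
    """
    if budget <= 0:
        raise ValueError(f"budget must be positive, got {budget}")
    m = pmin.size
    if budget >= m:
        # c = 1 is on the (capped) grid and 1·|S(1)| = m ≤ budget
        return 1.0
    srt = np.sort(pmin)
    js = np.arange(1, m)
    feasible = srt[1:] > budget / js  # order statistic rank j+1 vs grid point
    hit = np.flatnonzero(feasible)
    j_star = int(js[hit[0]]) if hit.size else m
    return min(budget / j_star, 1.0)


class _BaseUnionTest(BaseEstimator):
    """Shared fit plumbing: coerce input, compute decisions, store attributes."""

    def fit(self, X, y=None):
        """Run the procedure on an m×2 p-value table.

        Parameters
        ----------
        X : PValueTable, DataFrame with ``p1``/``p2`` columns, or (m, 2) array
        y : ignored

        Returns
        -------
        self
        """
        table = as_pvalue_table(X)
        self._decide(table)
        self.table_ = table
        self.m_ = table.m
        self.n_selected_ = int(self.selected_.sum())
        self.n_rejected_ = int(self.rejected_.sum())
        self.decision_ = TestDecision(
            procedure=self._procedure_name,
            level=self._level,
            screen_threshold=self.screen_threshold_,
            test_threshold=self.test_threshold_,
            selected=self.selected_,
            adjusted_p=self.adjusted_pvalues_,
            rejected=self.rejected_,
            ids=table.ids,
        )
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the per-row rejection indicator (0/1)."""
        return self.fit(X).rejected_.astype(int)

    @property
    def selection_(self) -> SelectionResult:
        check_is_fitted(self, "selected_")
        return SelectionResult(
            threshold=self.screen_threshold_,
            selected=self.selected_,
            ids=self.table_.ids,
        )


class ScreenMin(_BaseUnionTest):
    """Two-stage union-hypothesis test with a fixed screening threshold.

    Screen pairs with min p-value ≤ c, then reject a surviving pair when its
    max p-value is ≤ α/|S|.  Adjusted p-values are ``min(|S|·pmax, 1)`` for
    selected rows and 1 otherwise.

    Parameters
    ----------
    alpha : float in (0, 1), default 0.05
        Nominal familywise error rate.
    c : float in (0, 1] or None, default None
        Screening threshold; ``None`` uses the conventional default α/m.

    Attributes
    ----------
    screen_threshold_ : float
        The threshold actually used (c, or α/m when ``c=None``).
    test_threshold_ : float
        α/|S| (α when nothing is selected).
    selected_, rejected_ : ndarray of bool
    adjusted_pvalues_ : ndarray
    n_selected_, n_rejected_ : int

    Examples
    --------
    >>> import numpy as np
    >>> P = np.array([[0.001, 0.002], [0.01, 0.9], [0.3, 0.4]])
    >>> sm = ScreenMin(alpha=0.05, c=0.05).fit(P)
    >>> sm.n_selected_, sm.n_rejected_
    (2, 1)
    """

    _procedure_name = "screenmin-fixed"

    def __init__(self, alpha: float = 0.05, c: float | None = None):
        self.alpha = alpha
        self.c = c

    def _decide(self, table: PValueTable) -> None:
        alpha = _check_level(self.alpha)
        c = alpha / table.m if self.c is None else float(self.c)
        if not 0.0 < c <= 1.0:
            raise ValueError(f"screening threshold c must lie in (0, 1], got {c}")
        selected = table.pmin <= c
        s = int(selected.sum())
        adjusted = np.ones(table.m)
        adjusted[selected] = np.minimum(s * table.pmax[selected], 1.0)
        self.screen_threshold_ = c
        self.test_threshold_ = alpha / s if s > 0 else alpha
        self.selected_ = selected
        self.adjusted_pvalues_ = adjusted
        self.rejected_ = selected & (adjusted <= alpha)
        self._level = alpha


class AdaptiveScreenMin(_BaseUnionTest):
    """Single-threshold procedure with the data-dependent threshold γ.

    γ is the largest c on the grid {α/m, …, α/2, α} with c·|S(c)| ≤ α; rows
    are selected and rejected with the same threshold (reject when
    pmax ≤ γ).  The grid always contains a feasible point, since at c = α/m
    we have c·|S(c)| ≤ α.  Reported adjusted p-values
    ``min(|S(γ)|·pmax, 1)`` are a reporting convenience; the rejection
    decision is the threshold comparison.

    Attributes
    ----------
    screen_threshold_ = test_threshold_ : float
        The adaptive threshold γ.
    """

    _procedure_name = "screenmin-adaptive"

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def _decide(self, table: PValueTable) -> None:
        alpha = _check_level(self.alpha)
        gamma = single_threshold(table.pmin, alpha)
        selected = table.pmin <= gamma
        s = int(selected.sum())
        adjusted = np.ones(table.m)
        adjusted[selected] = np.minimum(s * table.pmax[selected], 1.0)
        self.screen_threshold_ = gamma
        self.test_threshold_ = gamma
        self.selected_ = selected
        self.adjusted_pvalues_ = adjusted
        self.rejected_ = table.pmax <= gamma
        self._level = alpha


class PferScreenMin(_BaseUnionTest):
    """Single-threshold procedure controlling the per-family error rate.

    Uses c_k = max{c ∈ {k/m, …, k} : c·|S(c)| ≤ k} (grid points capped at 1)
    for both screening and testing, which bounds the expected number of
    falsely rejected union hypotheses by k.  The fitted
    ``pfer_estimate_ = c_k·|S(c_k)|`` is an unbiased-or-upward-biased
    estimate of that expectation.

    Parameters
    ----------
    k : float > 0, default 1.0
        Budget on the expected number of false rejections.
    """

    _procedure_name = "screenmin-pfer"

    def __init__(self, k: float = 1.0):
        self.k = k

    def _decide(self, table: PValueTable) -> None:
        k = float(self.k)
        if k <= 0:
            raise ValueError(f"PFER budget k must be positive, got {k}")
        c_k = single_threshold(table.pmin, k)
        selected = table.pmin <= c_k
        s = int(selected.sum())
        adjusted = np.ones(table.m)
        adjusted[selected] = np.minimum(s * table.pmax[selected], 1.0)
        self.screen_threshold_ = c_k
        self.test_threshold_ = c_k
        self.selected_ = selected
        self.adjusted_pvalues_ = adjusted
        self.rejected_ = table.pmax <= c_k
        self.pfer_estimate_ = c_k * s
        self._level = k


class MaxPBonferroni(_BaseUnionTest):
    """One-stage Bonferroni baseline on the m maximum p-values.

    Rejects pair i when pmax_i ≤ α/m; adjusted p-values are
    ``min(m·pmax, 1)``.  Equivalent to :class:`ScreenMin` with c = 1.
    """

    _procedure_name = "bonferroni-maxp"

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def _decide(self, table: PValueTable) -> None:
        alpha = _check_level(self.alpha)
        adjusted = np.minimum(table.m * table.pmax, 1.0)
        self.screen_threshold_ = 1.0
        self.test_threshold_ = alpha / table.m
        self.selected_ = np.ones(table.m, dtype=bool)
        self.adjusted_pvalues_ = adjusted
        self.rejected_ = adjusted <= alpha
        self._level = alpha
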