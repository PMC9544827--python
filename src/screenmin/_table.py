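"""Containers for p-value tables and procedure outputs.

A *union hypothesis* ``H_i = H_i1 ∪ H_i2`` is true when at least one of its
two component null hypotheses is true; rejecting it asserts that both
components are false (e.g. a variable is associated with both the exposure
and the outcome in mediation screening, or a finding replicates in both of
two studies).  All procedures in this package operate on an m×2 table of
component p-values, through the row-wise minimum (used for screening) and
maximum (a valid p-value for the union, used for testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["PValueTable", "SelectionResult", "TestDecision"]


def _validate_pvalues(values: np.ndarray, name: str) -> None:
    if np.isnan(values).any():
        rows = np.flatnonzero(np.isnan(values))
        raise ValueError(f"missing {name} value(s) at row(s) {rows.tolist()}")
    bad = (values < 0.0) | (values > 1.0)
    if bad.any():
        rows = np.flatnonzero(bad)
        raise ValueError(
            f"{name} outside [0, 1] at row(s) {rows.tolist()}: "
            f"{values[bad][:5].tolist()}"
        )


class PValueTable:
    """An m×2 table of component p-values with derived row-wise min and max.

    Parameters
    ----------
    p1, p2 : array-like of shape (m,)
        Component p-values for the first and second null hypothesis of each
        pair.  Values must lie in [0, 1]; exact 0 and 1 are accepted.
    ids : sequence of str or int, optional
        Row identifiers.  Defaults to 1-based integers.

    Attributes
    ----------
    pmin, pmax : ndarray
        Row-wise minimum and maximum, recomputed from ``p1``/``p2`` so they
        can never be stored inconsistently.
    """

    def __init__(self, p1, p2, ids: Sequence | None = None):
        p1 = np.asarray(p1, dtype=float)
        p2 = np.asarray(p2, dtype=float)
        if p1.ndim != 1 or p2.ndim != 1 or p1.shape != p2.shape:
            raise ValueError("p1 and p2 must be one-dimensional and equal length")
        if p1.size == 0:
            raise ValueError("p-value table must contain at least one row")
        _validate_pvalues(p1, "p1")
        _validate_pvalues(p2, "p2")
        self.p1 = p1
        self.p2 = p2
        if ids is None:
            ids = np.arange(1, p1.size + 1)
        ids = np.asarray(ids)
        if ids.shape != p1.shape:
            raise ValueError("ids must match the number of rows")
        self.ids = ids

    @property
    def m(self) -> int:
        return self.p1.size

    @property
    def pmin(self) -> np.ndarray:
        return np.minimum(self.p1, self.p2)

    @property
    def pmax(self) -> np.ndarray:
        return np.maximum(self.p1, self.p2)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, p1_col: str = "p1", p2_col: str = "p2",
        id_col: str | None = None,
    ) -> "PValueTable":
        for col in (p1_col, p2_col):
            if col not in frame.columns:
                raise KeyError(f"required column {col!r} not found in input")
        ids = frame[id_col].to_numpy() if id_col else None
        return cls(frame[p1_col].to_numpy(), frame[p2_col].to_numpy(), ids=ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "p1": self.p1, "p2": self.p2,
             "pmin": self.pmin, "pmax": self.pmax}
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"PValueTable(m={self.m})"


def as_pvalue_table(X) -> PValueTable:
    """Coerce an input to a :class:`PValueTable`.

    Accepts a ``PValueTable``, a DataFrame with ``p1``/``p2`` columns, or an
    (m, 2) array.
    """
    if isinstance(X, PValueTable):
        return X
    if isinstance(X, pd.DataFrame):
        return PValueTable.from_frame(X)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an (m, 2) array of p-values, got shape {arr.shape}")
    return PValueTable(arr[:, 0], arr[:, 1])


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of screening at threshold ``c``: the selected set S = {i : pmin_i ≤ c}."""

    threshold: float
    selected: np.ndarray  # boolean indicator per row
    ids: np.ndarray = field(repr=False, default=None)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def index(self) -> np.ndarray:
        """Sorted positional indices of the selected rows."""
        return np.flatnonzero(self.selected)


@dataclass(frozen=True)
class TestDecision:
    """Per-row decisions of a two-stage procedure.

    ``adjusted_p`` is 1 for unselected rows; ``rejected`` implies ``selected``.
    ``screen_threshold`` and ``test_threshold`` coincide for the single-threshold
    (adaptive and PFER) procedures.
    """

    procedure: str
    level: float  # alpha for FWER procedures, k for PFER
    screen_threshold: float
    test_threshold: float
    selected: np.ndarray
    adjusted_p: np.ndarray
    rejected: np.ndarray
    ids: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if np.any(self.rejected & ~self.selected):
            raise ValueError("internal error: rejected a row that was not selected")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())

    def to_frame(self, table: PValueTable | None = None) -> pd.DataFrame:
        out = {}
        if table is not None:
            out.update(
                id=table.ids, p1=table.p1, p2=table.p2,
                pmin=table.pmin, pmax=table.pmax,
            )
        elif self.ids is not None:
            out["id"] = self.ids
        out["selected"] = self.selected.astype(int)
        out["p_adjusted"] = self.adjusted_p
        out["rejected"] = self.rejected.astype(int)
        return pd.DataFrame(out)
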