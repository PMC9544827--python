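"""Reading and writing p-value tables and decision reports.

Input is delimited text (TSV or CSV, auto-detected from the extension or
content when not given) with a header row; ``#``-prefixed lines are treated
as comments.  Output reports carry the full per-row schema plus a
``#``-prefixed run-metadata header, and round-trip through the reader.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._table import PValueTable, TestDecision

__all__ = ["read_pvalue_table", "write_results", "load_navy_metabolites"]

logger = logging.getLogger("screenmin")


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".txt", ".tab"):
        return "\t"
    # sniff the first non-comment line
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return "\t"


def read_pvalue_table(
    path,
    p1_col: str = "p1",
    p2_col: str = "p2",
    id_col: str | None = None,
    delimiter: str | None = None,
) -> PValueTable:
    """Read an m×2 p-value table from delimited text.

    Parameters
    ----------
    path : path-like
    p1_col, p2_col : str
        Names of the two component p-value columns.
    id_col : str, optional
        Column of row identifiers; defaults to 1-based integers.
    delimiter : str, optional
        Field delimiter; inferred from the extension/content when omitted.

    Raises
    ------
    ValueError
        With the offending row index for non-numeric cells, missing values
        or p-values outside [0, 1].
    """
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    try:
        frame = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"input file {path} is empty") from None
    if frame.empty:
        raise ValueError(f"input file {path} contains no data rows")
    for col in (p1_col, p2_col):
        if col not in frame.columns:
            raise ValueError(
                f"required column {col!r} not found in {path} "
                f"(columns: {list(frame.columns)})"
            )
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            rows = list(frame.index[bad][:5])
            raise ValueError(f"non-numeric {col} value(s) at row(s) {rows}")
        frame[col] = coerced
    ids = frame[id_col].to_numpy() if id_col else None
    table = PValueTable(frame[p1_col].to_numpy(), frame[p2_col].to_numpy(), ids=ids)
    logger.info("read %d rows from %s", table.m, path)
    return table


def write_results(
    decision: TestDecision,
    path,
    table: PValueTable | None = None,
    delimiter: str = "\t",
) -> None:
    """Write a per-row decision report with a ``#`` metadata header.

    Columns: id, p1, p2, pmin, pmax (when the source table is supplied),
    selected (0/1), p_adjusted, rejected (0/1).  The metadata lines record
    the procedure, thresholds, level and the selected/rejected counts, plus
    the sorted selected set for reproducibility.
    """
    path = Path(path)
    frame = decision.to_frame(table)
    selected_ids = (
        np.asarray(decision.ids)[decision.selected]
        if decision.ids is not None
        else np.flatnonzero(decision.selected) + 1
    )
    meta = [
        f"# procedure: {decision.procedure}",
        f"# level: {decision.level:.10g}",
        f"# screen_threshold: {decision.screen_threshold:.10g}",
        f"# test_threshold: {decision.test_threshold:.10g}",
        f"# n_selected: {decision.n_selected}",
        f"# n_rejected: {decision.n_rejected}",
        "# selected_set: " + ",".join(str(i) for i in selected_ids),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(meta) + "\n")
        frame.to_csv(fh, sep=delimiter, index=False)
    logger.info("wrote %d rows to %s", len(frame), path)


def load_navy_metabolites(with_names: bool = False):
    """The packaged 22-metabolite example table.

    p-Value pairs for the 22 circulating metabolites (of 149 candidates)
    that pass the adaptive screen in a case-control mediation analysis of
    fish intake and colorectal adenoma risk.  The component p-values are
    reconstructed from the row-wise minimum/maximum and the recorded side
    of the minimum: column 1 is the exposure-side (mediator model) test,
    column 2 the outcome-side test.

    Note the full screen had m = 149 candidate mediators; thresholds that
    depend on m (e.g. the default 0.05/149) must be supplied with respect
    to that m, not the 22 packaged rows.

    Returns
    -------
    PValueTable, or (PValueTable, DataFrame) when ``with_names`` is True.
    """
    ref = importlib.resources.files("screenmin") / "fixtures" / "navy_metabolites.tsv"
    with importlib.resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t", comment="#")
    p1 = np.where(frame["min_ind"] == 1, frame["pmin"], frame["pmax"])
    p2 = np.where(frame["min_ind"] == 1, frame["pmax"], frame["pmin"])
    table = PValueTable(p1, p2, ids=frame["id"].to_numpy())
    if with_names:
        return table, frame
    return table
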