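"""CSV / JSON input-output for datasets, results and fits.

All tables are plain long-format CSV so round trips are lossless and
diffable; fitted models serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .glmm import FitResult
from .glmm.data import REQUIRED_COLUMNS, DataError, TrialData, as_trial

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_results",
    "read_results",
    "write_fit_json",
]


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format cluster-period count table.

    Required columns: ``cluster_id, period, X, t_months, offset, Y``.
    Raises :class:`~swdsim.glmm.data.DataError` with row/column diagnostics
    on schema violations.
    """
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    as_trial(frame)  # full validation; result discarded
    return frame[list(REQUIRED_COLUMNS)]


def write_dataset(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a dataset table; the written file reads back identically."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a study results table (one row per scenario x model cell)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"scenario": str})


def write_fit_json(fit: FitResult, path: str | Path) -> None:
    """Serialize a fitted model (estimates, SE, CI, variance components)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")
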