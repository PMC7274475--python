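"""Result-table validation, aggregation and serialisation.

All experiment runners emit one long-format schema —
``(experiment, condition, replicate, trial, phase, quantity, value)`` —
so every figure-style aggregate is a group-by away.  ``write_results``
persists the table as RFC-4180-style CSV plus a JSON sidecar with
per-condition means / SDs and the resolved configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .experiments import RESULT_COLUMNS

__all__ = ["validate_table", "summarize", "write_results"]

_KEY = ["experiment", "condition", "replicate", "trial", "quantity"]


def validate_table(table: pd.DataFrame) -> None:
    """Check schema, finiteness and key uniqueness of a result table."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"result table lacks columns {missing}")
    if len(table) == 0:
        return
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise ValueError("result table contains non-finite values")
    if table.duplicated(subset=_KEY).any():
        raise ValueError(f"result table keys {_KEY} are not unique")


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(experiment, condition, phase, quantity) mean and SD over records."""
    if len(table) == 0:
        return pd.DataFrame(columns=["experiment", "condition", "phase", "quantity", "mean", "sd", "n"])
    grouped = table.groupby(["experiment", "condition", "phase", "quantity"])["value"]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
) -> Path:
    """Write the table as CSV and a JSON summary next to it.

    The CSV uses comma delimiters, a header row and '.' decimals; the
    sidecar ``<stem>.summary.json`` holds per-condition means and SDs and,
    when given, the resolved configuration.  Byte-identical for identical
    (table, config).
    """
    validate_table(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.12g")

    summary = summarize(table)
    payload = {
        "summary": summary.to_dict(orient="records"),
        "config": config.to_dict() if config is not None else None,
    }
    sidecar = path.with_suffix(".summary.json")
    with open(sidecar, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
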