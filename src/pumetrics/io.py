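"""Score-table input and report output.

Score tables are delimited text files (CSV/TSV) with a header, one row per
example: a real-valued prediction score, a mandatory pseudo-label column
(1 = labeled, 0 = unlabeled) for correction workflows, and optionally a
true-label column enabling traditional validation.  Reports are serialized
to JSON (round-trippable, with tool version, configuration, seed, and any
clipping/undefinedness flags) or to TSV for tabular curve data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ScoreTable", "InputError", "read_score_table", "write_report", "sweep_frame"]

logger = logging.getLogger("pumetrics")


class InputError(ValueError):
    """Invalid user-supplied input (bad file, bad column, bad value)."""


@dataclass(frozen=True)
class ScoreTable:
    """Validated prediction scores with pseudo- and optional true labels."""

    scores: np.ndarray
    pseudo_labels: np.ndarray
    true_labels: Optional[np.ndarray] = None
    ids: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def has_true_labels(self) -> bool:
        return self.true_labels is not None


def _validate_binary(values: pd.Series, column: str) -> np.ndarray:
    numeric = pd.to_numeric(values, errors="coerce")
    bad = ~numeric.isin((0, 1))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
        raise InputError(
            f"column {column!r} must be binary (0/1); row {row} has {values.iloc[row - 1]!r}"
        )
    return numeric.to_numpy(dtype=int)


def read_score_table(
    path,
    score_col: str = "score",
    pseudo_col: str = "pu_label",
    true_col: str = "true_label",
    id_col: str = "id",
    delimiter: Optional[str] = None,
) -> ScoreTable:
    """Read and validate a delimited score table.

    The delimiter is inferred from the extension (``.tsv`` → tab, otherwise
    comma) unless given explicitly.  Column names are configurable; the
    true-label and id columns are optional and picked up when present.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        frame = pd.read_csv(path, sep=delimiter)
    except FileNotFoundError:
        raise InputError(f"score file not found: {path}")
    except pd.errors.ParserError as exc:
        raise InputError(f"cannot parse {path}: {exc}")

    for column in (score_col, pseudo_col):
        if column not in frame.columns:
            raise InputError(
                f"missing required column {column!r} in {path} (found {list(frame.columns)})"
            )
    if frame.empty:
        raise InputError(f"score file {path} has no data rows")

    scores = pd.to_numeric(frame[score_col], errors="coerce")
    if scores.isna().any():
        row = int(np.flatnonzero(scores.isna().to_numpy())[0]) + 1
        raise InputError(
            f"column {score_col!r} must be numeric; row {row} has {frame[score_col].iloc[row - 1]!r}"
        )

    pseudo = _validate_binary(frame[pseudo_col], pseudo_col)
    true = _validate_binary(frame[true_col], true_col) if true_col in frame.columns else None
    ids = frame[id_col].to_numpy() if id_col in frame.columns else None
    logger.info("read %d rows from %s (true labels: %s)", len(frame), path, true is not None)
    return ScoreTable(
        scores=scores.to_numpy(dtype=float), pseudo_labels=pseudo, true_labels=true, ids=ids
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(report, path, format: str = "json") -> None:
    """Serialize a report (dataclass, dict or DataFrame) to JSON or TSV."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_jsonable(report), indent=2) + "\n")
    elif format == "tsv":
        frame = report if isinstance(report, pd.DataFrame) else pd.DataFrame(_jsonable(report))
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise InputError(f"unknown report format {format!r} (use 'json' or 'tsv')")
    logger.info("wrote %s report to %s", format, path)


def sweep_frame(sw) -> pd.DataFrame:
    """Tabulate a :class:`~pumetrics.gaussian.ThresholdSweep` as one ``tau``
    column plus one column per metric curve."""
    data = {"tau": sw.taus}
    for (metric, mode), curve in sw.curves.items():
        data[f"{metric}_{mode}"] = curve
    return pd.DataFrame(data)
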