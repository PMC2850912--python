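"""Reading and writing absorbance curves and parameter tables (CSV/JSON)."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .fitting import AbsorbanceSeries, FitResult

__all__ = [
    "DataFormatError",
    "read_absorbance_csv",
    "write_absorbance_csv",
    "fit_results_table",
    "write_parameter_table",
    "read_parameter_table",
]

TIME_COL = "time_min"
VALUE_COL = "absorbance"

#: fit-output table layout consumed by the meta-regressions
TABLE_COLUMNS = ["label", "ca_uM", "tau_min", "a", "b", "k", "r", "err", "mode", "converged"]


class DataFormatError(ValueError):
    """Malformed input data; the message names the offending line."""


def read_absorbance_csv(
    path: str | Path,
    time_col: str = TIME_COL,
    value_col: str = VALUE_COL,
    label: str | None = None,
) -> AbsorbanceSeries:
    """Read one OD time series from a headed CSV file.

    Non-numeric cells, missing columns and non-increasing time points are
    rejected with the 1-based line number of the first offending row.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or time_col not in reader.fieldnames or value_col not in reader.fieldnames:
            raise DataFormatError(
                f"{path}: header must contain columns {time_col!r} and {value_col!r} "
                f"(found {reader.fieldnames})"
            )
        for row in reader:
            line = reader.line_num
            try:
                t = float(row[time_col])
                v = float(row[value_col])
            except (TypeError, ValueError):
                raise DataFormatError(
                    f"{path}, line {line}: non-numeric cell "
                    f"({time_col}={row.get(time_col)!r}, {value_col}={row.get(value_col)!r})"
                ) from None
            if times and t <= times[-1]:
                kind = "duplicated" if t == times[-1] else "decreasing"
                raise DataFormatError(
                    f"{path}, line {line}: {kind} time point t={t:g} (previous {times[-1]:g})"
                )
            times.append(t)
            values.append(v)
    try:
        return AbsorbanceSeries(
            times=np.asarray(times), values=np.asarray(values),
            label=path.stem if label is None else label,
        )
    except ValueError as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def write_absorbance_csv(series: AbsorbanceSeries, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([TIME_COL, VALUE_COL])
        for t, v in zip(series.times, series.values):
            writer.writerow([repr(float(t)), repr(float(v))])


def fit_results_table(results: Iterable[tuple[AbsorbanceSeries, FitResult]]) -> pd.DataFrame:
    rows = []
    for series, res in results:
        p = res.params
        rows.append(
            dict(label=series.label, ca_uM=series.ca_uM, tau_min=p.tau, a=p.a,
                 b=p.b, k=p.k, r=p.r, err=res.err, mode=res.mode,
                 converged=res.converged)
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_parameter_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    """Read a parameter table; needs at least ca_uM, tau_min, a, k columns."""
    df = pd.read_csv(path)
    missing = {"ca_uM", "tau_min", "a", "k"} - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
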