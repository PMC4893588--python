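"""CSV trace reading and writing.

The canonical trace format is a headed CSV with an optional ISO-8601
``timestamp`` column and a ``glucose_mmol_per_L`` column (a column
simply named ``glucose`` is also accepted).  mg/dL inputs are converted
with the conventional clinical factor 18.0.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .evaluation import MMOL_TO_MGDL
from .series import GlucoseSeries

GLUCOSE_COLUMNS = ("glucose_mmol_per_L", "glucose")


def read_trace(
    path: Union[str, Path],
    glucose_column: Optional[str] = None,
    units: str = "mmol/L",
    sample_interval: float = 5.0,
) -> GlucoseSeries:
    """Read a glucose trace from CSV.

    Parse errors report 1-based file line numbers (header = line 1).
    """
    if units not in ("mmol/L", "mg/dL"):
        raise InvalidInputError(f"units must be 'mmol/L' or 'mg/dL', got {units!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise InvalidInputError(f"{path}: file is empty") from None
    if frame.empty:
        raise InvalidInputError(f"{path}: no data rows")
    if glucose_column is None:
        for cand in GLUCOSE_COLUMNS:
            if cand in frame.columns:
                glucose_column = cand
                break
        else:
            raise InvalidInputError(
                f"{path}: no glucose column found (expected one of {GLUCOSE_COLUMNS}); "
                f"columns present: {list(frame.columns)}"
            )
    elif glucose_column not in frame.columns:
        raise InvalidInputError(f"{path}: missing column {glucose_column!r}")

    raw = pd.to_numeric(frame[glucose_column], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(raw))
    if bad.size:
        raise InvalidInputError(
            f"{path}: non-numeric glucose at line {int(bad[0]) + 2}"
        )
    if units == "mg/dL":
        raw = raw / MMOL_TO_MGDL
    nonpos = np.flatnonzero(raw <= 0)
    if nonpos.size:
        raise InvalidInputError(
            f"{path}: non-positive glucose at line {int(nonpos[0]) + 2}"
        )
    start_time = None
    if "timestamp" in frame.columns:
        try:
            start_time = pd.to_datetime(frame["timestamp"].iloc[0]).to_pydatetime()
        except (ValueError, TypeError):
            start_time = None
    return GlucoseSeries(raw, sample_interval=sample_interval, start_time=start_time)


def write_trace(path: Union[str, Path], series: GlucoseSeries) -> None:
    """Write a trace as canonical CSV (round-trips through read_trace)."""
    frame = pd.DataFrame({"glucose_mmol_per_L": series.values})
    if series.start_time is not None:
        frame.insert(
            0,
            "timestamp",
            pd.date_range(
                series.start_time,
                periods=len(series),
                freq=pd.Timedelta(minutes=series.sample_interval),
            ),
        )
    # %.17g guarantees bit-exact float round-trips through the CSV
    frame.to_csv(path, index=False, float_format="%.17g")
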