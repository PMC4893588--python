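"""Container for a CGM glucose trace.

A continuous glucose monitor reports interstitial glucose on a fixed
cadence (conventionally every 5 minutes, 864 samples per 72 h).  All
model code in this package consumes the :class:`GlucoseSeries` wrapper,
which enforces the positivity the grey model's log transform requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence, Union

import numpy as np

from .errors import InvalidInputError

ArrayLike = Union[Sequence[float], np.ndarray]

#: Minimum window length accepted by the grey model fit: the least-squares
#: system needs at least 3 rows to leave a testable residual.
MIN_FIT_LENGTH = 4


@dataclass(frozen=True)
class GlucoseSeries:
    """A strictly positive univariate glucose trace.

    Parameters
    ----------
    values : array-like of float
        Glucose concentrations in mmol/L.  Every value must be > 0.
    sample_interval : float, default 5.0
        Minutes between consecutive samples.
    start_time : datetime, optional
        Timestamp of the first sample; carried as metadata only.
    """

    values: np.ndarray
    sample_interval: float = 5.0
    start_time: Optional[datetime] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidInputError("glucose series must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0]) + 1
            raise InvalidInputError(f"non-finite glucose value at index {bad}")
        if np.any(arr <= 0):
            bad = int(np.flatnonzero(arr <= 0)[0]) + 1
            raise InvalidInputError(
                f"glucose must be strictly positive; offending index {bad} "
                f"(value {arr[bad - 1]!r})"
            )
        if self.sample_interval <= 0:
            raise InvalidInputError("sample_interval must be positive")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    def __getitem__(self, key):
        return self.values[key]

    def window(self, start: int, stop: int) -> "GlucoseSeries":
        """Sub-series of 1-based sample indices ``start..stop`` inclusive."""
        if not (1 <= start <= stop <= len(self)):
            raise InvalidInputError(
                f"window [{start}, {stop}] out of bounds for series of length {len(self)}"
            )
        return GlucoseSeries(
            self.values[start - 1 : stop],
            sample_interval=self.sample_interval,
        )
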