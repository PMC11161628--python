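"""Unit-tagged scalar time series shared by the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SeriesError


@dataclass
class ScalarSeries:
    """A per-frame scalar observable.

    Attributes
    ----------
    times : ndarray
        Frame times in nanoseconds.
    values : ndarray
        Observable values; interpretation given by ``unit``
        (Å for RMSD and Rg, degrees for angles).
    unit : str
        Unit tag, e.g. ``"angstrom"`` or ``"degree"``.
    label : str
        Human-readable description of what was measured.
    """

    times: np.ndarray
    values: np.ndarray
    unit: str
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise SeriesError(
                f"times ({self.times.shape}) and values ({self.values.shape}) "
                "must have equal length"
            )
        if not self.unit:
            raise SeriesError("a unit tag is required")

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        """Write the series as a two-column CSV (time_ns, value)."""
        import pandas as pd

        pd.DataFrame({"time_ns": self.times, self.label or "value": self.values}).to_csv(
            path, index=False
        )
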