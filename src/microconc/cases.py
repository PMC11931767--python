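"""Case-series container: one row per event, ordered by date.

The case-only design works entirely within the event series: each case
carries a date, an assigned microplace id and — once computed — a binary
*repeat* indicator (1 if at least one other event in the full series shares
its microplace, 0 otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CaseSeries", "CASE_COLUMNS"]

CASE_COLUMNS = ["event_id", "date", "microplace_id", "assignment_distance", "repeat"]


@dataclass
class CaseSeries:
    """An ordered series of assigned cases.

    ``data`` columns: ``event_id`` (str), ``date`` (datetime64),
    ``microplace_id`` (str), ``assignment_distance`` (float, 0 for
    label-based assignment), ``repeat`` (nullable Int8; absent until
    computed).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in CASE_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA if col in ("microplace_id", "repeat") else np.nan
        df["event_id"] = df["event_id"].astype(str)
        df["date"] = pd.to_datetime(df["date"])
        df["repeat"] = df["repeat"].astype("Int8")
        df = df.sort_values(["date", "event_id"], kind="mergesort").reset_index(drop=True)
        self.data = df[CASE_COLUMNS]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_repeat(self) -> bool:
        return len(self.data) > 0 and self.data["repeat"].notna().all()

    @property
    def years(self) -> np.ndarray:
        """Calendar year of each case."""
        return self.data["date"].dt.year.to_numpy()

    @property
    def study_years(self) -> tuple[int, int]:
        if len(self.data) == 0:
            raise ValueError("empty case series has no study years")
        yrs = self.years
        return int(yrs.min()), int(yrs.max())

    def with_repeat(self, repeat: np.ndarray) -> "CaseSeries":
        if len(repeat) != len(self.data):
            raise ValueError("repeat vector length must match number of cases")
        df = self.data.copy()
        df["repeat"] = np.asarray(repeat, dtype="int8")
        return CaseSeries(df)

    # -- serialization ---------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CaseSeries":
        return cls(pd.read_csv(path, dtype={"event_id": str, "microplace_id": str}))

    @classmethod
    def from_records(cls, records) -> "CaseSeries":
        return cls(pd.DataFrame.from_records(records))
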