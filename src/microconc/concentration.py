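"""Repeat-location indicator and annual spatial concentration.

Spatial concentration is operationalized per event: the binary *repeat*
indicator is 1 when at least one other event anywhere in the study period
(past or future) occurred at the same microplace, 0 when the event's
location is unique in the series.  Annual concentration is the proportion
of a calendar year's events with repeat = 1, with repeat membership always
evaluated against the full series, never within-year.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cases import CaseSeries
from .network import MicroplaceNetwork

__all__ = [
    "compute_repeat_indicators",
    "annual_concentration",
    "summary_table",
    "round_pct",
]


def round_pct(proportion: float, decimals: int = 1) -> float:
    """Percent with half-up rounding (display convention for tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(proportion * 100)).quantize(q, rounding=ROUND_HALF_UP))


def compute_repeat_indicators(series: CaseSeries) -> CaseSeries:
    """Populate the repeat indicator for every case.

    ``repeat[i] = 1`` iff the whole series contains >= 2 cases at case
    *i*'s microplace.  Raises if any case lacks a microplace assignment.
    """
    df = series.data
    if len(df) == 0:
        return series.with_repeat(np.zeros(0, dtype="int8"))
    missing = df["microplace_id"].isna()
    if missing.any():
        bad = df.loc[missing, "event_id"].iloc[0]
        raise ValueError(f"case {bad!r} has no microplace assignment")
    counts = df["microplace_id"].value_counts()
    repeat = (df["microplace_id"].map(counts) >= 2).to_numpy(dtype="int8")
    return series.with_repeat(repeat)


def annual_concentration(series: CaseSeries, year_end: float | None = None) -> pd.DataFrame:
    """Per-calendar-year event counts and concentration.

    Columns: ``year``, ``n_events``, ``n_repeat``, ``concentration``
    (NaN where a year has no events), ``partial`` (True for a final
    partial year when ``year_end`` is fractional).  Repeat status comes
    from the already-computed full-series indicator.
    """
    if not series.has_repeat:
        raise ValueError("repeat indicators must be computed first")
    df = series.data
    years = df["date"].dt.year
    grouped = df.groupby(years)["repeat"].agg(n_events="size", n_repeat="sum")
    full_range = np.arange(years.min(), years.max() + 1)
    out = grouped.reindex(full_range, fill_value=0).reset_index(names="year")
    out["n_repeat"] = out["n_repeat"].astype(int)
    out["concentration"] = np.where(
        out["n_events"] > 0, out["n_repeat"] / out["n_events"].replace(0, 1), np.nan
    )
    out["partial"] = False
    if year_end is not None and year_end != int(year_end):
        out.loc[out["year"] == int(year_end), "partial"] = True
    return out


def summary_table(
    series: CaseSeries, network: MicroplaceNetwork | None = None
) -> dict:
    """Study-level summary: microplace counts by kind and repeat shares.

    Percentages are half-up rounded to one decimal for display; raw
    proportions are kept at full precision alongside.  With an empty
    series the shares are reported as ``None``.
    """
    if len(series) > 0 and not series.has_repeat:
        raise ValueError("repeat indicators must be computed first")
    n = len(series)
    n_repeat = int(series.data["repeat"].sum()) if n else 0
    n_non = n - n_repeat
    out: dict = {
        "n_events": n,
        "n_repeat": n_repeat,
        "n_non_repeat": n_non,
        "repeat_share": n_repeat / n if n else None,
        "repeat_pct": round_pct(n_repeat / n) if n else None,
        "non_repeat_pct": round_pct(n_non / n) if n else None,
    }
    if network is not None:
        counts = network.counts_by_kind
        total = len(network)
        out.update(
            {
                "n_microplaces": total,
                "n_segments": counts["segment"],
                "n_intersections": counts["intersection"],
                "segments_pct": round_pct(counts["segment"] / total),
                "intersections_pct": round_pct(counts["intersection"] / total),
            }
        )
    return out
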