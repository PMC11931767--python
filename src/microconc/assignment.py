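"""Resolve raw event locations to microplaces.

Events arrive with one of four location encodings: a pre-assigned
microplace id, a cross-street pair ("South St. & Main St." style, resolved
to an intersection), a street/address reference (resolved to a segment by
label), or planar coordinates (snapped to the nearest microplace within a
threshold).  Events that cannot be resolved are excluded and logged with a
reason rather than guessed at.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .cases import CaseSeries
from .network import MicroplaceNetwork

__all__ = [
    "LocationMode",
    "RawLocation",
    "UnknownLocationError",
    "UnresolvableLocationError",
    "OutOfRangeError",
    "parse_location",
    "assign_to_microplace",
    "build_case_series",
    "DEFAULT_SNAP_THRESHOLD",
]

DEFAULT_SNAP_THRESHOLD = 100.0


class LocationMode(str, Enum):
    PREASSIGNED = "preassigned"
    CROSS_STREETS = "cross_streets"
    ADDRESS_REF = "address_ref"
    COORDINATES = "coordinates"


class UnknownLocationError(ValueError):
    """No location field populated for an event."""


class UnresolvableLocationError(ValueError):
    """A label-based location matched nothing in the network."""


class OutOfRangeError(ValueError):
    """Nearest microplace farther than the snap threshold."""


@dataclass(frozen=True)
class RawLocation:
    mode: LocationMode
    payload: Any  # id | (street_a, street_b) | street label | (x, y)


def _filled(value: Any) -> bool:
    if value is None:
        return False
    if isinstance(value, float) and np.isnan(value):
        return False
    return not (isinstance(value, str) and value.strip() == "")


def parse_location(record: Mapping[str, Any]) -> RawLocation:
    """Classify one raw event row into a :class:`RawLocation`.

    Precedence when several encodings are populated: cross streets, then
    address reference, then coordinates, then pre-assigned id.  A row with
    no location information raises :class:`UnknownLocationError` naming the
    event (such events are excluded from the analytic sample).
    """
    a, b = record.get("cross_street_a"), record.get("cross_street_b")
    if _filled(a) and _filled(b):
        return RawLocation(LocationMode.CROSS_STREETS, (str(a), str(b)))
    addr = record.get("address_ref")
    if _filled(addr):
        return RawLocation(LocationMode.ADDRESS_REF, str(addr))
    x, y = record.get("x"), record.get("y")
    if _filled(x) and _filled(y):
        return RawLocation(LocationMode.COORDINATES, (float(x), float(y)))
    mp = record.get("microplace_id")
    if _filled(mp):
        return RawLocation(LocationMode.PREASSIGNED, str(mp))
    raise UnknownLocationError(
        f"event {record.get('event_id', '<unknown>')!r} has no location information"
    )


def assign_to_microplace(
    loc: RawLocation,
    network: MicroplaceNetwork,
    snap_threshold: float = DEFAULT_SNAP_THRESHOLD,
) -> tuple[str, float]:
    """Resolve a :class:`RawLocation` to ``(microplace_id, distance)``.

    Cross-street pairs match intersections by unordered, normalized label
    pair; address references match segments by normalized label;
    coordinates snap to the nearest microplace (ties broken by smallest
    id), rejected if farther than ``snap_threshold``.  Distance is 0 for
    all label-based modes.
    """
    if snap_threshold <= 0:
        raise ValueError("snap_threshold must be positive")
    if loc.mode is LocationMode.PREASSIGNED:
        if loc.payload not in network:
            raise UnresolvableLocationError(
                f"microplace id {loc.payload!r} not in network"
            )
        return loc.payload, 0.0
    if loc.mode is LocationMode.CROSS_STREETS:
        a, b = loc.payload
        hit = network.intersection_by_cross_streets(a, b)
        if hit is None:
            raise UnresolvableLocationError(
                f"no intersection matches cross streets {a!r} & {b!r}"
            )
        return hit, 0.0
    if loc.mode is LocationMode.ADDRESS_REF:
        hit = network.segment_by_label(loc.payload)
        if hit is None:
            raise UnresolvableLocationError(
                f"no street segment matches address {loc.payload!r}"
            )
        return hit, 0.0
    x, y = loc.payload
    mp_id, dist = network.nearest(x, y)
    if dist > snap_threshold:
        raise OutOfRangeError(
            f"nearest microplace {mp_id!r} at distance {dist:.3f} exceeds "
            f"snap threshold {snap_threshold:.3f}"
        )
    return mp_id, dist


def build_case_series(
    events: pd.DataFrame,
    network: MicroplaceNetwork,
    snap_threshold: float = DEFAULT_SNAP_THRESHOLD,
) -> tuple[CaseSeries, pd.DataFrame]:
    """Assign every event in a raw table; log the rest.

    Returns the assigned :class:`CaseSeries` (ordered by date then event
    id) and an exclusion log with one row per unassignable event
    (``event_id``, ``reason``).  ``|assigned| + |excluded| == |input|``
    always holds.
    """
    assigned = []
    excluded = []
    for rec in events.to_dict("records"):
        event_id = str(rec.get("event_id", ""))
        try:
            loc = parse_location(rec)
            mp_id, dist = assign_to_microplace(loc, network, snap_threshold)
        except (UnknownLocationError, UnresolvableLocationError, OutOfRangeError) as e:
            excluded.append({"event_id": event_id, "reason": str(e)})
            continue
        assigned.append(
            {
                "event_id": event_id,
                "date": rec["date"],
                "microplace_id": mp_id,
                "assignment_distance": dist,
            }
        )
    series = CaseSeries(
        pd.DataFrame(assigned)
        if assigned
        else pd.DataFrame(columns=["event_id", "date", "microplace_id"])
    )
    log = pd.DataFrame(excluded, columns=["event_id", "reason"])
    return series, log
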