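"""Street-network microplaces: segments and intersections.

A *microplace* is the smallest spatial unit used in place-based violence
research: a single street segment (block face) or a single street
intersection.  A :class:`MicroplaceNetwork` is the complete inventory of
microplaces for a study area, each with a unique id, a kind, a planar
geometry and an optional human-readable label (street name / cross-street
pair) used for label-based event assignment.

Coordinates are planar (projected) throughout; no geodetic handling is
performed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import LineString, Point, mapping, shape
from shapely.strtree import STRtree

__all__ = [
    "Kind",
    "Microplace",
    "MicroplaceNetwork",
    "EmptyNetworkError",
    "generate_network",
]


class EmptyNetworkError(ValueError):
    """Raised when a network with zero microplaces is requested or used."""


class Kind(str, Enum):
    SEGMENT = "segment"
    INTERSECTION = "intersection"


@dataclass(frozen=True)
class Microplace:
    """One street segment or intersection.

    ``geometry`` is a shapely LineString (segment, >= 2 vertices) or Point
    (intersection).  ``label`` carries the street name for segments and the
    cross-street pair (joined with ``" & "``) for intersections.
    """

    id: str
    kind: Kind
    geometry: LineString | Point
    label: str | None = None

    def __post_init__(self) -> None:
        if self.kind is Kind.SEGMENT and not isinstance(self.geometry, LineString):
            raise TypeError(f"segment {self.id!r} requires LineString geometry")
        if self.kind is Kind.INTERSECTION and not isinstance(self.geometry, Point):
            raise TypeError(f"intersection {self.id!r} requires Point geometry")


def normalize_label(label: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    out = []
    for ch in label.lower():
        if ch.isalnum():
            out.append(ch)
        elif ch.isspace():
            out.append(" ")
        # punctuation dropped
    return " ".join("".join(out).split())


def normalize_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered, normalized cross-street pair key."""
    na, nb = normalize_label(a), normalize_label(b)
    return (na, nb) if na <= nb else (nb, na)


class MicroplaceNetwork:
    """The full set of microplaces for a study area.

    Provides id lookup, label lookup (segments by street label,
    intersections by unordered cross-street pair) and nearest-geometry
    queries backed by an STRtree.
    """

    def __init__(self, microplaces: Sequence[Microplace]):
        places = list(microplaces)
        if not places:
            raise EmptyNetworkError("a network must contain at least one microplace")
        ids = [m.id for m in places]
        if len(set(ids)) != len(ids):
            raise ValueError("microplace ids must be unique within a network")
        self.microplaces: list[Microplace] = places
        self._by_id = {m.id: m for m in places}
        self._segment_by_label: dict[str, str] = {}
        self._intersection_by_pair: dict[tuple[str, str], str] = {}
        for m in places:
            if m.label is None:
                continue
            if m.kind is Kind.SEGMENT:
                self._segment_by_label.setdefault(normalize_label(m.label), m.id)
            else:
                parts = [p for p in m.label.split("&") if p.strip()]
                if len(parts) == 2:
                    key = normalize_pair(parts[0], parts[1])
                    self._intersection_by_pair.setdefault(key, m.id)
        self._tree: STRtree | None = None
        self._tree_order: list[str] | None = None

    # -- basic container behaviour -------------------------------------
    def __len__(self) -> int:
        return len(self.microplaces)

    def __contains__(self, microplace_id: str) -> bool:
        return microplace_id in self._by_id

    def __getitem__(self, microplace_id: str) -> Microplace:
        return self._by_id[microplace_id]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.microplaces]

    @property
    def counts_by_kind(self) -> dict[str, int]:
        counts = {Kind.SEGMENT.value: 0, Kind.INTERSECTION.value: 0}
        for m in self.microplaces:
            counts[m.kind.value] += 1
        return counts

    # -- lookups --------------------------------------------------------
    def segment_by_label(self, label: str) -> str | None:
        return self._segment_by_label.get(normalize_label(label))

    def intersection_by_cross_streets(self, a: str, b: str) -> str | None:
        return self._intersection_by_pair.get(normalize_pair(a, b))

    def nearest(self, x: float, y: float) -> tuple[str, float]:
        """Nearest microplace to a planar point.

        Ties (to machine tolerance) are broken by lexicographically
        smallest id so assignment is deterministic.  Returns
        ``(microplace_id, distance)``.
        """
        if self._tree is None:
            # sort geometries by id so tree queries are reproducible
            order = sorted(self.microplaces, key=lambda m: m.id)
            self._tree = STRtree([m.geometry for m in order])
            self._tree_order = [m.id for m in order]
        pt = Point(x, y)
        idx = self._tree.query_nearest(pt, all_matches=True)
        candidates = sorted(self._tree_order[i] for i in np.atleast_1d(idx))
        best = candidates[0]
        return best, float(self._by_id[best].geometry.distance(pt))

    # -- serialization ----------------------------------------------------
    def to_geojson(self) -> str:
        features = []
        for m in self.microplaces:
            features.append(
                {
                    "type": "Feature",
                    "id": m.id,
                    "geometry": mapping(m.geometry),
                    "properties": {"kind": m.kind.value, "label": m.label},
                }
            )
        return json.dumps(
            {"type": "FeatureCollection", "features": features}, sort_keys=True
        )

    def write_geojson(self, path: str | Path) -> None:
        Path(path).write_text(self.to_geojson())

    @classmethod
    def from_geojson(cls, source: str | Path) -> "MicroplaceNetwork":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        places = []
        for feat in doc["features"]:
            props = feat.get("properties") or {}
            places.append(
                Microplace(
                    id=str(feat["id"]),
                    kind=Kind(props["kind"]),
                    geometry=shape(feat["geometry"]),
                    label=props.get("label"),
                )
            )
        return cls(places)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [m.id for m in self.microplaces],
                "kind": [m.kind.value for m in self.microplaces],
                "label": [m.label for m in self.microplaces],
                "wkt": [m.geometry.wkt for m in self.microplaces],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MicroplaceNetwork":
        df = pd.read_csv(path)
        places = [
            Microplace(
                id=str(row.id),
                kind=Kind(row.kind),
                geometry=shapely_wkt.loads(row.wkt),
                label=None if pd.isna(row.label) else str(row.label),
            )
            for row in df.itertuples()
        ]
        return cls(places)


def generate_network(
    n_segments: int,
    n_intersections: int,
    seed: int = 0,
    spacing: float = 100.0,
    jitter: float = 8.0,
) -> MicroplaceNetwork:
    """Generate a planar grid-with-jitter street network.

    Nodes sit on a rectangular grid (``spacing`` planar units apart) with
    Gaussian positional jitter.  Segments are block faces along east-west
    "streets"; intersections are placed at grid nodes shared by two
    adjacent segments where possible (cross-labelled with the north-south
    "avenue" through that node), with any surplus intersections placed at
    remaining grid nodes.  Deterministic given ``seed``.

    Labels follow a ``"street R block C"`` / ``"street R & avenue C"``
    convention so label-based assignment can be exercised on synthetic
    data.
    """
    if n_segments < 0 or n_intersections < 0:
        raise ValueError("counts must be non-negative")
    if n_segments + n_intersections < 1:
        raise EmptyNetworkError("requested network has zero microplaces")

    rng = np.random.default_rng(seed)
    # grid large enough for the requested segments (per row: n_cols-1 edges)
    n_cols = max(2, int(np.ceil(np.sqrt(max(n_segments, n_intersections)))) + 1)
    n_rows = max(1, int(np.ceil(max(n_segments / (n_cols - 1), 1))))
    # also ensure enough nodes for surplus intersections
    while n_rows * n_cols < n_intersections + 1:
        n_rows += 1

    xs = np.arange(n_cols) * spacing + rng.normal(0.0, jitter, size=(n_rows, n_cols))
    ys = (np.arange(n_rows) * spacing)[:, None] + rng.normal(
        0.0, jitter, size=(n_rows, n_cols)
    )

    places: list[Microplace] = []
    width = len(str(max(n_segments, n_intersections, 1)))
    k = 0
    for r in range(n_rows):
        for c in range(n_cols - 1):
            if k >= n_segments:
                break
            geom = LineString(
                [(float(xs[r, c]), float(ys[r, c])), (float(xs[r, c + 1]), float(ys[r, c + 1]))]
            )
            places.append(
                Microplace(
                    id=f"seg-{k:0{width}d}",
                    kind=Kind.SEGMENT,
                    geometry=geom,
                    label=f"street {r} block {c}",
                )
            )
            k += 1
        if k >= n_segments:
            break

    # interior nodes shared by >= 2 segments first, then any grid node
    shared: list[tuple[int, int]] = []
    segs_in_row = {}
    remaining = n_segments
    for r in range(n_rows):
        segs_in_row[r] = min(remaining, n_cols - 1)
        remaining -= segs_in_row[r]
    for r in range(n_rows):
        for c in range(1, segs_in_row[r]):
            shared.append((r, c))
    spare = [
        (r, c)
        for r in range(n_rows)
        for c in range(n_cols)
        if (r, c) not in set(shared)
    ]
    nodes = (shared + spare)[:n_intersections]
    if len(nodes) < n_intersections:
        raise ValueError("grid too small for requested intersections")
    for j, (r, c) in enumerate(nodes):
        places.append(
            Microplace(
                id=f"int-{j:0{width}d}",
                kind=Kind.INTERSECTION,
                geometry=Point(float(xs[r, c]), float(ys[r, c])),
                label=f"street {r} & avenue {c}",
            )
        )
    return MicroplaceNetwork(places)
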