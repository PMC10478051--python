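"""Tract geometry containers and GeoJSON (RFC 7946) I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from shapely.geometry import Point, Polygon, mapping, shape

__all__ = ["TractGeometry", "write_geojson", "read_geojson"]


@dataclass(frozen=True)
class TractGeometry:
    tract_id: str
    polygon: Polygon

    @property
    def centroid(self) -> Point:
        return self.polygon.centroid


def write_geojson(
    geoms: Sequence[TractGeometry],
    path: str | Path,
    extra_properties: dict[str, dict] | None = None,
) -> None:
    """Write tracts as a FeatureCollection with a ``tract_id`` property.

    ``extra_properties`` maps tract_id -> additional property dict (used to
    attach hot-spot results for mapping).
    """
    features = []
    for g in geoms:
        props: dict = {"tract_id": g.tract_id}
        if extra_properties and g.tract_id in extra_properties:
            props.update(extra_properties[g.tract_id])
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(g.polygon)}
        )
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc), encoding="utf-8")


def read_geojson(path: str | Path) -> list[TractGeometry]:
    """Read a FeatureCollection; every feature must carry a ``tract_id``."""
    fc = json.loads(Path(path).read_text(encoding="utf-8"))
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    geoms = []
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties") or {}
        if "tract_id" not in props:
            raise ValueError(f"{path}: feature {i} missing 'tract_id' property")
        geoms.append(TractGeometry(str(props["tract_id"]), shape(feat["geometry"])))
    return geoms
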