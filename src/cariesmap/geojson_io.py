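"""GeoJSON reading/writing and contiguity for parish geometries.

Maps are exchanged as RFC 7946 FeatureCollections whose features carry the
parish id plus, on export, the smoothed relative risk, exceedance
probability and certainty color.  Adjacency can be derived from polygon
geometry by queen contiguity (any shared boundary point).
"""

from __future__ import annotations

import itertools
import json

import networkx as nx
import pandas as pd
from shapely.geometry import box, mapping, shape


def square_geometries(coords: dict) -> dict:
    """Unit-square polygons for lattice grid coordinates (row, col)."""
    return {p: box(c, -r - 1, c + 1, -r) for p, (r, c) in coords.items()}


def read_geojson_features(path, *, id_property: str = "parish_id") -> dict:
    """Load a GeoJSON FeatureCollection into {parish_id: shapely geometry}."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    out = {}
    for feat in doc["features"]:
        props = feat.get("properties") or {}
        pid = props.get(id_property, feat.get("id"))
        if pid is None:
            raise ValueError(f"{path}: feature without {id_property!r}")
        out[str(pid)] = shape(feat["geometry"])
    return out


def read_geojson_properties(path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    return pd.DataFrame([f.get("properties") or {} for f in doc["features"]])


def queen_contiguity(geometries: dict) -> nx.Graph:
    """Adjacency by shared boundary: queen rule (a single shared corner
    point is enough).  Quadratic scan — fine for tens of parishes."""
    g = nx.Graph()
    g.add_nodes_from(geometries)
    for (a, ga), (b, gb) in itertools.combinations(geometries.items(), 2):
        if ga.intersects(gb):
            g.add_edge(a, b)
    return g


def export_geojson(geometries: dict, posterior_table: pd.DataFrame, path) -> None:
    """Write the certainty map: one feature per parish with smrr,
    pr_exceed, category and color properties.

    The geometry ids and the posterior table's parish ids must match
    exactly; any mismatch is an error listing the unmatched ids.
    """
    if len(posterior_table) == 0:
        raise ValueError("posterior table is empty")
    post_ids = [str(p) for p in posterior_table["parish_id"]]
    geo_ids = {str(k) for k in geometries}
    missing_geom = sorted(set(post_ids) - geo_ids)
    missing_post = sorted(geo_ids - set(post_ids))
    if missing_geom or missing_post:
        raise ValueError(
            "parish id mismatch between geometry and posterior table: "
            f"no geometry for {missing_geom}; no posterior for {missing_post}"
        )
    features = []
    table = posterior_table.set_index(posterior_table["parish_id"].astype(str))
    for pid in sorted(post_ids):
        row = table.loc[pid]
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geometries[pid] if pid in geometries else geometries[row["parish_id"]]),
                "properties": {
                    "parish_id": pid,
                    "smrr": float(row["smrr"]),
                    "pr_exceed": float(row["pr_exceed"]),
                    "category": str(row["category"]),
                    "color": str(row["color"]),
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
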