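"""Reading and writing the package's artifact formats.

Spatial layers travel as GeoJSON FeatureCollections (shapely geometries plus
attribute properties) with a declared planar metric CRS; tables as CSV (and
Parquet for the expanded trip table).  Writers are deterministic: identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

#: All coordinates are planar meters in a local engineering CRS.
CRS_DOC = {"type": "name", "properties": {"name": "urn:routexpose:local-metric"}}


def write_layer(frame: pd.DataFrame, path) -> None:
    """Write a DataFrame with a ``geometry`` column as a GeoJSON file."""
    features = []
    prop_cols = [c for c in frame.columns if c != "geometry"]
    for _, row in frame.iterrows():
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(row["geometry"]),
                "properties": {c: _plain(row[c]) for c in prop_cols},
            }
        )
    doc = {"type": "FeatureCollection", "crs": CRS_DOC, "features": features}
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_layer(path) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection back into a geometry DataFrame."""
    doc = json.loads(Path(path).read_text())
    rows = []
    for feat in doc["features"]:
        row = dict(feat.get("properties") or {})
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    frame = pd.DataFrame(rows)
    if "geometry" in frame.columns:  # geometry last for readability
        cols = [c for c in frame.columns if c != "geometry"] + ["geometry"]
        frame = frame[cols]
    return frame


def _plain(v):
    if hasattr(v, "item"):
        return v.item()
    return v


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
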