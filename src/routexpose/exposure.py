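"""Per-trip exposure accounting: itinerary x grid overlay and trip features.

Each routed itinerary is cut against the hexagonal grid to obtain the length
traversed in every cell.  A trip's feature vector then combines its total
distance, the unweighted means of the built-environment attributes over the
distinct cells it crosses, and its noise exposure shares — the proportion of
the travelled distance spent in cells of each ordinal noise class.  Flows
are finally expanded to one row per commuter, matching the unit of analysis
of the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, OutOfExtentError, StateError
from .hexgrid import HexGrid, NoiseScheme

__all__ = ["TripRecord", "intersect_itinerary", "trip_features", "expand_flows"]

_REL_TOL = 1e-6


@dataclass
class TripRecord:
    """One trip's feature vector plus its mode label."""

    origin_cell: int
    dest_cell: int
    mode: str
    distance: float
    mean_building_area: float
    mean_street_length: float
    mean_poi: dict[str, float]
    noise_share: np.ndarray  # over scheme classes, ascending loudness

    def to_row(self, scheme: NoiseScheme) -> dict:
        row = {
            "mode": self.mode,
            "distance_m": self.distance,
            "mean_building_area_m2": self.mean_building_area,
            "mean_street_length_m": self.mean_street_length,
        }
        for cat, v in self.mean_poi.items():
            row[f"mean_poi_{cat}"] = v
        for key, share in zip(scheme.keys, self.noise_share):
            row[f"noise_share_{key}"] = share
        row["origin_cell"] = self.origin_cell
        row["dest_cell"] = self.dest_cell
        return row


def intersect_itinerary(itinerary, grid: HexGrid) -> dict[int, float]:
    """Length of the itinerary traversed in each grid cell, in meters.

    Cells are processed in ascending cell_id order and each processed cell's
    portion is removed from the remaining line, so a segment lying exactly on
    a shared cell edge is counted once, for the lower cell_id.  Traversed
    lengths sum to the itinerary length; an itinerary leaving the grid extent
    raises :class:`OutOfExtentError`.
    """
    geom = itinerary.geometry
    total = geom.length
    if total == 0.0:
        return {}
    idx = np.sort(grid.tree().query(geom, predicate="intersects"))
    cell_ids = grid.cells["cell_id"].to_numpy()
    geoms = grid.geometries
    out: dict[int, float] = {}
    remaining = geom
    for i in idx:
        if remaining.is_empty:
            break
        part = remaining.intersection(geoms[i])
        length = part.length
        if length > 0.0:
            out[int(cell_ids[i])] = length
            remaining = remaining.difference(geoms[i])
    if remaining.length > _REL_TOL * total + 1e-9:
        raise OutOfExtentError(
            f"itinerary leaves the grid extent ({remaining.length:.3f} m uncovered)"
        )
    return out


def trip_features(itinerary, grid: HexGrid, scheme: NoiseScheme) -> TripRecord:
    """Summarise one itinerary into the trip feature vector.

    Means are unweighted over the distinct cells with positive traversed
    length; noise shares are traversed length per class divided by the total
    traversed length, hence an exact probability vector.  A zero-distance
    trip takes all attributes, and share 1, from its origin cell.
    """
    if (grid.cells["noise_class"] < 0).any():
        raise StateError("grid has no noise classes; run assign_noise first")
    n_classes = len(scheme)
    cells = grid.cells.set_index("cell_id")
    lengths = intersect_itinerary(itinerary, grid)
    origin_cell = grid.cell_at(itinerary.origin)
    dest_cell = grid.cell_at(itinerary.dest)

    share = np.zeros(n_classes)
    if not lengths:
        crossed = [origin_cell]
        share[int(cells.loc[origin_cell, "noise_class"])] = 1.0
        distance = 0.0
    else:
        crossed = sorted(lengths)
        total = float(sum(lengths.values()))
        for cid, length in lengths.items():
            share[int(cells.loc[cid, "noise_class"])] += length / total
        distance = itinerary.total_distance

    sub = cells.loc[crossed]
    return TripRecord(
        origin_cell=origin_cell,
        dest_cell=dest_cell,
        mode=itinerary.mode,
        distance=distance,
        mean_building_area=float(sub["building_area_m2"].mean()),
        mean_street_length=float(sub["street_length_m"].mean()),
        mean_poi={c: float(sub[f"poi_{c}"].mean()) for c in grid.categories},
        noise_share=share,
    )


def expand_flows(records: list[tuple[TripRecord, int]], scheme: NoiseScheme) -> pd.DataFrame:
    """Duplicate each trip record by its commuter count: one row per individual.

    Rows are identical within a flow except for a fresh ``individual_id``.
    """
    rows = []
    for rec, count in records:
        if count < 1:
            raise InvalidConfigError(f"flow count must be >= 1, got {count}")
        rows.append((rec.to_row(scheme), count))
    expanded = []
    for row, count in rows:
        expanded.extend([row] * count)
    table = pd.DataFrame(expanded)
    if len(table):
        table.insert(0, "individual_id", np.arange(len(table), dtype=np.int64))
    return table
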