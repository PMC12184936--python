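"""Hexagonal tessellation and per-cell aggregation of built-environment layers.

The spatial unit of the whole analysis is a regular, pointy-top hexagonal
cell of configurable area (default 25 ha).  Buildings, streets and points of
interest are overlaid onto the grid and summarised per cell; road-traffic
noise, supplied as a set of class polygons, is reduced to one ordinal class
per cell by majority area.

All coordinates are planar meters.  Geographic (lon/lat) input is out of
scope: densities and lengths are metric quantities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .errors import CoverageError, GeometryError, InvalidConfigError, OutOfExtentError

__all__ = [
    "NoiseClass",
    "NoiseScheme",
    "HexGrid",
    "SCHEMES",
    "get_scheme",
    "make_grid",
    "aggregate_buildings",
    "aggregate_streets",
    "count_pois",
    "assign_noise",
]

#: Six-way point-of-interest categorisation used for urban-function counts.
DEFAULT_POI_CATEGORIES = (
    "educational",
    "recreational",
    "medical",
    "public_services",
    "retail",
    "others",
)


@dataclass(frozen=True)
class NoiseClass:
    """One ordinal noise band: a display label, a column-safe key and dB bounds."""

    label: str
    key: str
    low_db: float
    high_db: float


@dataclass(frozen=True)
class NoiseScheme:
    """An ordered set of contiguous dB bands, ascending by loudness.

    Index 0 is the quietest class.  The built-in schemes mirror the two
    strategic noise maps the method was designed around: a six-class scheme
    (London-style, 16 h averages, open-ended below 55 dB and above 75 dB)
    and a five-class scheme (Brisbane-style, 18 h averages).
    """

    name: str
    classes: tuple[NoiseClass, ...]

    def __post_init__(self):
        n = len(self.classes)
        if not 2 <= n <= 10:
            raise InvalidConfigError(f"noise scheme needs 2..10 classes, got {n}")
        for a, b in zip(self.classes, self.classes[1:]):
            if a.high_db != b.low_db:
                raise InvalidConfigError(
                    f"scheme {self.name!r}: classes must be contiguous on the dB "
                    f"axis ({a.label} ends at {a.high_db}, {b.label} starts at {b.low_db})"
                )

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(c.key for c in self.classes)

    def share_columns(self) -> list[str]:
        return [f"noise_share_{k}" for k in self.keys]

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "classes": [
                    {"label": c.label, "key": c.key, "low_db": c.low_db, "high_db": c.high_db}
                    for c in self.classes
                ],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "NoiseScheme":
        doc = json.loads(text)
        return cls(
            name=doc["name"],
            classes=tuple(
                NoiseClass(c["label"], c["key"], float(c["low_db"]), float(c["high_db"]))
                for c in doc["classes"]
            ),
        )


_INF = float("inf")

# The London scheme is printed with a 54.9/55.0 gap between its two quietest
# bands; dB being continuous, the boundary is taken as 55.0 exactly.
SCHEMES: dict[str, NoiseScheme] = {
    "london6": NoiseScheme(
        "london6",
        (
            NoiseClass("<55.0 dB", "lt55", -_INF, 55.0),
            NoiseClass("55.0-59.9 dB", "55_60", 55.0, 60.0),
            NoiseClass("60.0-64.9 dB", "60_65", 60.0, 65.0),
            NoiseClass("65.0-69.9 dB", "65_70", 65.0, 70.0),
            NoiseClass("70.0-74.9 dB", "70_75", 70.0, 75.0),
            NoiseClass(">75.0 dB", "gt75", 75.0, _INF),
        ),
    ),
    "brisbane5": NoiseScheme(
        "brisbane5",
        (
            NoiseClass("<58 dB", "lt58", -_INF, 58.0),
            NoiseClass("58-63 dB", "58_63", 58.0, 63.0),
            NoiseClass("63-68 dB", "63_68", 63.0, 68.0),
            NoiseClass("68-73 dB", "68_73", 68.0, 73.0),
            NoiseClass(">73 dB", "gt73", 73.0, _INF),
        ),
    ),
}


def get_scheme(name: str) -> NoiseScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise InvalidConfigError(
            f"unknown noise scheme {name!r}; built-ins: {sorted(SCHEMES)}"
        ) from None


@dataclass
class HexGrid:
    """A congruent hexagonal tessellation with per-cell aggregates.

    ``cells`` holds one row per hexagon: ``cell_id`` (sequential, row-major),
    ``row``/``col`` lattice indices, the shapely polygon, accumulated
    ``building_area_m2`` and ``street_length_m``, one ``poi_<category>``
    count column per category and the ordinal ``noise_class`` (-1 until
    :func:`assign_noise` runs).
    """

    cells: pd.DataFrame
    cell_area: float
    edge_length: float
    bbox: tuple[float, float, float, float]
    categories: tuple[str, ...] = DEFAULT_POI_CATEGORIES
    scheme: NoiseScheme | None = None
    _tree: shapely.STRtree | None = field(default=None, repr=False, compare=False)

    def copy(self) -> "HexGrid":
        return replace(self, cells=self.cells.copy(), _tree=self._tree)

    @property
    def geometries(self) -> np.ndarray:
        return self.cells["geometry"].to_numpy()

    def tree(self) -> shapely.STRtree:
        # cells are stored in ascending cell_id order, so STRtree indices
        # coincide with positional cell order.
        if self._tree is None:
            self._tree = shapely.STRtree(self.geometries)
        return self._tree

    def cell_at(self, point) -> int:
        """cell_id containing a point; a point on a shared edge goes to the
        lowest cell_id."""
        pt = shapely.Point(point)
        idx = self.tree().query(pt, predicate="intersects")
        if len(idx) == 0:
            raise OutOfExtentError(f"point {tuple(point)} lies outside the grid extent")
        return int(self.cells["cell_id"].to_numpy()[idx].min())


def hexagon_edge_for_area(cell_area: float) -> float:
    """Edge length s of a regular hexagon with the given area, A = (3*sqrt(3)/2) s^2."""
    return math.sqrt(2.0 * cell_area / (3.0 * math.sqrt(3.0)))


def make_grid(
    bbox: tuple[float, float, float, float],
    cell_area: float = 250_000.0,
    categories: tuple[str, ...] = DEFAULT_POI_CATEGORIES,
) -> HexGrid:
    """Tessellate (and slightly overhang) ``bbox`` with congruent pointy-top hexagons.

    The grid keeps every cell whose interior overlaps the bbox, so the bbox is
    fully covered; cell ids are sequential in row-major (row, col) order and
    stable for a given bbox/cell_area.
    """
    if cell_area <= 0:
        raise InvalidConfigError(f"cell_area must be positive, got {cell_area}")
    xmin, ymin, xmax, ymax = map(float, bbox)
    if not (xmax > xmin and ymax > ymin):
        raise InvalidConfigError(f"bbox must have positive width and height: {bbox}")

    s = hexagon_edge_for_area(cell_area)
    w = math.sqrt(3.0) * s  # horizontal center spacing
    vs = 1.5 * s  # vertical center spacing
    half = math.sqrt(3.0) / 2.0 * s
    offsets = np.array(
        [
            (half, 0.5 * s),
            (0.0, s),
            (-half, 0.5 * s),
            (-half, -0.5 * s),
            (0.0, -s),
            (half, -0.5 * s),
        ]
    )

    r0 = math.floor((ymin - ymin) / vs) - 1
    r1 = math.ceil((ymax - ymin) / vs) + 1
    c0 = math.floor((xmin - xmin) / w) - 2
    c1 = math.ceil((xmax - xmin) / w) + 2
    clip = box(xmin, ymin, xmax, ymax)

    rows: list[tuple] = []
    for r in range(r0, r1 + 1):
        cy = ymin + vs * r
        stagger = 0.5 * w if (r % 2) else 0.0
        for c in range(c0, c1 + 1):
            cx = xmin + w * c + stagger
            verts = offsets + (cx, cy)
            poly = Polygon(verts)
            if poly.intersection(clip).area > 0.0:
                rows.append((r, c, poly))

    cells = pd.DataFrame(rows, columns=["row", "col", "geometry"])
    cells = cells.sort_values(["row", "col"], kind="mergesort").reset_index(drop=True)
    cells.insert(0, "cell_id", np.arange(len(cells), dtype=np.int64))
    cells["building_area_m2"] = 0.0
    cells["street_length_m"] = 0.0
    for cat in categories:
        cells[f"poi_{cat}"] = 0
    cells["noise_class"] = -1
    return HexGrid(
        cells=cells,
        cell_area=float(cell_area),
        edge_length=s,
        bbox=(xmin, ymin, xmax, ymax),
        categories=tuple(categories),
    )


def _validate_geoms(geoms: np.ndarray, kind: str) -> None:
    bad = np.nonzero(~shapely.is_valid(geoms))[0]
    if len(bad):
        raise GeometryError(f"invalid {kind} geometry at index {int(bad[0])}")


def _overlay_pairs(grid: HexGrid, geoms: np.ndarray):
    """(input index, cell position) pairs for all geometry/cell intersections."""
    li, ti = grid.tree().query(geoms, predicate="intersects")
    return li, ti


def aggregate_buildings(grid: HexGrid, buildings) -> HexGrid:
    """Accumulate clipped building areas into each cell.

    A building spanning several cells contributes each clipped part to its own
    cell, so total building area is conserved under gridding.
    """
    geoms = _as_geom_array(buildings)
    out = grid.copy()
    if len(geoms) == 0:
        return out
    _validate_geoms(geoms, "building")
    li, ti = _overlay_pairs(grid, geoms)
    if len(li):
        areas = shapely.area(shapely.intersection(geoms[li], grid.geometries[ti]))
        acc = np.zeros(len(out.cells))
        np.add.at(acc, ti, areas)
        out.cells["building_area_m2"] = out.cells["building_area_m2"].to_numpy() + acc
    return out


def aggregate_streets(grid: HexGrid, streets) -> HexGrid:
    """Accumulate clipped street lengths into each cell (length-conserving)."""
    geoms = _as_geom_array(streets)
    out = grid.copy()
    if len(geoms) == 0:
        return out
    _validate_geoms(geoms, "street")
    li, ti = _overlay_pairs(grid, geoms)
    if len(li):
        lengths = shapely.length(shapely.intersection(geoms[li], grid.geometries[ti]))
        acc = np.zeros(len(out.cells))
        np.add.at(acc, ti, lengths)
        out.cells["street_length_m"] = out.cells["street_length_m"].to_numpy() + acc
    return out


def count_pois(grid: HexGrid, pois: pd.DataFrame) -> HexGrid:
    """Accumulate per-category POI counts.

    ``pois`` needs a ``geometry`` (Point) and a ``category`` column.  A point
    lying exactly on a shared cell edge is assigned once, to the lowest
    cell_id, so totals are conserved.
    """
    out = grid.copy()
    if len(pois) == 0:
        return out
    unknown = set(pois["category"]) - set(grid.categories)
    if unknown:
        raise InvalidConfigError(
            f"unknown POI categories {sorted(unknown)}; configured: {list(grid.categories)}"
        )
    geoms = _as_geom_array(pois)
    li, ti = _overlay_pairs(grid, geoms)
    if len(li) == 0:
        return out
    pairs = pd.DataFrame({"poi": li, "cell_pos": ti})
    assigned = pairs.groupby("poi")["cell_pos"].min()  # edge points -> lowest cell_id
    cats = pois["category"].to_numpy()[assigned.index.to_numpy()]
    for cat in grid.categories:
        sel = assigned.to_numpy()[cats == cat]
        if len(sel):
            acc = np.zeros(len(out.cells), dtype=np.int64)
            np.add.at(acc, sel, 1)
            out.cells[f"poi_{cat}"] = out.cells[f"poi_{cat}"].to_numpy() + acc
    return out


#: relative area tie tolerance when two noise classes cover a cell equally
_TIE_RTOL = 1e-9


def assign_noise(grid: HexGrid, noise: pd.DataFrame, scheme: NoiseScheme) -> HexGrid:
    """Give each cell the noise class covering the majority of its area.

    Ties (within 1e-9 relative area) break toward the louder class — a
    conservative exposure choice.  Cells must be covered by the noise layer
    over at least 99% of their area inside the noise layer's bounding box;
    a larger gap raises :class:`CoverageError`.
    """
    out = grid.copy()
    geoms = _as_geom_array(noise)
    if len(geoms) == 0:
        raise CoverageError("empty noise layer")
    _validate_geoms(geoms, "noise")
    klass = noise["noise_class"].to_numpy(dtype=np.int64)
    if klass.min() < 0 or klass.max() >= len(scheme):
        raise InvalidConfigError(
            f"noise_class values must index scheme {scheme.name!r} (0..{len(scheme) - 1})"
        )

    n_cells = len(out.cells)
    cover = np.zeros((n_cells, len(scheme)))
    li, ti = _overlay_pairs(grid, geoms)
    if len(li):
        areas = shapely.area(shapely.intersection(geoms[li], grid.geometries[ti]))
        np.add.at(cover, (ti, klass[li]), areas)

    covered = cover.sum(axis=1)
    clip = box(*grid.bbox)
    expected = shapely.area(shapely.intersection(grid.geometries, clip))
    gap = covered < 0.99 * expected
    if gap.any():
        bad = int(out.cells["cell_id"].to_numpy()[np.nonzero(gap)[0][0]])
        raise CoverageError(
            f"noise layer covers <99% of cell {bad} within its extent"
        )

    best = cover.max(axis=1, keepdims=True)
    tied = cover >= best * (1.0 - _TIE_RTOL)
    # loudest among (near-)maximal classes: highest ordinal index
    chosen = (tied * np.arange(len(scheme))).max(axis=1)
    out.cells["noise_class"] = chosen.astype(np.int64)
    out.scheme = scheme
    return out


def _as_geom_array(obj) -> np.ndarray:
    """Accept a DataFrame with a geometry column, a sequence, or an ndarray."""
    if isinstance(obj, pd.DataFrame):
        return obj["geometry"].to_numpy()
    return np.asarray(list(obj), dtype=object)
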