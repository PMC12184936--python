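"""Mode-aware street graph and shortest-distance itineraries.

The routing criterion is distance (not time): downstream trip features are
distance-based, and per-mode speeds are out of scope.  Ties between
equal-length paths are broken toward the lexicographically smallest node-id
sequence, which makes itineraries reproducible across runs and platforms.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString

from .errors import EmptyNetworkError, InvalidConfigError, NoRouteError

__all__ = ["DEFAULT_MODE_RULES", "StreetNetwork", "Itinerary", "build_network", "shortest_itinerary"]

#: Which modes may use each street class.  All modes may use every class by
#: default (arterials carry sidewalks); restrictive rule sets can be passed
#: to :func:`build_network` to model e.g. pedestrian-free motorways.
DEFAULT_MODE_RULES = {
    "arterial": frozenset({"car", "bicycle", "walk"}),
    "local": frozenset({"car", "bicycle", "walk"}),
}

_SNAP = 1e-6  # endpoint snapping resolution, meters


@dataclass
class Itinerary:
    """A routed trip: OD endpoints, the edge sequence and its total length.

    ``total_distance`` includes the straight access/egress connectors from
    the OD points to their nearest mode-accessible nodes.
    """

    origin: tuple[float, float]
    dest: tuple[float, float]
    mode: str
    node_ids: list[int]
    edge_ids: list[int]
    geometry: LineString
    total_distance: float


@dataclass
class StreetNetwork:
    """An undirected street graph with per-edge allowed modes."""

    graph: nx.Graph  # nodes: int ids with pos=(x, y); edges: length, geometry, modes
    node_xy: np.ndarray  # (n, 2), indexed by node id
    _mode_cache: dict = field(default_factory=dict, repr=False)

    def mode_adjacency(self, mode: str):
        """Adjacency dict and KD-tree over nodes reachable by ``mode``."""
        if mode not in self._mode_cache:
            adj: dict[int, list] = {}
            for u, v, data in self.graph.edges(data=True):
                if mode in data["modes"]:
                    adj.setdefault(u, []).append((v, data["length"], (u, v)))
                    adj.setdefault(v, []).append((u, data["length"], (u, v)))
            for nbrs in adj.values():
                nbrs.sort()
            node_ids = np.array(sorted(adj), dtype=np.int64)
            tree = cKDTree(self.node_xy[node_ids]) if len(node_ids) else None
            self._mode_cache[mode] = (adj, node_ids, tree)
        return self._mode_cache[mode]

    def nearest_node(self, point, mode: str) -> int:
        adj, node_ids, tree = self.mode_adjacency(mode)
        if tree is None:
            raise NoRouteError(point, point, mode)
        d, i = tree.query(point)
        # on an exact distance tie prefer the lowest node id
        ties = tree.query_ball_point(point, r=d + 1e-9)
        return int(node_ids[min(ties)])


def build_network(streets, mode_rules: dict | None = None) -> StreetNetwork:
    """Node a street layer into a graph, one node per distinct endpoint.

    ``streets`` is a DataFrame with ``geometry`` (LineString) and
    ``street_class`` columns; segments are assumed noded at shared endpoints
    (the generator guarantees this).  Endpoint coordinates are snapped at
    1e-6 m; node ids are assigned in sorted coordinate order so they are
    stable for a given street set.
    """
    rules = {k: frozenset(v) for k, v in (mode_rules or DEFAULT_MODE_RULES).items()}
    if len(streets) == 0:
        raise EmptyNetworkError("cannot build a network from an empty street set")

    geoms = streets["geometry"].to_numpy()
    klasses = streets["street_class"].to_numpy()
    unknown = set(klasses) - set(rules)
    if unknown:
        raise InvalidConfigError(f"no mode rule for street classes {sorted(unknown)}")

    def snap(xy):
        return (round(xy[0] / _SNAP) * _SNAP, round(xy[1] / _SNAP) * _SNAP)

    endpoints = []
    for g in geoms:
        coords = list(g.coords)
        endpoints.append((snap(coords[0]), snap(coords[-1])))
    node_keys = sorted({p for pair in endpoints for p in pair})
    key_to_id = {k: i for i, k in enumerate(node_keys)}

    graph = nx.Graph()
    for k, i in key_to_id.items():
        graph.add_node(i, pos=k)
    for eid, (g, klass, (a, b)) in enumerate(zip(geoms, klasses, endpoints)):
        u, v = key_to_id[a], key_to_id[b]
        length = float(g.length)
        graph.add_edge(u, v, edge_id=eid, length=length, geometry=g,
                       street_class=klass, modes=rules[klass])
    node_xy = np.array(node_keys, dtype=float)
    return StreetNetwork(graph=graph, node_xy=node_xy)


def _lex_dijkstra(adj, src: int, dst: int):
    """Shortest path by length with lexicographic node-id tie-breaking.

    The priority is (length, node-id path); appending an edge increases the
    key monotonically, so the first settlement of a node carries the minimal
    key — the shortest path, and among equal-length paths the one with the
    lexicographically smallest id sequence.
    """
    heap = [(0.0, (src,))]
    settled = set()
    while heap:
        d, path = heapq.heappop(heap)
        u = path[-1]
        if u == dst:
            return d, list(path)
        if u in settled:
            continue
        settled.add(u)
        for v, w, _edge in adj.get(u, ()):
            if v not in settled:
                heapq.heappush(heap, (d + w, path + (v,)))
    return None


def shortest_itinerary(net: StreetNetwork, origin, dest, mode: str) -> Itinerary:
    """Minimum-length itinerary on the mode subgraph, with straight
    access/egress connectors included in the total distance.

    Raises :class:`NoRouteError` when origin and destination fall in
    different components of the mode subgraph.
    """
    origin = (float(origin[0]), float(origin[1]))
    dest = (float(dest[0]), float(dest[1]))
    adj, _ids, _tree = net.mode_adjacency(mode)
    src = net.nearest_node(origin, mode)
    dst = net.nearest_node(dest, mode)

    if src == dst:
        node_path, net_len = [src], 0.0
        coords = [origin, tuple(net.node_xy[src]), dest]
        edge_ids: list[int] = []
    else:
        found = _lex_dijkstra(adj, src, dst)
        if found is None:
            raise NoRouteError(origin, dest, mode)
        net_len, node_path = found
        coords = [origin]
        edge_ids = []
        for u, v in zip(node_path, node_path[1:]):
            data = net.graph.edges[u, v]
            edge_ids.append(data["edge_id"])
            seg = list(data["geometry"].coords)
            ux, uy = net.node_xy[u]
            if (seg[0][0] - ux) ** 2 + (seg[0][1] - uy) ** 2 > (
                seg[-1][0] - ux
            ) ** 2 + (seg[-1][1] - uy) ** 2:
                seg = seg[::-1]
            coords.extend(seg if u == node_path[0] else seg[1:])
        coords.append(dest)

    entry = float(np.hypot(origin[0] - net.node_xy[src][0], origin[1] - net.node_xy[src][1]))
    exit_ = float(np.hypot(dest[0] - net.node_xy[dst][0], dest[1] - net.node_xy[dst][1]))
    # drop zero-length connector vertices so the geometry stays simple
    clean = [coords[0]]
    for c in coords[1:]:
        if c != clean[-1]:
            clean.append(c)
    if len(clean) == 1:
        geom = LineString([clean[0], clean[0]])
    else:
        geom = LineString(clean)
    return Itinerary(
        origin=origin,
        dest=dest,
        mode=mode,
        node_ids=node_path,
        edge_ids=edge_ids,
        geometry=geom,
        total_distance=entry + net_len + exit_,
    )
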