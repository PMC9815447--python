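"""Road graph construction, point snapping, and origin-destination distances.

The road network is an undirected graph with node positions in projected
meters and edge weights equal to segment length.  Unit centers and the
facility are snapped to their nearest graph node; the OD matrix holds the
shortest-path (Dijkstra) distance from every unit to the facility, with the
two snap gaps optionally added as straight-line connectors (default on —
real population centers rarely sit exactly on a road).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .exceptions import DistcostError, UnreachableError, ValidationError
from .region_model import Coord, Facility, Region

logger = logging.getLogger(__name__)

#: nodes closer than this (meters) are merged into one when building a graph
DEFAULT_MERGE_TOL = 0.5
#: snapping a point farther than this (meters) from the network logs a warning
DEFAULT_SNAP_WARN = 1000.0


class RoadGraph:
    """Undirected weighted road graph.

    Parameters
    ----------
    nodes
        Mapping node_id -> (x, y) in meters.
    edges
        Iterable of (node_a, node_b, length_m); lengths must be positive and
        endpoints must exist in ``nodes``.
    """

    def __init__(
        self,
        nodes: Mapping[str, Coord],
        edges: Iterable[tuple[str, str, float]],
    ):
        g = nx.Graph()
        for nid, (x, y) in nodes.items():
            g.add_node(nid, x=float(x), y=float(y))
        for a, b, length in edges:
            if a not in g or b not in g:
                raise ValidationError(f"edge ({a!r}, {b!r}) references unknown node")
            if not length > 0:
                raise ValidationError(
                    f"edge ({a!r}, {b!r}) has non-positive length {length}"
                )
            # parallel roads between the same nodes: keep the shorter one
            if g.has_edge(a, b):
                g[a][b]["length"] = min(g[a][b]["length"], float(length))
            else:
                g.add_edge(a, b, length=float(length))
        self._g = g
        self._kdtree: cKDTree | None = None
        self._kd_ids: list[str] = []

    # -- introspection -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> dict[str, Coord]:
        return {n: (d["x"], d["y"]) for n, d in self._g.nodes(data=True)}

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["length"]) for a, b, d in self._g.edges(data=True)]

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self._g)

    # -- snapping ------------------------------------------------------
    def _tree(self) -> cKDTree:
        if self._kdtree is None:
            self._kd_ids = list(self._g.nodes)
            pts = np.array(
                [[self._g.nodes[n]["x"], self._g.nodes[n]["y"]] for n in self._kd_ids]
            )
            self._kdtree = cKDTree(pts)
        return self._kdtree

    def nearest_node(self, point: Coord) -> tuple[str, float]:
        """Nearest graph node to ``point`` and the Euclidean gap to it.

        Equidistant candidates are broken by lexicographically smallest
        node_id, so the result does not depend on insertion order.
        """
        if self.n_nodes == 0:
            raise DistcostError("cannot snap to an empty graph")
        tree = self._tree()
        d0, i0 = tree.query(point)
        eps = 1e-9 * max(1.0, d0)
        cands = tree.query_ball_point(point, d0 + eps)
        best = min(self._kd_ids[i] for i in cands) if len(cands) > 1 else self._kd_ids[i0]
        return best, float(d0)


def build_graph(
    road_lines: Iterable[list[Coord]],
    merge_tol: float = DEFAULT_MERGE_TOL,
) -> RoadGraph:
    """Build a :class:`RoadGraph` from polylines in projected meters.

    Consecutive vertices of each polyline become edges weighted by Euclidean
    segment length.  Endpoints closer than ``merge_tol`` share a node: node
    ids are derived from coordinates quantized to the tolerance grid, which
    also makes the graph invariant to the order of the input lines.
    """
    lines = [list(line) for line in road_lines]
    if not lines or all(len(ln) < 2 for ln in lines):
        raise ValidationError("no road segments in input")

    def node_id(p: Coord) -> str:
        qx = round(p[0] / merge_tol)
        qy = round(p[1] / merge_tol)
        return f"n{qx}:{qy}"

    nodes: dict[str, Coord] = {}
    edges: list[tuple[str, str, float]] = []
    for line in lines:
        for p, q in zip(line, line[1:]):
            a, b = node_id(p), node_id(q)
            nodes.setdefault(a, (float(p[0]), float(p[1])))
            nodes.setdefault(b, (float(q[0]), float(q[1])))
            if a == b:
                continue  # degenerate segment below merge tolerance
            length = math.hypot(q[0] - p[0], q[1] - p[1])
            edges.append((a, b, length))
    return RoadGraph(nodes, edges)


def snap(
    point: Coord, graph: RoadGraph, warn_threshold: float = DEFAULT_SNAP_WARN
) -> tuple[str, float]:
    """Snap a point to its nearest network node; returns (node_id, gap_m)."""
    node, gap = graph.nearest_node(point)
    if gap > warn_threshold:
        logger.warning(
            "snap gap %.1f m exceeds %.0f m threshold (point %s -> node %s)",
            gap, warn_threshold, point, node,
        )
    return node, gap


def network_distance(origin_node: str, dest_node: str, graph: RoadGraph) -> float:
    """Shortest-path length in meters between two graph nodes.

    Returns ``math.inf`` when the nodes are disconnected — never a silent 0.
    """
    g = graph.graph
    if origin_node not in g or dest_node not in g:
        raise ValidationError(
            f"node not in graph: {origin_node!r} or {dest_node!r}"
        )
    if origin_node == dest_node:
        return 0.0
    try:
        return float(nx.dijkstra_path_length(g, origin_node, dest_node, weight="length"))
    except nx.NetworkXNoPath:
        return math.inf


@dataclass
class ODMatrix:
    """Origin-destination distances: every unit center to one facility.

    ``entries`` maps (unit_id, facility_id) -> distance in meters;
    ``snap_report`` records each unit's snap gap, ``facility_snap`` the
    facility's.  With connectors included, the distance is
    snap_gap(center) + network shortest path + snap_gap(facility).
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    snap_report: dict[str, float] = field(default_factory=dict)
    facility_snap: float = 0.0
    include_connectors: bool = True

    def distance(self, unit_id: str, facility_id: str) -> float:
        return self.entries[(unit_id, facility_id)]

    def unit_distances(self, facility_id: str) -> dict[str, float]:
        return {u: d for (u, f), d in self.entries.items() if f == facility_id}


def euclidean_od_matrix(region: Region, facility: Facility) -> ODMatrix:
    """Straight-line fallback engine: Euclidean center-to-facility distances.

    Useful for testing and for near-linear corridors where one road carries
    all traffic; never the default, since it ignores the network entirely.
    """
    fx, fy = facility.location
    od = ODMatrix(include_connectors=False)
    for u in region.units:
        if u.center is None:
            raise ValidationError(f"unit {u.unit_id!r} has no center")
        cx, cy = u.center
        od.entries[(u.unit_id, facility.facility_id)] = math.hypot(cx - fx, cy - fy)
        od.snap_report[u.unit_id] = 0.0
    return od


def od_matrix(
    region: Region,
    facility: Facility,
    graph: RoadGraph,
    include_connectors: bool = True,
    snap_warn_threshold: float = DEFAULT_SNAP_WARN,
) -> ODMatrix:
    """Distances from every unit center in ``region`` to ``facility``.

    Runs one single-source Dijkstra from the facility's snapped node, so the
    cost is O(E log V) regardless of the number of units.  Units with no
    path to the facility raise :class:`UnreachableError` listing their ids.
    """
    fac_node, fac_gap = snap(facility.location, graph, snap_warn_threshold)
    dist_from_fac = nx.single_source_dijkstra_path_length(
        graph.graph, fac_node, weight="length"
    )
    od = ODMatrix(include_connectors=include_connectors, facility_snap=fac_gap)
    unreachable: list[str] = []
    for u in region.units:
        if u.center is None:
            raise ValidationError(f"unit {u.unit_id!r} has no center")
        node, gap = snap(u.center, graph, snap_warn_threshold)
        od.snap_report[u.unit_id] = gap
        base = dist_from_fac.get(node)
        if base is None:
            unreachable.append(u.unit_id)
            continue
        d = base + (gap + fac_gap if include_connectors else 0.0)
        od.entries[(u.unit_id, facility.facility_id)] = d
    if unreachable:
        raise UnreachableError(
            f"{len(unreachable)} unit(s) cannot reach facility "
            f"{facility.facility_id!r}: {unreachable[:10]}",
            unit_ids=unreachable,
        )
    return od
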