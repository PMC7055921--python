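"""Circumradius-filtered Delaunay neighborhood graphs.

The core construction: a Delaunay triangulation over all cell coordinates
(phenotype-blind), then an alpha-complex-style filter — every side of a
triangle whose circumcircle radius is smaller than a cutoff ``t`` becomes a
graph edge.  Connected components of the filtered graph are the candidate
infiltrates.  The cutoff plays the role of the pathologist's visual grouping
distance; at 0.253 μm/px the default 45 px corresponds to ~11.4 μm between
cell centres.

An edge survives if ANY incident triangle qualifies (boundary edges have a
single incident triangle); the inequality is strict (radius < t).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .cells import CellMap, CellRecord

logger = logging.getLogger(__name__)

#: Default circumradius cutoff in pixels at the default resolution.
DEFAULT_THRESHOLD_PX = 45.0
#: The physical cutoff the default preserves across resolutions (μm).
DEFAULT_THRESHOLD_UM = 11.385
#: Components smaller than this are not reported as infiltrates.
DEFAULT_MIN_NODES = 10

#: Relative zero-area tolerance for degenerate (collinear) triangles.
_AREA_RTOL = 1e-12


class DegeneratePointSetError(ValueError):
    """Fewer than 3 cells, or all cells collinear: no triangulation exists."""


@dataclass(frozen=True)
class TriangleRecord:
    """One Delaunay triangle with its circumcircle radius in pixels."""

    vertex_ids: tuple[str, str, str]
    circumradius_px: float


@dataclass
class NeighborhoodGraph:
    """A (possibly filtered) cell graph.

    ``graph`` is an undirected networkx graph whose nodes are cell_ids with
    attributes ``x``, ``y``, ``phenotype`` and whose edges may carry a
    ``label`` attribute ("alpha" or an integer gamma index) once labelled.
    """

    graph: nx.Graph
    threshold_px: float
    designated_type_a: str = "B"
    roi_id: str = ""

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def phenotype_of(self, node) -> str:
        return self.graph.nodes[node]["phenotype"]

    def coordinates(self) -> np.ndarray:
        return np.array(
            [(d["x"], d["y"]) for _, d in self.graph.nodes(data=True)], dtype=float
        )


@dataclass
class InfiltrateGraph(NeighborhoodGraph):
    """One connected component of a filtered graph = one infiltrate."""

    infiltrate_id: str = ""
    # filtered triangles restricted to this component, for hull drawing
    triangles: list[TriangleRecord] = field(default_factory=list)


def circumradius(p1: Sequence[float], p2: Sequence[float], p3: Sequence[float]) -> float:
    """Circumcircle radius of a triangle, ``R = abc / (4 * area)``.

    Returns +inf for (near-)collinear points: a triangle whose doubled area
    falls below ``1e-12`` of the squared longest side never passes any
    radius cutoff.
    """
    (x1, y1), (x2, y2), (x3, y3) = (p1[0], p1[1]), (p2[0], p2[1]), (p3[0], p3[1])
    a = math.hypot(x2 - x3, y2 - y3)
    b = math.hypot(x1 - x3, y1 - y3)
    c = math.hypot(x1 - x2, y1 - y2)
    cross = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
    area = abs(cross) / 2.0
    longest_sq = max(a, b, c) ** 2
    if area <= _AREA_RTOL * longest_sq or longest_sq == 0.0:
        return math.inf
    return a * b * c / (4.0 * area)


def build_delaunay(cell_map: CellMap) -> list[TriangleRecord]:
    """Delaunay triangles over all cell coordinates, with circumradii.

    Phenotype-blind by design: the triangulation sees only positions.
    Raises :class:`DegeneratePointSetError` for < 3 cells or a collinear
    point set.
    """
    cells = cell_map.cells
    if len(cells) < 3:
        raise DegeneratePointSetError(
            f"ROI {cell_map.roi_id}: degenerate point set ({len(cells)} cells)"
        )
    pts = np.array([(c.x, c.y) for c in cells], dtype=float)
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegeneratePointSetError(
            f"ROI {cell_map.roi_id}: degenerate point set (collinear cells)"
        ) from exc
    records = []
    for simplex in tri.simplices:
        i, j, k = (int(v) for v in simplex)
        r = circumradius(pts[i], pts[j], pts[k])
        records.append(
            TriangleRecord(
                vertex_ids=(cells[i].cell_id, cells[j].cell_id, cells[k].cell_id),
                circumradius_px=r,
            )
        )
    return records


def _filtered_graph(
    cell_map: CellMap,
    triangles: Iterable[TriangleRecord],
    threshold_px: float,
) -> nx.Graph:
    """Union of the sides of all triangles with circumradius < t."""
    g = nx.Graph()
    for c in cell_map.cells:
        g.add_node(c.cell_id, x=c.x, y=c.y, phenotype=c.phenotype)
    for t in triangles:
        if t.circumradius_px < threshold_px:
            a, b, c = t.vertex_ids
            g.add_edge(a, b)
            g.add_edge(b, c)
            g.add_edge(a, c)
    return g


def build_neighborhood_graphs(
    cell_map: CellMap,
    threshold_px: float = DEFAULT_THRESHOLD_PX,
    min_nodes: int = DEFAULT_MIN_NODES,
    designated_type_a: str = "B",
) -> list[InfiltrateGraph]:
    """Build the filtered Delaunay graph and split it into infiltrates.

    Every connected component with at least ``min_nodes`` cells becomes an
    :class:`InfiltrateGraph` with α/γ edge labels assigned; smaller
    components are discarded (counted in a log line).  A degenerate point
    set yields an empty list with a warning rather than an error.
    """
    if threshold_px < 0:
        raise ValueError("threshold_px must be >= 0")
    if min_nodes < 1:
        raise ValueError("min_nodes must be >= 1")
    try:
        triangles = build_delaunay(cell_map)
    except DegeneratePointSetError as exc:
        logger.warning("%s; emitting no infiltrates", exc)
        return []
    g = _filtered_graph(cell_map, triangles, threshold_px)
    # strip isolated nodes: only cells joined by a qualifying triangle side
    # belong to an infiltrate
    g.remove_nodes_from([n for n in g.nodes if g.degree[n] == 0])

    from .features import label_edges  # deferred: features imports our types

    infiltrates: list[InfiltrateGraph] = []
    n_discarded = 0
    components = sorted(nx.connected_components(g), key=min)
    for idx, comp in enumerate(components):
        if len(comp) < min_nodes:
            n_discarded += 1
            continue
        sub = g.subgraph(comp).copy()
        comp_tris = [
            t
            for t in triangles
            if t.circumradius_px < threshold_px and all(v in comp for v in t.vertex_ids)
        ]
        infiltrate = InfiltrateGraph(
            graph=sub,
            threshold_px=threshold_px,
            designated_type_a=designated_type_a,
            roi_id=cell_map.roi_id,
            infiltrate_id=f"{cell_map.roi_id}.{len(infiltrates)}",
            triangles=comp_tris,
        )
        label_edges(infiltrate, designated_type_a)
        infiltrates.append(infiltrate)
    logger.info(
        "ROI %s: %d infiltrate(s) at t=%g px; %d component(s) below %d nodes discarded",
        cell_map.roi_id,
        len(infiltrates),
        threshold_px,
        n_discarded,
        min_nodes,
    )
    return infiltrates


def split_compartments(infiltrate: InfiltrateGraph) -> list[set]:
    """Single-phenotype compartments of one infiltrate.

    Drops all inter-phenotype edges and returns the connected components of
    what remains, keeping only components of ≥ 3 cells: single cells and
    cell pairs do not span a compartment.
    """
    g = infiltrate.graph
    mono = nx.Graph()
    mono.add_nodes_from(g.nodes(data=True))
    for u, v in g.edges:
        if g.nodes[u]["phenotype"] == g.nodes[v]["phenotype"]:
            mono.add_edge(u, v)
    return [comp for comp in nx.connected_components(mono) if len(comp) >= 3]


def concave_hull(points: np.ndarray, alpha_px: float) -> Polygon | None:
    """Alpha-shape outline of a point set.

    Unions all Delaunay triangles whose circumradius is below ``alpha_px``;
    the boundary of that union is the concave hull.  Returns None for fewer
    than 3 points, a degenerate set, or when no triangle qualifies.  Using
    the same radius scale that defined graph connectivity keeps hull and
    graph mutually consistent.
    """
    if alpha_px <= 0:
        raise ValueError("alpha_px must be positive")
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return None
    try:
        tri = Delaunay(pts)
    except QhullError:
        return None
    polys = []
    for simplex in tri.simplices:
        p = pts[simplex]
        if circumradius(p[0], p[1], p[2]) < alpha_px:
            polys.append(Polygon(p))
    if not polys:
        return None
    merged = unary_union(polys)
    if merged.is_empty or merged.geom_type not in ("Polygon", "MultiPolygon"):
        return None
    if merged.geom_type == "MultiPolygon":
        # keep the largest piece: one infiltrate, one outline
        merged = max(merged.geoms, key=lambda p: p.area)
    return merged


def infiltrate_hull(infiltrate: InfiltrateGraph) -> Polygon | None:
    """Concave hull of an infiltrate from its own filtered triangles."""
    node_xy = {n: (d["x"], d["y"]) for n, d in infiltrate.graph.nodes(data=True)}
    polys = [
        Polygon([node_xy[v] for v in t.vertex_ids])
        for t in infiltrate.triangles
        if t.circumradius_px < infiltrate.threshold_px
    ]
    if not polys:
        pts = infiltrate.coordinates()
        return concave_hull(pts, infiltrate.threshold_px)
    merged = unary_union(polys)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda p: p.area)
    return merged
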