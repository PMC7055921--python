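"""Calibration of the circumradius cutoff t from pathologist annotations.

An annotated infiltrate outline is treated as ground truth for
connectivity: at a good cutoff, the filtered graph restricted to the cells
inside one outline forms a single connected component.  The calibrated t is
the smallest candidate for which (a configurable fraction of) the
annotations are not fragmented.  Edges to cells outside an outline are
ignored when scoring it — connectivity is judged inside the pathologist's
cluster only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely.geometry import Point, Polygon

from .cells import CellMap, CellRecord
from .graphs import build_delaunay

logger = logging.getLogger(__name__)

#: Default candidate grid: 5..100 px in steps of 5.
DEFAULT_T_GRID = tuple(float(t) for t in range(5, 105, 5))


class BadAnnotationError(ValueError):
    """Annotation polygon is degenerate or self-intersecting."""


class NoGroundTruthError(ValueError):
    """No annotation encloses at least two cells; nothing to calibrate on."""


@dataclass
class AnnotationPolygon:
    """A pathologist-drawn infiltrate outline in pixel coordinates."""

    annotation_id: str
    roi_id: str
    vertices: list[tuple[float, float]]
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise BadAnnotationError(
                f"annotation {self.annotation_id!r}: fewer than 3 vertices"
            )
        if not self.shapely().is_valid:
            raise BadAnnotationError(
                f"annotation {self.annotation_id!r}: self-intersecting polygon"
            )

    def shapely(self) -> Polygon:
        return Polygon(self.vertices)


def cells_in_polygon(cell_map: CellMap, polygon: AnnotationPolygon) -> list[CellRecord]:
    """Cells inside or on the boundary of the annotation outline."""
    poly = polygon.shapely()
    return [c for c in cell_map.cells if poly.covers(Point(c.x, c.y))]


def edge_birth_radii(cell_map: CellMap) -> dict[tuple[str, str], float]:
    """For every Delaunay edge, the smallest circumradius among its
    incident triangles — the edge appears in the filtered graph exactly for
    cutoffs t above this value (strictly)."""
    birth: dict[tuple[str, str], float] = {}
    for tri in build_delaunay(cell_map):
        a, b, c = tri.vertex_ids
        for u, v in ((a, b), (b, c), (a, c)):
            key = (u, v) if u < v else (v, u)
            prev = birth.get(key, math.inf)
            if tri.circumradius_px < prev:
                birth[key] = tri.circumradius_px
    return birth


def fragmentation_at(
    cell_map: CellMap,
    annotations: list[AnnotationPolygon],
    threshold_px: float,
    _birth: dict[tuple[str, str], float] | None = None,
) -> dict[str, int | str]:
    """Connected-component count of the induced subgraph inside each
    annotation at cutoff t.  Annotations enclosing < 2 cells map to the
    string ``"empty"`` and are excluded from calibration scoring."""
    birth = edge_birth_radii(cell_map) if _birth is None else _birth
    result: dict[str, int | str] = {}
    for ann in annotations:
        inside = {c.cell_id for c in cells_in_polygon(cell_map, ann)}
        if len(inside) < 2:
            result[ann.annotation_id] = "empty"
            continue
        g = nx.Graph()
        g.add_nodes_from(inside)
        for (u, v), r in birth.items():
            if r < threshold_px and u in inside and v in inside:
                g.add_edge(u, v)
        result[ann.annotation_id] = nx.number_connected_components(g)
    return result


@dataclass
class CalibrationReport:
    t_grid: list[float]
    fraction_connected: list[float]
    chosen_t: float
    best_approximation: bool
    median_kept_edge_um: float | None
    median_removed_edge_um: float | None
    n_annotations_scored: int
    n_annotations_empty: int
    per_annotation_components: dict[float, dict[str, int | str]] = field(
        default_factory=dict
    )

    def as_dict(self) -> dict:
        return {
            "t_grid": self.t_grid,
            "fraction_connected": self.fraction_connected,
            "chosen_t": self.chosen_t,
            "best_approximation": self.best_approximation,
            "median_kept_edge_um": self.median_kept_edge_um,
            "median_removed_edge_um": self.median_removed_edge_um,
            "n_annotations_scored": self.n_annotations_scored,
            "n_annotations_empty": self.n_annotations_empty,
        }


def _edge_length_um(cell_map: CellMap) -> dict[tuple[str, str], float]:
    xy = {c.cell_id: (c.x, c.y) for c in cell_map.cells}
    res = cell_map.resolution_um_per_px

    def length(u: str, v: str) -> float:
        (x1, y1), (x2, y2) = xy[u], xy[v]
        return math.hypot(x2 - x1, y2 - y1) * res

    return {key: length(*key) for key in edge_birth_radii(cell_map)}


def calibrate_threshold(
    cell_maps: list[CellMap],
    annotations: list[AnnotationPolygon],
    t_grid: tuple[float, ...] = DEFAULT_T_GRID,
    target_fraction: float = 1.0,
) -> CalibrationReport:
    """Choose the smallest cutoff that keeps annotated infiltrates connected.

    For each candidate t, the non-fragmentation fraction is the share of
    scorable annotations (≥ 2 enclosed cells) whose induced subgraph has a
    single component.  ``chosen_t`` is the smallest grid value reaching
    ``target_fraction`` (default 1.0); if none does, the maximizing grid
    value is returned with ``best_approximation`` set.  Kept/removed
    Delaunay-edge length medians at the chosen t are reported in μm.
    """
    if not t_grid:
        raise ValueError("empty t_grid")
    t_grid = tuple(sorted(t_grid))
    if not (0.0 < target_fraction <= 1.0):
        raise ValueError("target_fraction must be in (0, 1]")

    by_roi = {cm.roi_id: cm for cm in cell_maps}
    births = {cm.roi_id: edge_birth_radii(cm) for cm in cell_maps}

    fractions: list[float] = []
    per_t: dict[float, dict[str, int | str]] = {}
    n_scored = n_empty = 0
    for t in t_grid:
        counts: dict[str, int | str] = {}
        n_ok = n_tot = 0
        for ann in annotations:
            cm = by_roi.get(ann.roi_id)
            if cm is None:
                continue
            res = fragmentation_at(cm, [ann], t, _birth=births[cm.roi_id])
            counts.update(res)
            val = res[ann.annotation_id]
            if val == "empty":
                continue
            n_tot += 1
            if val == 1:
                n_ok += 1
        per_t[t] = counts
        if n_tot == 0:
            raise NoGroundTruthError("no annotation encloses at least 2 cells")
        fractions.append(n_ok / n_tot)
        n_scored = n_tot
        n_empty = sum(1 for v in counts.values() if v == "empty")

    best_approx = False
    chosen = None
    for t, frac in zip(t_grid, fractions):
        if frac >= target_fraction:
            chosen = t
            break
    if chosen is None:
        chosen = t_grid[int(np.argmax(fractions))]
        best_approx = True
        logger.warning(
            "no grid value reached target fraction %.3f; best approximation t=%g",
            target_fraction,
            chosen,
        )

    kept: list[float] = []
    removed: list[float] = []
    for cm in cell_maps:
        lengths = _edge_length_um(cm)
        for key, r in births[cm.roi_id].items():
            (kept if r < chosen else removed).append(lengths[key])
    return CalibrationReport(
        t_grid=list(t_grid),
        fraction_connected=fractions,
        chosen_t=chosen,
        best_approximation=best_approx,
        median_kept_edge_um=float(np.median(kept)) if kept else None,
        median_removed_edge_um=float(np.median(removed)) if removed else None,
        n_annotations_scored=n_scored,
        n_annotations_empty=n_empty,
        per_annotation_components=per_t,
    )
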