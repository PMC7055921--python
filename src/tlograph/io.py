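"""Readers and writers for the pipeline's file formats, run configuration,
and the density-map ROI selector.

Formats: the cell table CSV (``cell_id,x_px,y_px,phenotype``), GeoJSON
FeatureCollections for annotations and hulls (pixel coordinates, same frame
as the cell table), the per-infiltrate feature CSV, and a TOML run config.
Every tabular output starts with a ``# config:`` comment embedding the
resolved run configuration so results are traceable and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box, mapping
from shapely.ops import unary_union

from .calibration import AnnotationPolygon
from .cells import (
    DEFAULT_PHENOTYPES,
    DEFAULT_RESOLUTION_UM_PER_PX,
    CellMap,
    CellRecord,
)
from .features import FeatureVector
from .graphs import DEFAULT_MIN_NODES, DEFAULT_THRESHOLD_UM

logger = logging.getLogger(__name__)

CELL_TABLE_COLUMNS = ("cell_id", "x_px", "y_px", "phenotype")

FEATURE_CSV_COLUMNS = (
    "roi_id",
    "infiltrate_id",
    "n_nodes",
    "frac_B",
    "n_edges",
    "n_alpha",
    "frac_alpha_B",
    "homogeneity",
    "kappa_2",
    "kappa_5",
    "clustering_C",
    "avg_degree",
    "mean_pairwise_dist_um",
)


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run.

    ``threshold_px`` defaults to the physical cutoff (11.385 μm) converted
    at the configured resolution, i.e. 45 px at 0.253 μm/px; supplying a
    different resolution preserves the cutoff in micrometres.
    """

    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX
    threshold_px: float | None = None
    min_nodes: int = DEFAULT_MIN_NODES
    designated_type_a: str = "B"
    kappa_orders: tuple[int, ...] = (2, 5)
    svm_c: float = 1.0
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution_um_per_px must be positive")
        if self.threshold_px is None:
            self.threshold_px = DEFAULT_THRESHOLD_UM / self.resolution_um_per_px
        if self.threshold_px < 0 or self.min_nodes < 1 or self.k_folds < 2:
            raise ValueError("invalid RunConfig values")
        self.kappa_orders = tuple(int(a) for a in self.kappa_orders)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kappa_orders"] = list(self.kappa_orders)
        return d

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def read_cell_table(path: str | Path, roi_id: str | None = None) -> CellMap:
    """Load and validate a cell table CSV into a CellMap.

    Fails with the offending row number on a missing column, a non-numeric
    coordinate, or a phenotype outside the registry.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    cells = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            x, y = float(row.x_px), float(row.y_px)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path.name} row {idx}: non-numeric coordinate") from exc
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValueError(f"{path.name} row {idx}: non-finite coordinate")
        if row.phenotype not in DEFAULT_PHENOTYPES:
            raise ValueError(
                f"{path.name} row {idx}: unknown phenotype {row.phenotype!r}"
            )
        cells.append(
            CellRecord(cell_id=str(row.cell_id), x=x, y=y, phenotype=str(row.phenotype))
        )
    cm = CellMap(roi_id=roi_id or path.stem, cells=cells)
    logger.info("ROI %s: read %d cell(s) from %s", cm.roi_id, len(cm), path)
    return cm


def write_cell_table(cell_map: CellMap, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cell_map.cells],
            "x_px": [c.x for c in cell_map.cells],
            "y_px": [c.y for c in cell_map.cells],
            "phenotype": [c.phenotype for c in cell_map.cells],
        }
    )
    df.to_csv(path, index=False)


def read_annotations(path: str | Path, roi_id: str | None = None) -> list[AnnotationPolygon]:
    """GeoJSON FeatureCollection of Polygons -> annotation outlines."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path.name}: expected a GeoJSON FeatureCollection")
    out = []
    for i, feat in enumerate(data.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise ValueError(f"{path.name} feature {i}: expected Polygon geometry")
        ring = [tuple(map(float, pt)) for pt in geom["coordinates"][0]]
        if len(ring) > 1 and ring[0] == ring[-1]:
            ring = ring[:-1]  # GeoJSON rings repeat the first vertex
        props = feat.get("properties") or {}
        out.append(
            AnnotationPolygon(
                annotation_id=str(props.get("annotation_id", f"{path.stem}_{i}")),
                roi_id=str(props.get("roi_id", roi_id or path.stem)),
                vertices=ring,
                label=props.get("label"),
            )
        )
    return out


def write_polygons_geojson(
    polygons: list[Polygon], properties: list[dict], path: str | Path
) -> None:
    """Write polygons (hulls, compartments, ROIs) as a FeatureCollection."""
    features = [
        {"type": "Feature", "geometry": mapping(poly), "properties": props}
        for poly, props in zip(polygons, properties)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def features_to_dataframe(vectors: list[FeatureVector]) -> pd.DataFrame:
    rows = [v.as_row() for v in vectors]
    df = pd.DataFrame(rows, columns=list(FEATURE_CSV_COLUMNS))
    return df


def write_feature_csv(
    vectors: list[FeatureVector], path: str | Path, config: RunConfig | None = None
) -> None:
    df = features_to_dataframe(vectors)
    _write_csv_with_config(df, path, config)


def write_degree_csv(
    vectors: list[FeatureVector], path: str | Path, config: RunConfig | None = None
) -> None:
    rows = [
        {"infiltrate_id": v.infiltrate_id, "k": k, "P_k": p}
        for v in vectors
        for k, p in sorted(v.degree_distribution.items())
    ]
    df = pd.DataFrame(rows, columns=["infiltrate_id", "k", "P_k"])
    _write_csv_with_config(df, path, config)


def _write_csv_with_config(df: pd.DataFrame, path: str | Path, config: RunConfig | None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config is not None:
            fh.write(f"# config: {json.dumps(config.as_dict(), sort_keys=True)}\n")
        df.to_csv(fh, index=False)


def density_roi_selection(
    cell_map: CellMap, bin_px: float, min_count: int
) -> tuple[list[Polygon], np.ndarray]:
    """Propose ROIs from a lymphocyte density map.

    The slide extent is tiled with square bins of ``bin_px``; bins holding
    at least ``min_count`` cells are merged (adjacent bins union) into
    rectilinear ROI polygons.  Returns the polygons and the full bin-count
    grid (which sums to the number of cells).
    """
    if bin_px <= 0:
        raise ValueError("bin_px must be positive")
    if len(cell_map) == 0:
        return [], np.zeros((0, 0))
    xs = np.array([c.x for c in cell_map.cells])
    ys = np.array([c.y for c in cell_map.cells])
    x0, y0 = math.floor(xs.min() / bin_px) * bin_px, math.floor(ys.min() / bin_px) * bin_px
    nx_bins = max(1, math.ceil((xs.max() - x0) / bin_px + 1e-9))
    ny_bins = max(1, math.ceil((ys.max() - y0) / bin_px + 1e-9))
    counts, xe, ye = np.histogram2d(
        xs,
        ys,
        bins=[nx_bins, ny_bins],
        range=[[x0, x0 + nx_bins * bin_px], [y0, y0 + ny_bins * bin_px]],
    )
    boxes = [
        box(xe[i], ye[j], xe[i + 1], ye[j + 1])
        for i in range(nx_bins)
        for j in range(ny_bins)
        if counts[i, j] >= min_count
    ]
    if not boxes:
        return [], counts
    merged = unary_union(boxes)
    polys = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    polys = sorted(polys, key=lambda p: (p.bounds[0], p.bounds[1]))
    return polys, counts
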