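"""Cell coordinate containers.

Cells arrive as point coordinates with a phenotype label (typically CD3+
T cells and CD20+ B cells detected upstream in a whole-slide image).  All
coordinates are pixels in the WSI frame: origin top-left, y increasing
downward.  Physical distances are derived via the scan resolution in
micrometres per pixel and only at reporting boundaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: Default scan resolution (Aperio AT2 at 40x) in micrometres per pixel.
DEFAULT_RESOLUTION_UM_PER_PX = 0.253

#: Default phenotype registry: T and B lymphocytes.
DEFAULT_PHENOTYPES = ("T", "B")


@dataclass(frozen=True)
class CellRecord:
    """A single detected cell: identifier, pixel coordinates, phenotype."""

    cell_id: str
    x: float
    y: float
    phenotype: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"cell {self.cell_id!r}: non-finite coordinates")


@dataclass
class CellMap:
    """All cells of one ROI or small WSI.

    Invariants enforced at construction: unique cell ids, positive
    resolution, phenotypes restricted to the registry, and no two retained
    cells at identical coordinates (the duplicate with the lexicographically
    smallest cell_id is kept; later ones are dropped with a warning, since
    coincident points break triangulation uniqueness).
    """

    roi_id: str
    cells: list[CellRecord] = field(default_factory=list)
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES

    def __post_init__(self) -> None:
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution_um_per_px must be positive")
        seen_ids: set[str] = set()
        for c in self.cells:
            if c.cell_id in seen_ids:
                raise ValueError(f"duplicate cell_id {c.cell_id!r}")
            seen_ids.add(c.cell_id)
            if c.phenotype not in self.phenotypes:
                raise ValueError(
                    f"cell {c.cell_id!r}: phenotype {c.phenotype!r} not in "
                    f"registry {self.phenotypes}"
                )
        self.cells = _dedupe_coordinates(self.roi_id, self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    def phenotype_counts(self) -> dict[str, int]:
        counts = {p: 0 for p in self.phenotypes}
        for c in self.cells:
            counts[c.phenotype] += 1
        return counts


def _dedupe_coordinates(roi_id: str, cells: list[CellRecord]) -> list[CellRecord]:
    """Keep one record per exact coordinate (smallest cell_id wins)."""
    by_xy: dict[tuple[float, float], CellRecord] = {}
    order: list[tuple[float, float]] = []
    n_dropped = 0
    for c in cells:
        key = (c.x, c.y)
        prev = by_xy.get(key)
        if prev is None:
            by_xy[key] = c
            order.append(key)
        else:
            n_dropped += 1
            if c.cell_id < prev.cell_id:
                by_xy[key] = c
    if n_dropped:
        logger.warning(
            "ROI %s: dropped %d cell(s) with duplicate coordinates", roi_id, n_dropped
        )
    return [by_xy[k] for k in order]
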