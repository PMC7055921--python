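"""Synthetic T/B point patterns emulating the four infiltrate classes.

Real infiltrates are not publicly deposited, so every downstream module is
exercised on simulated coordinate maps that reproduce the classes'
phenomenology:

* ``T_CELL_AREA`` — a uniformly mixed infiltrate with few B cells
  (default 17 B per 100 cells).
* ``MIXED_UNSTRUCTURED`` — uniformly mixed with a higher B share (35%),
  phenotypes assigned independently of position.
* ``INTERMEDIATE`` — B-rich (60%) with most B cells gathered in a few loose
  Gaussian clumps over a T background: some B-B connectivity but no clean
  compartments.
* ``TLO_LIKE`` — a dense B core disc with a small fraction of interspersed
  T cells, wrapped in a T-cell mantle: the canonical TLO geometry.

Cell spacing is controlled by the mean nearest-neighbour distance (default
8 μm, comfortably below the ~11 μm connectivity cutoff so an infiltrate
forms a single component at the default threshold).  All randomness flows
from one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cells import DEFAULT_RESOLUTION_UM_PER_PX, CellMap, CellRecord
from .classify import ClassLabel

#: Default B-cell fraction per class.
CLASS_B_FRACTION = {
    ClassLabel.T_CELL_AREA: 0.17,
    ClassLabel.MIXED_UNSTRUCTURED: 0.35,
    ClassLabel.INTERMEDIATE: 0.60,
    ClassLabel.TLO_LIKE: 0.50,
}

DEFAULT_N_CELLS = 200
DEFAULT_SPACING_UM = 8.0
DEFAULT_N_B_CLUMPS = 3
#: Share of INTERMEDIATE B cells placed inside clumps (rest scattered).
CLUMP_FRACTION = 0.75
#: Clump standard deviation, in units of the mean spacing.
CLUMP_SD_SPACINGS = 1.5
#: T cells interspersed within a TLO core, as a fraction of core cells.
DEFAULT_T_INTERSPERSED = 0.05
#: Minimum cell-centre separation as a fraction of the mean spacing.
#: Nuclei exclude each other, so real infiltrates are hard-core patterns,
#: noticeably more regular than Poisson noise at the same intensity.
HARD_CORE_FRACTION = 0.8
#: Disc radius prefactor: with the hard core above, a disc of radius
#: 1.3·s·sqrt(n/π) holds n cells at a mean nearest-neighbour distance ≈ s.
DISC_RADIUS_FACTOR = 1.3


class BadSpecError(ValueError):
    pass


@dataclass
class SyntheticPatternSpec:
    """Parameters of one simulated infiltrate."""

    class_label: ClassLabel
    n_cells: int = DEFAULT_N_CELLS
    b_fraction: float | None = None  # None -> class default
    mean_spacing_um: float = DEFAULT_SPACING_UM
    n_b_clumps: int = DEFAULT_N_B_CLUMPS
    core_radius_um: float | None = None  # None -> derived from density
    mantle_width_um: float | None = None  # None -> derived from density
    t_interspersed_fraction: float = DEFAULT_T_INTERSPERSED
    seed: int = 0
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.mean_spacing_um <= 0:
            raise BadSpecError("bad spec: n_cells and mean_spacing_um must be positive")
        if self.b_fraction is None:
            self.b_fraction = CLASS_B_FRACTION[ClassLabel(self.class_label)]
        if not (0.0 <= self.b_fraction <= 1.0):
            raise BadSpecError("bad spec: b_fraction outside [0, 1]")
        if not (0.0 <= self.t_interspersed_fraction < 1.0):
            raise BadSpecError("bad spec: t_interspersed_fraction outside [0, 1)")


def _disc_radius_px(n: int, spacing_px: float) -> float:
    """Disc radius holding n hard-core cells at mean NN distance ≈ spacing."""
    return DISC_RADIUS_FACTOR * spacing_px * math.sqrt(n / math.pi)


def _disc_proposal(radius: float):
    def sample(rng: np.random.Generator) -> np.ndarray:
        r = radius * math.sqrt(rng.random())
        theta = 2.0 * math.pi * rng.random()
        return np.array([r * math.cos(theta), r * math.sin(theta)])

    return sample


def _annulus_proposal(r_inner: float, r_outer: float):
    def sample(rng: np.random.Generator) -> np.ndarray:
        r = math.sqrt(r_inner**2 + rng.random() * (r_outer**2 - r_inner**2))
        theta = 2.0 * math.pi * rng.random()
        return np.array([r * math.cos(theta), r * math.sin(theta)])

    return sample


def _clump_proposal(centers: np.ndarray, sd: float):
    def sample(rng: np.random.Generator) -> np.ndarray:
        c = centers[rng.integers(0, len(centers))]
        return c + rng.normal(scale=sd, size=2)

    return sample


def _place_hard_core(
    rng: np.random.Generator,
    n: int,
    proposal,
    r_min: float,
    existing: np.ndarray | None = None,
    max_tries_per_point: int = 200,
) -> np.ndarray:
    """Dart-throwing with a minimum separation (Matérn-III-style).

    Proposals violating the hard core against every already-placed point
    (including ``existing``) are rejected; after an excessive number of
    rejections the remaining points are accepted unconditionally so the
    requested count is always met.
    """
    placed = np.empty((n, 2))
    prior = existing if existing is not None else np.empty((0, 2))
    count, tries = 0, 0
    budget = n * max_tries_per_point
    r2 = r_min * r_min
    while count < n and tries < budget:
        tries += 1
        p = proposal(rng)
        pool = np.vstack([prior, placed[:count]]) if (len(prior) or count) else None
        if pool is None or ((pool - p) ** 2).sum(axis=1).min() >= r2:
            placed[count] = p
            count += 1
    while count < n:  # dense spec: give up on the hard core, keep the count
        placed[count] = proposal(rng)
        count += 1
    return placed


def generate_pattern(spec: SyntheticPatternSpec) -> CellMap:
    """Simulate one infiltrate as a CellMap (pixel coordinates, centred at
    the field origin shifted to positive coordinates).  Deterministic for a
    fixed spec and seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    spacing_px = spec.mean_spacing_um / spec.resolution_um_per_px
    n_b = int(round(spec.b_fraction * n))
    n_t = n - n_b
    label = ClassLabel(spec.class_label)

    r_min = HARD_CORE_FRACTION * spacing_px

    if label in (ClassLabel.T_CELL_AREA, ClassLabel.MIXED_UNSTRUCTURED):
        radius = _disc_radius_px(n, spacing_px)
        xy = _place_hard_core(rng, n, _disc_proposal(radius), r_min)
        phenotypes = np.array(["B"] * n_b + ["T"] * n_t)
        rng.shuffle(phenotypes)
    elif label is ClassLabel.INTERMEDIATE:
        radius = _disc_radius_px(n, spacing_px)
        n_clumped = int(round(CLUMP_FRACTION * n_b))
        n_scattered = n_b - n_clumped
        centers = _place_hard_core(
            rng,
            spec.n_b_clumps,
            _disc_proposal(0.6 * radius),
            4.0 * CLUMP_SD_SPACINGS * spacing_px,
        )
        sd = CLUMP_SD_SPACINGS * spacing_px
        clumped = _place_hard_core(rng, n_clumped, _clump_proposal(centers, sd), r_min)
        background = _place_hard_core(
            rng, n_scattered + n_t, _disc_proposal(radius), r_min, existing=clumped
        )
        xy = np.vstack([clumped, background])
        phenotypes = np.array(["B"] * n_clumped + ["B"] * n_scattered + ["T"] * n_t)
    elif label is ClassLabel.TLO_LIKE:
        n_core = int(round(n_b / (1.0 - spec.t_interspersed_fraction)))
        n_core = min(n_core, n)
        n_core_t = n_core - n_b
        n_mantle = n - n_core
        if spec.core_radius_um is not None:
            r_core = spec.core_radius_um / spec.resolution_um_per_px
        else:
            r_core = _disc_radius_px(n_core, spacing_px)
        if spec.mantle_width_um is not None:
            r_outer = r_core + spec.mantle_width_um / spec.resolution_um_per_px
        else:
            # mantle sized for equal density with the core
            r_outer = r_core * math.sqrt(1.0 + n_mantle / max(n_core, 1))
        if r_outer <= r_core and n_mantle > 0:
            raise BadSpecError("bad spec: core fills the whole field")
        core = _place_hard_core(rng, n_core, _disc_proposal(r_core), r_min)
        core_types = np.array(["B"] * n_b + ["T"] * n_core_t)
        rng.shuffle(core_types)
        mantle = _place_hard_core(
            rng, n_mantle, _annulus_proposal(r_core, r_outer), r_min, existing=core
        )
        xy = np.vstack([core, mantle])
        phenotypes = np.concatenate([core_types, np.array(["T"] * n_mantle)])
        radius = r_outer
    else:  # pragma: no cover - closed enumeration
        raise BadSpecError(f"bad spec: unknown class {spec.class_label!r}")

    xy = xy + radius + spacing_px  # shift into positive pixel coordinates
    roi_id = f"{label.value.lower()}_s{spec.seed}"
    cells = [
        CellRecord(cell_id=f"c{i:05d}", x=float(x), y=float(y), phenotype=str(p))
        for i, ((x, y), p) in enumerate(zip(xy, phenotypes))
    ]
    return CellMap(
        roi_id=roi_id, cells=cells, resolution_um_per_px=spec.resolution_um_per_px
    )


def generate_labeled_cohort(
    n_per_class: int,
    seed: int = 0,
    n_cells: int = DEFAULT_N_CELLS,
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX,
) -> tuple[list[CellMap], list[ClassLabel]]:
    """A balanced cohort across the four classes.

    Per-pattern seeds derive from the master seed via a SeedSequence spawn,
    so the cohort is reproducible and patterns are mutually independent.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(4 * n_per_class) % (2**31)]
    maps: list[CellMap] = []
    labels: list[ClassLabel] = []
    i = 0
    for label in ClassLabel:
        for rep in range(n_per_class):
            spec = SyntheticPatternSpec(
                class_label=label,
                n_cells=n_cells,
                seed=child_seeds[i],
                resolution_um_per_px=resolution_um_per_px,
            )
            cm = generate_pattern(spec)
            cm.roi_id = f"{label.value.lower()}_{rep:03d}"
            maps.append(cm)
            labels.append(label)
            i += 1
    return maps, labels
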