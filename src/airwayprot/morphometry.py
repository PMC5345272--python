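"""Stereological morphometry of the reticular basement membrane (RBM) and
subepithelial cell-infiltrate densitometry.

RBM thickness is estimated by the orthogonal-intercept method: a square
grid is overlaid on the section, the membrane-crossing segment length is
measured at each grid/membrane intersection, and the arithmetic mean of
the intercepts is corrected by pi/4 for section obliquity:

    tau = (pi/4) * mean(orthogonal intercepts)

Cell infiltrates (eosinophils, neutrophils) are counted by two blinded
operators in the band extending 50 um under the RBM and expressed as
cells/mm^2 of subepithelium, averaging the two operators and then the
patient's samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Point

__all__ = [
    "InterceptSet",
    "BiopsySpecimen",
    "CellCountObservation",
    "rbm_thickness",
    "measure_orthogonal_intercepts",
    "biopsy_suitable",
    "cell_density",
]

MIN_VALID_INTERCEPTS = 40
MIN_RBM_LENGTH_MM = 1.0
MIN_SUBEPITHELIAL_AREA_MM2 = 0.1


@dataclass
class InterceptSet:
    """Orthogonal intercept lengths (um) from one grid overlay."""

    intercept_lengths: np.ndarray
    grid_spacing: float = 100.0   # um
    sampling_step: float = 20.0   # um along the membrane
    section_id: str = ""

    def __post_init__(self) -> None:
        self.intercept_lengths = np.asarray(self.intercept_lengths, dtype=float)
        if self.intercept_lengths.ndim != 1:
            raise ValueError("intercept lengths must be a flat sequence")
        if len(self.intercept_lengths) and (self.intercept_lengths <= 0).any():
            raise ValueError("intercept lengths must be positive")
        if self.grid_spacing <= 0 or self.sampling_step <= 0:
            raise ValueError("grid spacing and sampling step must be positive")

    def __len__(self) -> int:
        return len(self.intercept_lengths)

    @property
    def is_valid_measurement(self) -> bool:
        return len(self) >= MIN_VALID_INTERCEPTS


@dataclass
class CellCountObservation:
    """Blinded two-operator cell count over a measured subepithelial band
    (the band extends 50 um under the RBM)."""

    cell_type: str                      # "eosinophil" or "neutrophil"
    counts_by_operator: tuple[int, int]
    band_area: float                    # mm^2
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.cell_type not in ("eosinophil", "neutrophil"):
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if len(self.counts_by_operator) != 2:
            raise ValueError("exactly two operator counts required")
        if any(c < 0 for c in self.counts_by_operator):
            raise ValueError("counts must be nonnegative")
        if self.band_area <= 0:
            raise ValueError("band area must be positive")


@dataclass
class BiopsySpecimen:
    """One biopsy's morphometric material."""

    rbm_length: float = 0.0          # mm of preserved RBM
    subepithelial_area: float = 0.0  # mm^2
    intercepts: list[InterceptSet] = field(default_factory=list)
    cell_observations: list[CellCountObservation] = field(default_factory=list)
    specimen_id: str = ""

    def __post_init__(self) -> None:
        if self.rbm_length < 0 or self.subepithelial_area < 0:
            raise ValueError("lengths and areas must be nonnegative")


def rbm_thickness(intercepts: InterceptSet) -> float:
    """tau = (pi/4) x arithmetic mean of orthogonal intercepts, in um.

    Warns (does not fail) below the 40-intercept validity convention so
    that small synthetic sections remain measurable.
    """
    if len(intercepts) == 0:
        raise ValueError("empty intercept set")
    if not intercepts.is_valid_measurement:
        warnings.warn(
            f"only {len(intercepts)} intercepts; at least "
            f"{MIN_VALID_INTERCEPTS} are conventionally required",
            stacklevel=2)
    return float(math.pi / 4.0 * intercepts.intercept_lengths.mean())


def biopsy_suitable(specimen: BiopsySpecimen) -> bool:
    """Suitability gate: >= 1.0 mm preserved RBM length AND >= 0.1 mm^2
    subepithelial area (both inclusive)."""
    return (specimen.rbm_length >= MIN_RBM_LENGTH_MM
            and specimen.subepithelial_area >= MIN_SUBEPITHELIAL_AREA_MM2)


def cell_density(observations: Sequence[CellCountObservation]) -> float:
    """Patient-level density in cells/mm^2: per sample the two operator
    counts are averaged and divided by the band area; samples are then
    averaged."""
    if not observations:
        raise ValueError("need at least one observation")
    densities = [(obs.counts_by_operator[0] + obs.counts_by_operator[1]) / 2.0
                 / obs.band_area for obs in observations]
    return float(np.mean(densities))


def _local_normal(line: LineString, arc: float, eps: float = 1e-6) -> np.ndarray:
    """Unit normal of a polyline at arc-length position ``arc``."""
    a = max(arc - eps, 0.0)
    b = min(arc + eps, line.length)
    p0, p1 = line.interpolate(a), line.interpolate(b)
    t = np.array([p1.x - p0.x, p1.y - p0.y])
    norm = np.linalg.norm(t)
    if norm == 0:
        raise ValueError("degenerate boundary segment")
    t /= norm
    return np.array([-t[1], t[0]])


def _ray_hit_distance(origin: Point, direction: np.ndarray,
                      target: LineString, reach: float) -> float | None:
    end = (origin.x + direction[0] * reach, origin.y + direction[1] * reach)
    hit = LineString([(origin.x, origin.y), end]).intersection(target)
    if hit.is_empty:
        return None
    pts: list[Point] = []
    for geom in getattr(hit, "geoms", [hit]):
        if isinstance(geom, Point):
            pts.append(geom)
        else:  # collinear overlap: take its nearest endpoint
            pts.extend(Point(c) for c in geom.coords)
    return min(origin.distance(p) for p in pts)


def measure_orthogonal_intercepts(upper_boundary: Sequence[tuple[float, float]],
                                  lower_boundary: Sequence[tuple[float, float]],
                                  grid_origin: tuple[float, float] = (0.0, 0.0),
                                  grid_spacing: float = 100.0,
                                  sampling_step: float = 20.0,
                                  direction: str = "normal",
                                  section_id: str = "") -> InterceptSet:
    """Measure membrane-crossing intercepts on digitized boundaries.

    ``upper_boundary`` is the epithelium-RBM junction, ``lower_boundary``
    the RBM-subepithelial junction, both planar polylines in um (origin at
    the section lower-left, y increasing upward).  A square grid of the
    given spacing, anchored at ``grid_origin``, is intersected with the
    upper boundary; intersection points closer than ``sampling_step``
    along the membrane than the previously kept point are thinned out.
    At each kept point the intercept is the segment length to the lower
    boundary, measured along the local boundary normal
    (``direction="normal"``, the default) or along the generating grid
    line (``direction="grid"``).
    """
    if direction not in ("normal", "grid"):
        raise ValueError("direction must be 'normal' or 'grid'")
    if grid_spacing <= 0 or sampling_step <= 0:
        raise ValueError("grid spacing and sampling step must be positive")
    upper = LineString(upper_boundary)
    lower = LineString(lower_boundary)
    if upper.crosses(lower):
        raise ValueError("boundaries cross: invalid membrane geometry")

    minx, miny, maxx, maxy = LineString(
        list(upper.coords) + list(lower.coords)).bounds
    pad = grid_spacing
    reach = 4.0 * math.hypot(maxx - minx + 2 * pad, maxy - miny + 2 * pad) + pad

    # grid lines covering the bounding box, anchored at grid_origin
    hits: list[tuple[float, Point, np.ndarray]] = []  # (arc, point, grid dir)
    ox, oy = grid_origin
    k0 = math.floor((minx - pad - ox) / grid_spacing)
    k1 = math.ceil((maxx + pad - ox) / grid_spacing)
    for k in range(k0, k1 + 1):
        x = ox + k * grid_spacing
        gline = LineString([(x, miny - pad), (x, maxy + pad)])
        _collect_hits(gline, upper, np.array([0.0, 1.0]), hits)
    k0 = math.floor((miny - pad - oy) / grid_spacing)
    k1 = math.ceil((maxy + pad - oy) / grid_spacing)
    for k in range(k0, k1 + 1):
        y = oy + k * grid_spacing
        gline = LineString([(minx - pad, y), (maxx + pad, y)])
        _collect_hits(gline, upper, np.array([1.0, 0.0]), hits)

    hits.sort(key=lambda h: h[0])
    lengths = []
    last_arc = -math.inf
    for arc, pt, gdir in hits:
        if arc - last_arc < sampling_step:
            continue
        if direction == "normal":
            d = _local_normal(upper, arc)
        else:
            d = gdir
        dist = _ray_hit_distance(pt, d, lower, reach)
        if dist is None:
            dist = _ray_hit_distance(pt, -d, lower, reach)
        if dist is None or dist == 0:
            continue  # membrane edge or touching boundaries: no intercept here
        lengths.append(dist)
        last_arc = arc
    return InterceptSet(np.array(lengths), grid_spacing=grid_spacing,
                        sampling_step=sampling_step, section_id=section_id)


def _collect_hits(gline: LineString, upper: LineString, gdir: np.ndarray,
                  out: list) -> None:
    inter = gline.intersection(upper)
    if inter.is_empty:
        return
    for geom in getattr(inter, "geoms", [inter]):
        if isinstance(geom, Point):
            out.append((upper.project(geom), geom, gdir))
        else:
            for c in geom.coords:
                p = Point(c)
                out.append((upper.project(p), p, gdir))
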