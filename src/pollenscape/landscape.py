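"""Landscape composition metrics in circular buffers around pollen receptors.

Computes, for buffer radii of 50, 250 and 1000 m: percent cover of area-based
land-use classes (maize, semi-natural grassland, oilseed rape), clipped
lengths of linear landscape elements (roads, water courses, woody elements),
the orthogonal-to-parallel (O:P) length ratio of each linear element type,
and the number of occupied plant populations in the buffer.

The O:P decomposition measures whether linear elements point towards a
receptor or run across that direction: for each element clipped to the
buffer, the axis is the unit vector from the receptor to the element's
midpoint (the point at half its arc length); each segment vector contributes
its absolute projection onto the axis to the parallel component and onto the
normal to the orthogonal component.

All geometry is planar metric (pre-projected coordinates); shapely does the
polygon/polyline work, GeoJSON in/out is plain JSON.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

__all__ = [
    "AREA_CLASSES",
    "LINEAR_TYPES",
    "RADII",
    "AVAILABILITY",
    "BufferSpec",
    "LandUseMap",
    "LinearElementSet",
    "PopulationSet",
    "percent_cover",
    "linear_length",
    "op_components",
    "op_ratio",
    "count_populations",
    "metric_table",
]

AREA_CLASSES = ("SEMNATGRASS", "RAPESEED", "MAIZE", "OTHER")
LINEAR_TYPES = ("L_ROAD", "L_WATER", "L_WOOD")
RADII = (50.0, 250.0, 1000.0)

# Table of which metric is defined at which buffer radius
AVAILABILITY: dict[str, tuple[float, ...]] = {
    "SEMNATGRASS": (1000.0,),
    "RAPESEED": (1000.0,),
    "MAIZE": (50.0, 250.0, 1000.0),
    "L_ROAD": (50.0, 250.0, 1000.0),
    "L_WATER": (50.0, 250.0, 1000.0),
    "L_WOOD": (250.0, 1000.0),
    "N_P": (250.0, 1000.0),
}

_BUFFER_SEGS = 64  # quarter-circle segments; area error ~1e-5 relative


@dataclass(frozen=True)
class BufferSpec:
    receptor_id: str
    center: tuple[float, float]
    radius: float

    def disc(self) -> Polygon:
        return Point(self.center).buffer(self.radius, quad_segs=_BUFFER_SEGS)


class LandUseMap:
    """Land-use polygons with a class attribute; uncovered area is OTHER."""

    def __init__(self, polygons: Iterable[tuple[str, BaseGeometry]]):
        self.by_class: dict[str, list[BaseGeometry]] = {c: [] for c in AREA_CLASSES}
        for cls, geom in polygons:
            if cls not in AREA_CLASSES:
                raise ValueError(f"unknown land-use class {cls!r}")
            if not geom.is_valid:
                geom = make_valid(geom)
                if not geom.is_valid:
                    raise ValueError(f"unrepairable polygon of class {cls}")
            self.by_class[cls].append(geom)

    @classmethod
    def from_geojson(cls, path) -> "LandUseMap":
        with open(path) as fh:
            fc = json.load(fh)
        return cls(
            (f["properties"]["class"], shape(f["geometry"])) for f in fc["features"]
        )


class LinearElementSet:
    """Polylines typed as road / water course / woody element."""

    def __init__(self, elements: Iterable[tuple[str, LineString]]):
        self.by_type: dict[str, list[LineString]] = {t: [] for t in LINEAR_TYPES}
        for typ, line in elements:
            if typ not in LINEAR_TYPES:
                raise ValueError(f"unknown linear element type {typ!r}")
            if len(line.coords) < 2 or line.length <= 0:
                raise ValueError(f"degenerate {typ} element")
            self.by_type[typ].append(line)

    @classmethod
    def from_geojson(cls, path) -> "LinearElementSet":
        with open(path) as fh:
            fc = json.load(fh)
        return cls(
            (f["properties"]["type"], shape(f["geometry"])) for f in fc["features"]
        )


class PopulationSet:
    """Plant populations (patch polygons or centroids) with occupancy flags."""

    def __init__(self, populations: Iterable[tuple[str, BaseGeometry, bool]]):
        self.populations = [(pid, geom, bool(occ)) for pid, geom, occ in populations]

    @classmethod
    def from_geojson(cls, path) -> "PopulationSet":
        with open(path) as fh:
            fc = json.load(fh)
        return cls(
            (
                f["properties"].get("patch_id", str(i)),
                shape(f["geometry"]),
                f["properties"].get("occupied", True),
            )
            for i, f in enumerate(fc["features"])
        )


def _check_available(metric: str, radius: float) -> None:
    radii = AVAILABILITY.get(metric)
    if radii is not None and radius not in radii:
        raise ValueError(f"metric {metric} is not defined at radius {radius:g} m")


# ---------------------------------------------------------------------------
# Area metrics

def percent_cover(lum: LandUseMap, spec: BufferSpec, cls: str) -> float:
    """Percent of the buffer disc covered by polygons of one class.

    OTHER is the complement of the three named classes (uncovered ground
    counts as OTHER).
    """
    _check_available(cls, spec.radius)
    disc = spec.disc()
    if cls == "OTHER":
        named = sum(percent_cover(lum, BufferSpec(spec.receptor_id, spec.center, spec.radius), c)
                    for c in AREA_CLASSES[:-1] if spec.radius in AVAILABILITY[c])
        return 100.0 - named
    area = 0.0
    for geom in lum.by_class[cls]:
        area += disc.intersection(geom).area
    return 100.0 * area / disc.area


# ---------------------------------------------------------------------------
# Linear element metrics

def _clip_polyline_circle(
    coords: np.ndarray, center: tuple[float, float], r: float
) -> list[np.ndarray]:
    """Exact intersection of a polyline with a disc.

    Each segment's inside interval is solved analytically (quadratic in the
    segment parameter), so the clip — unlike clipping against a polygonised
    buffer — is rotation invariant to float precision.  Returns one coordinate
    array per connected piece.
    """
    c = np.asarray(center, dtype=float)
    parts: list[list[np.ndarray]] = []
    open_part: list[np.ndarray] | None = None
    eps = 1e-12
    for p, q in zip(coords[:-1], coords[1:]):
        d = q - p
        a = float(d @ d)
        if a == 0.0:
            continue
        w = p - c
        b = 2.0 * float(w @ d)
        cc = float(w @ w) - r * r
        disc = b * b - 4.0 * a * cc
        if disc < 0.0:
            open_part = None
            continue
        sq = math.sqrt(disc)
        lo = max((-b - sq) / (2.0 * a), 0.0)
        hi = min((-b + sq) / (2.0 * a), 1.0)
        if lo >= hi:
            open_part = None
            continue
        start, end = p + lo * d, p + hi * d
        if open_part is not None and lo <= eps:
            open_part.append(end)
        else:
            open_part = [start, end]
            parts.append(open_part)
        if hi < 1.0 - eps:
            open_part = None
    return [np.asarray(part) for part in parts if len(part) >= 2]


def _clipped_parts(elems: LinearElementSet, spec: BufferSpec, typ: str) -> list[LineString]:
    """Element pieces inside the buffer; a multi-part clip (an element that
    crosses the buffer more than once) yields one part per crossing, each
    later given its own axis."""
    parts: list[LineString] = []
    for line in elems.by_type[typ]:
        for arr in _clip_polyline_circle(
            np.asarray(line.coords, dtype=float), spec.center, spec.radius
        ):
            piece = LineString(arr)
            if piece.length > 0:
                parts.append(piece)
    return parts


def linear_length(elems: LinearElementSet, spec: BufferSpec, typ: str) -> float:
    """Total clipped length (m) of elements of one type inside the buffer."""
    _check_available(typ, spec.radius)
    return float(sum(p.length for p in _clipped_parts(elems, spec, typ)))


def op_components(
    part: LineString, center: tuple[float, float]
) -> tuple[float, float] | None:
    """(parallel_m, orthogonal_m) of one clipped element piece.

    The axis points from the buffer center to the piece's half-arc-length
    midpoint; each segment vector v contributes |v.u| to the parallel and
    |v.n| to the orthogonal component.  Returns None (with a warning) when
    the midpoint coincides with the center, leaving the axis undefined.
    """
    mid = part.interpolate(0.5, normalized=True)
    axis = np.array([mid.x - center[0], mid.y - center[1]])
    norm = np.hypot(*axis)
    if norm < 1e-12:
        warnings.warn("element midpoint coincides with receptor; element skipped")
        return None
    u = axis / norm
    n = np.array([-u[1], u[0]])
    coords = np.asarray(part.coords)
    segs = np.diff(coords, axis=0)
    return float(np.abs(segs @ u).sum()), float(np.abs(segs @ n).sum())


def op_ratio(
    elems: LinearElementSet,
    spec: BufferSpec,
    typ: str,
    ratio_max: float = 1e3,
    clip: str = "after",
) -> float | None:
    """Pooled orthogonal-to-parallel length ratio of one element type.

    Components are summed over all clipped pieces of the type in the buffer
    (pooled sums, not per-element averages).  If the pooled parallel
    component is below 1e-9 m the ratio is capped at ``ratio_max``.  Returns
    None when no element of the type intersects the buffer (metric missing,
    not zero).  ``clip='before'`` uses the whole-element midpoint for the
    axis instead of the clipped piece's midpoint.
    """
    _check_available(typ, spec.radius)
    if clip == "after":
        pieces = [(p, p) for p in _clipped_parts(elems, spec, typ)]
    elif clip == "before":
        pieces = []
        for line in elems.by_type[typ]:
            for arr in _clip_polyline_circle(
                np.asarray(line.coords, dtype=float), spec.center, spec.radius
            ):
                g = LineString(arr)
                if g.length > 0:
                    pieces.append((g, line))
    else:
        raise ValueError("clip must be 'after' or 'before'")
    par = orth = 0.0
    seen = False
    for piece, axis_source in pieces:
        mid = axis_source.interpolate(0.5, normalized=True)
        comp = op_components(piece, spec.center) if clip == "after" else _components_with_axis(
            piece, spec.center, (mid.x, mid.y)
        )
        if comp is None:
            continue
        seen = True
        par += comp[0]
        orth += comp[1]
    if not seen:
        return None
    if par < 1e-9:
        return ratio_max
    return min(orth / par, ratio_max)


def _components_with_axis(
    part: LineString, center: tuple[float, float], midpoint: tuple[float, float]
) -> tuple[float, float] | None:
    axis = np.array([midpoint[0] - center[0], midpoint[1] - center[1]])
    norm = np.hypot(*axis)
    if norm < 1e-12:
        warnings.warn("element midpoint coincides with receptor; element skipped")
        return None
    u = axis / norm
    n = np.array([-u[1], u[0]])
    segs = np.diff(np.asarray(part.coords), axis=0)
    return float(np.abs(segs @ u).sum()), float(np.abs(segs @ n).sum())


# ---------------------------------------------------------------------------
# Population counts

def count_populations(
    pops: PopulationSet, spec: BufferSpec, own_patch_id: str | None = None
) -> int:
    """Occupied populations intersecting the buffer, excluding the
    receptor's own population."""
    _check_available("N_P", spec.radius)
    disc = spec.disc()
    n = 0
    for pid, geom, occupied in pops.populations:
        if not occupied or pid == own_patch_id:
            continue
        if geom.intersects(disc):
            n += 1
    return n


# ---------------------------------------------------------------------------
# Table driver

def metric_table(
    receptors: Sequence[tuple[str, tuple[float, float], str]],
    lum: LandUseMap,
    elems: LinearElementSet,
    pops: PopulationSet,
    radii: Sequence[float] = RADII,
    ratio_max: float = 1e3,
):
    """One row per receptor x radius with every metric defined at that
    radius; undefined cells are NaN/missing.

    ``receptors`` holds (receptor_id, (x, y), patch_id) triples.  Returns a
    pandas DataFrame.
    """
    import pandas as pd

    rows = []
    for rid, center, patch_id in receptors:
        for radius in radii:
            spec = BufferSpec(rid, center, radius)
            row: dict[str, object] = {"receptor_id": rid, "radius": radius}
            for cls in AREA_CLASSES[:-1]:
                if radius in AVAILABILITY[cls]:
                    row[cls] = percent_cover(lum, spec, cls)
            for typ in LINEAR_TYPES:
                if radius in AVAILABILITY[typ]:
                    row[typ] = linear_length(elems, spec, typ)
                    ratio = op_ratio(elems, spec, typ, ratio_max=ratio_max)
                    row[f"OP_{typ}"] = float("nan") if ratio is None else ratio
            if radius in AVAILABILITY["N_P"]:
                row["N_P"] = count_populations(pops, spec, own_patch_id=patch_id)
            rows.append(row)
    return pd.DataFrame(rows)
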