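"""Harmonization of historic and current species range maps.

Historic range maps digitized from heterogeneous sources rarely align with
modern survey polygons: thin "slivers" and isolated "islands" of apparent
range expansion appear along mismatched edges, coastlines disagree between
sources, and some ranges extend above or below a species' elevational
limits.  This module turns raw polygon (or raster) inputs into a pair of
aligned binary rasters per species such that, after harmonization,

    current ⊆ historic ⊆ land

holds everywhere.  Three rules are applied, in order:

1. **Superset enforcement** — apparent expansions are treated as mapping
   error, so the historic range is extended to cover the entire current
   range (union).
2. **Coastline adjustment** — land cells near both the range edge and the
   coast are added, aligning ranges whose sources used different
   shorelines; both rasters are then clipped to the land mask.
3. **Altitude clipping** — where a species has recorded elevational
   limits, cells whose elevation falls outside them are dropped (with a
   per-species opt-out for species whose published limits describe the
   current range only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import shape as shapely_shape
from shapely import contains_xy, prepare

from .grid import GridSpec, CellAreas

__all__ = [
    "SpeciesTraits",
    "SpeciesRangePair",
    "HarmonizeParams",
    "rasterize_polygons",
    "enforce_superset",
    "coastline_adjust",
    "altitude_clip",
    "harmonize_species",
]


@dataclass
class SpeciesTraits:
    """Identity and attributes of a species carried through the pipeline."""

    name: str
    family: str = ""
    mass_kg: float = np.nan
    iucn_status: str = ""
    population_trend: str = ""  # decreasing | stable | increasing
    elevation_min: float | None = None
    elevation_max: float | None = None
    altitude_clip_enabled: bool = True

    def __post_init__(self):
        if np.isfinite(self.mass_kg) and self.mass_kg <= 0:
            raise ValueError(f"{self.name}: mass must be positive")
        if (
            self.elevation_min is not None
            and self.elevation_max is not None
            and self.elevation_min > self.elevation_max
        ):
            raise ValueError(f"{self.name}: elevation_min > elevation_max")


@dataclass
class SpeciesRangePair:
    """Harmonized historic + current binary rasters for one species.

    ``provenance`` records every harmonization step with the number of
    cells it added/removed in each raster, so any area statistic can be
    traced back to the raw inputs.
    """

    traits: SpeciesTraits
    historic: np.ndarray
    current: np.ndarray
    grid: GridSpec
    provenance: list[dict] = field(default_factory=list)

    def validate(self, land: np.ndarray | None = None) -> None:
        if not np.all(self.historic[self.current.astype(bool)]):
            raise ValueError(f"{self.traits.name}: current not a subset of historic")
        if land is not None and not np.all(land[self.historic.astype(bool)]):
            raise ValueError(f"{self.traits.name}: historic extends off the land mask")


@dataclass
class HarmonizeParams:
    """Knobs of the harmonization pipeline.

    ``coastline_k`` is in fine-grid cells (Chebyshev distance); the
    default 3 matches a three-cell buffer at 0.05° resolution.
    """

    coastline_k: int = 3
    superset_enforce: bool = True
    clip_altitude: bool = True
    elevation_stat: str = "mean"  # statistic the elevation raster represents

    def __post_init__(self):
        if self.coastline_k < 0:
            raise ValueError("coastline_k must be >= 0")


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_polygons(
    features,
    grid: GridSpec,
    status_filter=None,
    status_attr: str = "presence",
) -> np.ndarray:
    """Burn polygons to a binary raster by centroid containment.

    ``features`` may be a GeoJSON FeatureCollection ``dict``, a list of
    GeoJSON Feature dicts, or a list of shapely geometries.  When
    ``status_filter`` is given (e.g. ``{1, 2}`` for IUCN extant /
    probably extant), only features whose ``status_attr`` property is in
    the filter are burned.  A cell is set iff its centroid falls inside
    (or on the boundary of) a retained polygon.
    """
    if isinstance(features, dict) and features.get("type") == "FeatureCollection":
        features = features["features"]
    geoms = []
    for feat in features:
        if isinstance(feat, dict):
            props = feat.get("properties") or {}
            if status_filter is not None and props.get(status_attr) not in status_filter:
                continue
            geoms.append(shapely_shape(feat["geometry"]))
        else:  # bare shapely geometry — no status to filter on
            geoms.append(feat)
    out = np.zeros(grid.shape, dtype=bool)
    if not geoms:
        warnings.warn("no polygons retained after status filtering; raster is empty")
        return out
    lon_mesh, lat_mesh = grid.centroid_mesh()
    for geom in geoms:
        prepare(geom)
        # restrict the centroid test to the polygon's bounding box
        minx, miny, maxx, maxy = geom.bounds
        r0, c1 = grid.cell_index(maxx, miny)  # south-east corner
        r1, c0 = grid.cell_index(minx, maxy)  # north-west corner
        sub = np.s_[max(r1, 0) : r0 + 1, max(c0, 0) : c1 + 1]
        inside = contains_xy(geom, lon_mesh[sub], lat_mesh[sub])
        # centroids on the boundary count as covered
        if not inside.all():
            from shapely import intersects_xy

            inside |= intersects_xy(geom, lon_mesh[sub], lat_mesh[sub])
        out[sub] |= inside
    return out


# ---------------------------------------------------------------------------
# Harmonization rules
# ---------------------------------------------------------------------------

def enforce_superset(
    historic: np.ndarray,
    current: np.ndarray,
    areas: CellAreas | None = None,
) -> tuple[np.ndarray, dict]:
    """Extend the historic range to cover the current range.

    Apparent range expansions (current cells outside historic) are treated
    as mapping artefacts and absorbed into the historic range.  The report
    gives the induced % increase in historic range area, area-weighted
    when ``areas`` is supplied, cell-counted otherwise.
    """
    historic = historic.astype(bool)
    current = current.astype(bool)
    new = current & ~historic
    merged = historic | current
    w = areas.as_raster() if areas is not None else np.ones(historic.shape)
    hist_area = float(w[historic].sum())
    add_area = float(w[new].sum())
    report = {
        "cells_added": int(new.sum()),
        "historic_empty": not historic.any(),
        "pct_area_increase": (100.0 * add_area / hist_area) if hist_area > 0 else np.nan,
    }
    if report["historic_empty"]:
        warnings.warn("historic range empty: % area increase undefined")
    return merged, report


def coastline_adjust(range_raster: np.ndarray, land: np.ndarray, k: int) -> np.ndarray:
    """Add coastal land cells near the range to align mismatched shorelines.

    A land cell is added iff its Chebyshev grid distance is ≤ ``k`` to
    some range cell *and* ≤ ``k`` to some non-land cell.  Never removes
    cells; the output is clipped to land.
    """
    rng = range_raster.astype(bool)
    land = land.astype(bool)
    if k == 0:
        return rng.copy()
    struct = np.ones((2 * k + 1, 2 * k + 1), dtype=bool)
    near_range = ndimage.binary_dilation(rng, structure=struct)
    near_ocean = ndimage.binary_dilation(~land, structure=struct)
    return rng | (land & near_range & near_ocean)


def altitude_clip(
    range_raster: np.ndarray,
    elevation: np.ndarray,
    traits: SpeciesTraits,
) -> np.ndarray:
    """Drop range cells outside the species' elevational limits.

    Identity when clipping is disabled for the species or no limits are
    recorded.  Missing bounds on one side are treated as open.
    """
    rng = range_raster.astype(bool)
    if not traits.altitude_clip_enabled:
        return rng.copy()
    lo, hi = traits.elevation_min, traits.elevation_max
    if lo is None and hi is None:
        return rng.copy()
    keep = np.ones_like(rng)
    if lo is not None:
        keep &= elevation >= lo
    if hi is not None:
        keep &= elevation <= hi
    out = rng & keep
    if rng.any() and not out.any():
        warnings.warn(
            f"{traits.name}: altitude clipping removed the entire range "
            f"(limits [{lo}, {hi}])"
        )
    return out


def _delta(step: str, target: str, before: np.ndarray, after: np.ndarray) -> dict:
    return {
        "step": step,
        "raster": target,
        "cells_added": int((after & ~before).sum()),
        "cells_removed": int((before & ~after).sum()),
    }


def harmonize_species(
    traits: SpeciesTraits,
    historic_raw: np.ndarray,
    current_raw: np.ndarray,
    land: np.ndarray,
    elevation: np.ndarray,
    grid: GridSpec,
    params: HarmonizeParams | None = None,
    areas: CellAreas | None = None,
) -> SpeciesRangePair:
    """Run the full harmonization pipeline for one species.

    Order: superset → coastline adjustment (both rasters) → land-mask
    intersection → altitude clip (both rasters) → final re-assertion of
    current ⊆ historic by union.  Each step's cell deltas are recorded in
    the pair's provenance.
    """
    params = params or HarmonizeParams()
    land = land.astype(bool)
    hist = historic_raw.astype(bool).copy()
    curr = current_raw.astype(bool).copy()
    prov: list[dict] = []

    if params.superset_enforce:
        before = hist
        hist, report = enforce_superset(hist, curr, areas)
        entry = _delta("superset", "historic", before, hist)
        entry["pct_area_increase"] = report["pct_area_increase"]
        prov.append(entry)

    if params.coastline_k > 0:
        # iterate the adjustment to a fixed point: a single dilation pass is
        # not idempotent along narrow coastal strips, and the whole pipeline
        # must be (re-running harmonization may not move ranges further)
        for name, ras in (("historic", hist), ("current", curr)):
            adj = ras
            for _ in range(100):
                nxt = coastline_adjust(adj, land, params.coastline_k)
                if np.array_equal(nxt, adj):
                    break
                adj = nxt
            else:  # pragma: no cover - pathological strip geometry
                warnings.warn(f"{traits.name}: coastline adjustment did not converge")
            prov.append(_delta("coastline_adjust", name, ras, adj))
            if name == "historic":
                hist = adj
            else:
                curr = adj

    for name, ras in (("historic", hist), ("current", curr)):
        clipped = ras & land
        prov.append(_delta("land_mask", name, ras, clipped))
        if name == "historic":
            hist = clipped
        else:
            curr = clipped

    if params.clip_altitude:
        for name, ras in (("historic", hist), ("current", curr)):
            clipped = altitude_clip(ras, elevation, traits)
            prov.append(_delta("altitude_clip", name, ras, clipped))
            if name == "historic":
                hist = clipped
            else:
                curr = clipped

    # clipping applies identically to both rasters so the subset relation
    # survives, but re-assert it by union in case of asymmetric inputs
    if not np.all(hist[curr]):
        before = hist
        hist = hist | curr
        entry = _delta("subset_repair", "historic", before, hist)
        prov.append(entry)

    pair = SpeciesRangePair(
        traits=traits, historic=hist, current=curr, grid=grid, provenance=prov
    )
    pair.validate(land)
    return pair
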