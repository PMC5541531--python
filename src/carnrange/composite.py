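"""Composite richness mapping and zonal contraction statistics.

Harmonized per-species range pairs are stacked into richness composites
(historic, current, lost, percent lost), intact-guild maps (cells where at
least one species occurred historically and none has been lost), and
area-weighted zonal summaries by biome or geographical region.  All "% of
land" quantities weight cells by their spherical area, not by cell count;
zonal richness means can use either weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import CellAreas
from .harmonize import SpeciesRangePair

__all__ = [
    "RichnessStack",
    "PERSISTENCE_CODES",
    "contraction_percent",
    "persistence_raster",
    "richness_stack",
    "intact_guild_raster",
    "area_fraction",
    "zonal_richness_summary",
    "trait_contraction_table",
]

#: categorical codes of :func:`persistence_raster`
PERSISTENCE_CODES = {"outside": 0, "persisted": 1, "contracted": 2}


@dataclass
class RichnessStack:
    """Composite richness rasters over a set of species.

    ``pct_lost`` is NaN (not zero) where historic richness is zero, so a
    rendered map distinguishes "never occupied" from "nothing lost".
    """

    historic_richness: np.ndarray
    current_richness: np.ndarray
    lost_richness: np.ndarray
    pct_lost: np.ndarray
    n_species: int


def contraction_percent(pair: SpeciesRangePair, areas: CellAreas) -> float:
    """Percent of historic range area lost, area-weighted.

    100 · area(historic \\ current) / area(historic).
    """
    hist = pair.historic.astype(bool)
    if not hist.any():
        raise ValueError(f"{pair.traits.name}: empty historic range")
    lost = hist & ~pair.current.astype(bool)
    w = areas.as_raster()
    return 100.0 * float(w[lost].sum()) / float(w[hist].sum())


def persistence_raster(pair: SpeciesRangePair) -> np.ndarray:
    """Categorical map {0 outside, 1 persisted, 2 contracted}."""
    hist = pair.historic.astype(bool)
    curr = pair.current.astype(bool)
    out = np.zeros(hist.shape, dtype=np.int8)
    out[hist & curr] = PERSISTENCE_CODES["persisted"]
    out[hist & ~curr] = PERSISTENCE_CODES["contracted"]
    return out


def richness_stack(pairs: list[SpeciesRangePair]) -> RichnessStack:
    """Sum species ranges into historic/current/lost/percent-lost composites."""
    if not pairs:
        raise ValueError("no species supplied")
    shape = pairs[0].historic.shape
    for p in pairs:
        if p.historic.shape != shape or p.current.shape != shape:
            raise ValueError(f"{p.traits.name}: raster shape mismatch")
    hist = np.zeros(shape, dtype=np.int16)
    curr = np.zeros(shape, dtype=np.int16)
    for p in pairs:
        hist += p.historic.astype(np.int16)
        curr += p.current.astype(np.int16)
    lost = hist - curr
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(hist >= 1, 100.0 * lost / hist, np.nan)
    return RichnessStack(
        historic_richness=hist,
        current_richness=curr,
        lost_richness=lost,
        pct_lost=pct,
        n_species=len(pairs),
    )


def intact_guild_raster(stack: RichnessStack) -> np.ndarray:
    """Cells whose historic guild (≥ 1 species) has lost no species."""
    return (stack.historic_richness >= 1) & (stack.lost_richness == 0)


def area_fraction(
    mask: np.ndarray,
    areas: CellAreas,
    zone_mask: np.ndarray | None = None,
) -> float:
    """Percent of the zone's spherical area covered by ``mask``.

    ``zone_mask`` defaults to the whole grid; pass the land mask for
    "% of land" statistics.
    """
    mask = mask.astype(bool)
    zone = np.ones_like(mask) if zone_mask is None else zone_mask.astype(bool)
    w = areas.as_raster()
    denom = float(w[zone].sum())
    if denom == 0:
        raise ValueError("zone has zero area")
    return 100.0 * float(w[mask & zone].sum()) / denom


def zonal_richness_summary(
    stack: RichnessStack,
    zones: np.ndarray,
    areas: CellAreas,
    land: np.ndarray | None = None,
    weighting: str = "area",
) -> pd.DataFrame:
    """Per-zone mean richness change and guild-intactness statistics.

    Returns one row per integer zone code with area- (default) or
    cell-count-weighted mean historic richness, mean current richness,
    their difference (mean decline), the percent of the zone's land with
    an intact guild, and the percent historically occupied by ≥ 1
    species.  Sorted by mean decline, largest first.  Zones with no land
    cells are dropped with a warning.
    """
    if weighting not in ("area", "count"):
        raise ValueError("weighting must be 'area' or 'count'")
    land = np.ones(zones.shape, dtype=bool) if land is None else land.astype(bool)
    w = areas.as_raster() if weighting == "area" else np.ones(zones.shape)
    w_area = areas.as_raster()  # land-fraction statistics are always area-weighted
    intact = intact_guild_raster(stack)
    occupied = stack.historic_richness >= 1
    rows = []
    for z in np.unique(zones[land]):
        sel = (zones == z) & land
        if not sel.any():
            warnings.warn(f"zone {z}: no land cells, dropped")
            continue
        wz = w[sel]
        denom = wz.sum()
        mean_hist = float((stack.historic_richness[sel] * wz).sum() / denom)
        mean_curr = float((stack.current_richness[sel] * wz).sum() / denom)
        land_area = w_area[sel].sum()
        rows.append(
            {
                "zone": int(z),
                "mean_historic_richness": mean_hist,
                "mean_current_richness": mean_curr,
                "mean_decline": mean_hist - mean_curr,
                "pct_intact_guild": 100.0 * float(w_area[sel & intact].sum() / land_area),
                "pct_historically_occupied": 100.0
                * float(w_area[sel & occupied].sum() / land_area),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("mean_decline", ascending=False, ignore_index=True)
    return out


def trait_contraction_table(
    pairs: list[SpeciesRangePair], areas: CellAreas
) -> pd.DataFrame:
    """Per-species contraction percentages with traits, largest loss first."""
    rows = [
        {
            "species": p.traits.name,
            "family": p.traits.family,
            "mass_kg": p.traits.mass_kg,
            "pct_contraction": contraction_percent(p, areas),
            "iucn_status": p.traits.iucn_status,
            "population_trend": p.traits.population_trend,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows).sort_values(
        "pct_contraction", ascending=False, ignore_index=True
    )
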