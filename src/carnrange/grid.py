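"""Raster lattices on the sphere.

Everything downstream — rasterized ranges, richness composites, the 50 km
observation grid for the contraction model — lives on the grids defined
here.  Two lattices matter: a fine geographic grid (default 0.05°) on which
ranges are rasterized, and a coarse grid obtained by integer block
aggregation of the fine one, on which model observations are built.

All areas and distances are spherical (radius ``EARTH_RADIUS_KM``); no
ellipsoidal geodesy is attempted.  Cell indexing is 0-based with row 0 at
the northern edge; cells are half-open intervals ``[edge, edge + res)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GridSpec",
    "CellAreas",
    "make_grid",
    "cell_areas",
    "great_circle_distance",
    "neighbors_within",
    "equal_area_xy",
    "centroid_table",
    "write_ascii_grid",
    "read_ascii_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat lattice.

    Parameters
    ----------
    resolution : float
        Cell size in degrees.
    lon_min, lon_max, lat_min, lat_max : float
        Bounding box in degrees.  The box must be an exact integer
        multiple of ``resolution`` along both axes.
    n_rows, n_cols : int
        Lattice shape; row 0 is the northernmost band.
    registration : str
        Edge-alignment rule; cells are half-open ``[edge, edge + res)``.
    projection_tag : str
        Identifier recorded in outputs; ``"geographic"`` for lon/lat
        grids, the equal-area tag for aggregated model grids.
    """

    resolution: float
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    n_rows: int
    n_cols: int
    registration: str = "edge"
    projection_tag: str = "geographic"

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.lon_min, self.lon_max, self.lat_min, self.lat_max)

    def cell_centroid(self, row, col):
        """Centroid lon/lat of cell ``(row, col)``; accepts arrays."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.lon_min + (col + 0.5) * self.resolution
        lat = self.lat_max - (row + 0.5) * self.resolution
        return lon, lat

    def cell_index(self, lon, lat):
        """Inverse of :meth:`cell_centroid` (floor to containing cell)."""
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        col = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        row = np.floor((self.lat_max - lat) / self.resolution).astype(int)
        # points exactly on the south/east boundary belong to the last cell
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col

    def centroid_mesh(self):
        """(lon, lat) 2-D arrays of every cell centroid."""
        rows = np.arange(self.n_rows)
        cols = np.arange(self.n_cols)
        lon = self.lon_min + (cols + 0.5) * self.resolution
        lat = self.lat_max - (rows + 0.5) * self.resolution
        return np.meshgrid(lon, lat)

    def row_lats(self) -> np.ndarray:
        """Centroid latitude of each row, north to south."""
        rows = np.arange(self.n_rows)
        return self.lat_max - (rows + 0.5) * self.resolution

    def coarsen(self, factor: int, projection_tag: str = "block-aggregate") -> "GridSpec":
        """Aggregate ``factor``×``factor`` fine cells into one coarse cell."""
        if factor < 1 or self.n_rows % factor or self.n_cols % factor:
            raise ValueError(
                f"grid of shape {self.shape} is not divisible by factor {factor}"
            )
        return GridSpec(
            resolution=self.resolution * factor,
            lon_min=self.lon_min,
            lon_max=self.lon_max,
            lat_min=self.lat_min,
            lat_max=self.lat_max,
            n_rows=self.n_rows // factor,
            n_cols=self.n_cols // factor,
            registration=self.registration,
            projection_tag=projection_tag,
        )


def make_grid(
    resolution: float,
    extent: tuple[float, float, float, float] = (-180.0, 180.0, -90.0, 90.0),
    projection_tag: str = "geographic",
) -> GridSpec:
    """Build a :class:`GridSpec`, rejecting extents the resolution cannot tile.

    ``extent`` is ``(lon_min, lon_max, lat_min, lat_max)`` in degrees.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    lon_min, lon_max, lat_min, lat_max = extent
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError(f"degenerate extent {extent}")
    n_cols = (lon_max - lon_min) / resolution
    n_rows = (lat_max - lat_min) / resolution
    if abs(n_cols - round(n_cols)) > 1e-8 or abs(n_rows - round(n_rows)) > 1e-8:
        raise ValueError(
            f"extent {extent} is not an integer multiple of resolution {resolution}"
        )
    return GridSpec(
        resolution=float(resolution),
        lon_min=float(lon_min),
        lon_max=float(lon_max),
        lat_min=float(lat_min),
        lat_max=float(lat_max),
        n_rows=int(round(n_rows)),
        n_cols=int(round(n_cols)),
        projection_tag=projection_tag,
    )


@dataclass(frozen=True)
class CellAreas:
    """Spherical cell areas (km²) of a geographic grid, one value per
    latitude band (all cells in a band share an area)."""

    band_km2: np.ndarray  # length n_rows, north to south
    grid: GridSpec = field(repr=False)

    def as_raster(self) -> np.ndarray:
        """Broadcast band areas to the full grid shape."""
        return np.broadcast_to(
            self.band_km2[:, None], self.grid.shape
        ).copy()


def cell_areas(grid: GridSpec, radius_km: float = EARTH_RADIUS_KM) -> CellAreas:
    """Exact spherical area of each latitude band's cells.

    band area = R² · Δλ · (sin φ_top − sin φ_bottom), Δλ in radians.
    """
    res = np.deg2rad(grid.resolution)
    rows = np.arange(grid.n_rows)
    lat_top = np.deg2rad(grid.lat_max - rows * grid.resolution)
    lat_bot = np.deg2rad(grid.lat_max - (rows + 1) * grid.resolution)
    band = radius_km**2 * res * (np.sin(lat_top) - np.sin(lat_bot))
    return CellAreas(band_km2=band, grid=grid)


def great_circle_distance(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Haversine great-circle distance in km; broadcasts over arrays."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _unit_sphere_xyz(lon, lat, radius_km=EARTH_RADIUS_KM):
    lon = np.deg2rad(np.asarray(lon, dtype=float))
    lat = np.deg2rad(np.asarray(lat, dtype=float))
    return np.column_stack(
        (
            radius_km * np.cos(lat) * np.cos(lon),
            radius_km * np.cos(lat) * np.sin(lon),
            radius_km * np.sin(lat),
        )
    )


def neighbors_within(
    lons,
    lats,
    radius_km: float,
    include_self: bool = False,
) -> list[np.ndarray]:
    """Indices of points within a great-circle distance band of each point.

    Exact: a KD-tree on 3-D sphere coordinates is queried with the chord
    length equivalent to the great-circle radius, so the result matches an
    all-pairs haversine scan.  The focal point is excluded unless
    ``include_self``.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size == 0:
        return []
    xyz = _unit_sphere_xyz(lons, lats)
    # chord length subtending a great-circle arc of radius_km
    chord = 2.0 * EARTH_RADIUS_KM * np.sin(
        min(radius_km / (2.0 * EARTH_RADIUS_KM), np.pi / 2)
    )
    tree = cKDTree(xyz)
    hits = tree.query_ball_point(xyz, r=chord * (1 + 1e-12))
    out = []
    for i, idx in enumerate(hits):
        idx = np.asarray(idx, dtype=int)
        if not include_self:
            idx = idx[idx != i]
        out.append(np.sort(idx))
    return out


def equal_area_xy(lon, lat, radius_km: float = EARTH_RADIUS_KM):
    """Lambert cylindrical equal-area coordinates (km), standard parallel 0°.

    x = R·λ, y = R·sin φ.  Used for the exported model-grid centroid table;
    distances in model space use great circles on the lon/lat centroids.
    """
    lon = np.deg2rad(np.asarray(lon, dtype=float))
    lat = np.deg2rad(np.asarray(lat, dtype=float))
    return radius_km * lon, radius_km * np.sin(lat)


def centroid_table(grid: GridSpec):
    """Flat table of every cell: cell_id, row, col, lon, lat, x_km, y_km."""
    import pandas as pd

    lon, lat = grid.centroid_mesh()
    rows, cols = np.meshgrid(
        np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij"
    )
    x, y = equal_area_xy(lon.ravel(), lat.ravel())
    return pd.DataFrame(
        {
            "cell_id": rows.ravel() * grid.n_cols + cols.ravel(),
            "row": rows.ravel(),
            "col": cols.ravel(),
            "lon": lon.ravel(),
            "lat": lat.ravel(),
            "x_km": x,
            "y_km": y,
        }
    )


# ---------------------------------------------------------------------------
# Raster I/O — ESRI ASCII grid (plain text, row 0 = north, matching GridSpec)
# ---------------------------------------------------------------------------

def write_ascii_grid(path, array: np.ndarray, grid: GridSpec, nodata=-9999) -> None:
    """Write a raster as an ESRI ASCII grid with the grid's georeferencing."""
    array = np.asarray(array)
    if array.shape != grid.shape:
        raise ValueError(f"array shape {array.shape} != grid shape {grid.shape}")
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.lon_min!r}\n"
        f"yllcorner {grid.lat_min!r}\n"
        f"cellsize {grid.resolution!r}\n"
        f"NODATA_value {nodata}\n"
    )
    data = np.where(np.isfinite(array.astype(float)), array, nodata)
    fmt = "%d" if np.issubdtype(array.dtype, np.integer) or array.dtype == bool else "%.8g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)


def read_ascii_grid(path, dtype=float):
    """Read an ESRI ASCII grid; returns ``(array, GridSpec, nodata)``.

    NODATA cells become NaN for float dtypes and are left at the nodata
    code for integer dtypes.
    """
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    res = header["cellsize"]
    grid = GridSpec(
        resolution=res,
        lon_min=header["xllcorner"],
        lon_max=header["xllcorner"] + n_cols * res,
        lat_min=header["yllcorner"],
        lat_max=header["yllcorner"] + n_rows * res,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    data = data.reshape(grid.shape)
    nodata = header["nodata_value"]
    if np.issubdtype(np.dtype(dtype), np.floating):
        data = data.astype(dtype)
        data[data == nodata] = np.nan
    else:
        data = data.astype(dtype)
    return data, grid, nodata
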