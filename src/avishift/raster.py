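"""Georeferenced grid container and GeoTIFF round-trip.

The :class:`RasterGrid` is the lingua franca of the pipeline: climate stacks,
elevation, region partitions, reserve masks, suitability surfaces, binary
range maps, richness and priority-rank grids are all instances of it.

Conventions (fixed across the package):

* geographic WGS84 lon/lat, north-up; row 0 is the northernmost row;
* cell-center registration for reported coordinates; a point belongs to the
  half-open cell ``[x, x + cell_size)`` in longitude and, measured from the
  southern grid edge, ``[y, y + cell_size)`` in latitude;
* missing data is NaN in float grids.

Files are written as GeoTIFFs: plain TIFF pages (one per band) carrying the
standard GeoTIFF tags — ModelPixelScale (33550), ModelTiepoint (33922) and a
GeoKeyDirectory (34735) declaring geographic WGS84 — plus a JSON image
description holding the band names. Only geographic (lon/lat) rasters are
supported; a projected file raises :class:`~avishift.errors.UnsupportedCRSError`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import AlignmentError, ConfigurationError, UnsupportedCRSError

EARTH_RADIUS_KM = 6371.0

# GeoTIFF tag/key codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_MODEL_TYPE_GEOGRAPHIC = 2
_GCS_WGS84 = 4326


@dataclass
class RasterGrid:
    """A single- or multi-band north-up geographic grid.

    Parameters
    ----------
    values : ndarray
        ``(n_rows, n_cols)`` or ``(n_bands, n_rows, n_cols)`` array.
    lon_west, lat_north : float
        Coordinates of the outer corner of the top-left cell, decimal degrees.
    cell_size : float
        Cell edge length in decimal degrees (square cells).
    band_names : tuple of str
        One label per band; defaults to ``band_1 .. band_k``.
    """

    values: np.ndarray
    lon_west: float
    lat_north: float
    cell_size: float
    band_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ConfigurationError("raster values must be 2-D or 3-D")
        if self.cell_size <= 0:
            raise ConfigurationError("cell size must be positive")
        if not self.band_names:
            self.band_names = tuple(
                f"band_{i + 1}" for i in range(self.n_bands)
            )
        if len(self.band_names) != self.n_bands:
            raise ConfigurationError(
                f"{len(self.band_names)} band names for {self.n_bands} bands"
            )
        self.band_names = tuple(self.band_names)

    # -- shape/georeference -------------------------------------------------
    @property
    def n_bands(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]

    @property
    def n_rows(self) -> int:
        return self.values.shape[-2]

    @property
    def n_cols(self) -> int:
        return self.values.shape[-1]

    @property
    def lat_south(self) -> float:
        return self.lat_north - self.n_rows * self.cell_size

    @property
    def lon_east(self) -> float:
        return self.lon_west + self.n_cols * self.cell_size

    def band(self, name: str) -> np.ndarray:
        """Return one band as a 2-D view by name."""
        try:
            i = self.band_names.index(name)
        except ValueError:
            raise KeyError(f"no band named {name!r}; have {self.band_names}")
        return self.values if self.values.ndim == 2 else self.values[i]

    def lon_centers(self) -> np.ndarray:
        return self.lon_west + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes ordered north to south (row order)."""
        return self.lat_north - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_of(self, lon, lat):
        """Map point coordinates to (row, col) under the half-open convention.

        Points outside the grid get index -1 in the offending axis.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_west) / self.cell_size).astype(int)
        row_s = np.floor((lat - self.lat_south) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_s
        bad_col = (col < 0) | (col >= self.n_cols)
        bad_row = (row < 0) | (row >= self.n_rows)
        col = np.where(bad_col, -1, col)
        row = np.where(bad_row, -1, row)
        return row, col

    def center_of(self, row, col):
        """Cell-center (lon, lat) for integer indices."""
        lon = self.lon_west + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.lat_north - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def cell_area_km2(self) -> np.ndarray:
        """Per-row spherical cell area (km^2), broadcast to the grid shape."""
        dlat = np.deg2rad(self.cell_size)
        lat = np.deg2rad(self.lat_centers())
        area_row = EARTH_RADIUS_KM**2 * dlat * dlat * np.cos(lat)
        return np.repeat(area_row[:, None], self.n_cols, axis=1)

    # -- structural helpers -------------------------------------------------
    def same_georeference(self, other: "RasterGrid", atol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.lon_west - other.lon_west) <= atol
            and abs(self.lat_north - other.lat_north) <= atol
            and abs(self.cell_size - other.cell_size) <= atol
        )

    def require_aligned(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.same_georeference(other):
            raise AlignmentError(
                f"{what} is not aligned: "
                f"({self.n_rows}x{self.n_cols}, W={self.lon_west}, "
                f"N={self.lat_north}, d={self.cell_size}) vs "
                f"({other.n_rows}x{other.n_cols}, W={other.lon_west}, "
                f"N={other.lat_north}, d={other.cell_size})"
            )

    def with_values(self, values: np.ndarray, band_names=None) -> "RasterGrid":
        """New grid sharing this georeference."""
        return replace(
            self,
            values=np.asarray(values),
            band_names=tuple(band_names) if band_names else (),
        )

    def copy(self) -> "RasterGrid":
        return replace(self, values=self.values.copy())


def stack_bands(grids: list[RasterGrid], names: list[str]) -> RasterGrid:
    """Stack single-band grids into one multi-band grid (alignment checked)."""
    first = grids[0]
    arrs = []
    for g, n in zip(grids, names):
        first.require_aligned(g, what=f"band {n}")
        if g.values.ndim != 2:
            raise ConfigurationError("stack_bands expects single-band grids")
        arrs.append(g.values)
    return first.with_values(np.stack(arrs), band_names=names)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


# -- GeoTIFF I/O -------------------------------------------------------------

def write_raster(grid: RasterGrid, path) -> None:
    """Write a :class:`RasterGrid` to a GeoTIFF (one page per band)."""
    geokeys = (
        1, 1, 0, 3,                      # directory header, 3 keys
        1024, 0, 1, _MODEL_TYPE_GEOGRAPHIC,  # GTModelType = geographic
        1025, 0, 1, 1,                   # GTRasterType = PixelIsArea
        2048, 0, 1, _GCS_WGS84,          # GeographicType = WGS84
    )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.lon_west, grid.lat_north, 0.0)),
        (_TAG_GEOKEYS, "H", len(geokeys), geokeys),
    ]
    description = json.dumps({"band_names": list(grid.band_names)})
    data = grid.values if grid.values.ndim == 3 else grid.values[None, :, :]
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        description=description,
        extratags=extratags,
        metadata=None,
    )


def read_raster(path) -> RasterGrid:
    """Read a geographic GeoTIFF written by :func:`write_raster` (or alike)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _TAG_GEOKEYS in tags:
            keys = np.asarray(tags[_TAG_GEOKEYS].value).ravel()
            model_type = None
            for i in range(4, len(keys) - 3, 4):
                if keys[i] == 1024:
                    model_type = int(keys[i + 3])
            if model_type is not None and model_type != _MODEL_TYPE_GEOGRAPHIC:
                raise UnsupportedCRSError(
                    f"{path}: only geographic (lon/lat) rasters are supported"
                )
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise UnsupportedCRSError(f"{path}: missing GeoTIFF georeference tags")
        scale = np.asarray(tags[_TAG_PIXEL_SCALE].value, dtype=float)
        tie = np.asarray(tags[_TAG_TIEPOINT].value, dtype=float)
        if abs(scale[0] - scale[1]) > 1e-12:
            raise UnsupportedCRSError(f"{path}: non-square cells unsupported")
        band_names = ()
        desc = page.description or ""
        try:
            meta = json.loads(desc)
            band_names = tuple(meta.get("band_names", ()))
        except (json.JSONDecodeError, AttributeError):
            pass
        values = tif.asarray()
    if values.ndim == 3 and values.shape[0] == 1 and len(band_names) <= 1:
        values = values[0]
    return RasterGrid(
        values=values,
        lon_west=float(tie[3]),
        lat_north=float(tie[4]),
        cell_size=float(scale[0]),
        band_names=band_names,
    )
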