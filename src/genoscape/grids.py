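"""Georeferenced grid containers and GeoTIFF input/output.

Conventions used throughout the package (chosen once, applied everywhere):

* grids are 0-based, row-major ``(row, col)`` arrays; row 0 is the
  *northern* edge;
* the geotransform is ``(x_origin, y_origin, cell_size)`` where
  ``(x_origin, y_origin)`` is the *top-left corner* of cell ``(0, 0)``
  and ``cell_size`` is in degrees (square cells);
* the centre of cell ``(r, c)`` is
  ``(x_origin + (c + 0.5) * cell_size, y_origin - (r + 0.5) * cell_size)``;
* the CRS is geographic WGS84 (EPSG:4326).

GeoTIFFs are written with the standard ModelPixelScale / ModelTiepoint /
GeoKeyDirectory tags so the files open correctly in GDAL-based tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["GridSpec", "EnvStack", "write_geotiff", "read_geotiff"]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKeyDirectory: version 1.1.0, 3 keys:
#   GTModelTypeGeoKey = 2 (geographic), GTRasterTypeGeoKey = 1 (PixelIsArea),
#   GeographicTypeGeoKey = 4326 (WGS84)
_GEOKEYS_WGS84 = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


@dataclass(frozen=True)
class GridSpec:
    """Geometry shared by every raster in one analysis."""

    rows: int
    cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.rows}x{self.cols}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude and latitude of every cell centre, each shaped (rows, cols)."""
        xs = self.x_origin + (np.arange(self.cols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(self.rows) + 0.5) * self.cell_size
        lon, lat = np.meshgrid(xs, ys)
        return lon, lat

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell index containing a point; half-open cells [x, x+cs) x (y-cs, y]."""
        c = int(np.floor((lon - self.x_origin) / self.cell_size))
        r = int(np.floor((self.y_origin - lat) / self.cell_size))
        if not (0 <= r < self.rows and 0 <= c < self.cols):
            raise ValueError(f"point ({lon}, {lat}) falls outside the grid")
        return r, c

    def matches(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class EnvStack:
    """Named multi-layer raster stack for one time point.

    ``data`` has shape ``(n_layers, rows, cols)``; ``mask`` is True where
    cells are valid (nodata cells are False and carry NaN in ``data``).
    """

    grid: GridSpec
    layer_names: list[str]
    data: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_layers, rows, cols)")
        if self.data.shape != (len(self.layer_names), self.grid.rows, self.grid.cols):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.layer_names)} layers on {self.grid.shape}"
            )
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("layer names must be unique")
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape must match the grid")

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    def layer(self, name: str) -> np.ndarray:
        try:
            i = self.layer_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown layer {name!r}; available: {', '.join(self.layer_names)}"
            ) from None
        return self.data[i]

    def values_at(self, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
        """Layer values at point locations, shaped (n_points, n_layers)."""
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        out = np.empty((lons.size, self.n_layers))
        for k, (lo, la) in enumerate(zip(lons, lats)):
            r, c = self.grid.index_of(lo, la)
            out[k] = self.data[:, r, c]
        return out

    def copy(self) -> "EnvStack":
        return EnvStack(self.grid, list(self.layer_names), self.data.copy(), self.mask.copy())


def _geo_extratags(grid: GridSpec, nodata: str | None = "nan"):
    tags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x_origin, grid.y_origin, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(_GEOKEYS_WGS84), _GEOKEYS_WGS84),
    ]
    if nodata is not None:
        tags.append((_GDAL_NODATA, "s", 0, nodata))
    return tags


def write_geotiff(
    path,
    data: np.ndarray,
    grid: GridSpec,
    description: str = "",
    dtype=None,
) -> None:
    """Write a single- or multi-band GeoTIFF.

    ``data`` is (rows, cols) or (bands, rows, cols). Byte data (e.g. RGB or
    class rasters) is written without a nodata tag; float data uses NaN.
    """
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[1:] != grid.shape:
        raise ValueError(f"data shape {arr.shape} does not match grid {grid.shape}")
    is_float = np.issubdtype(arr.dtype, np.floating)
    extratags = _geo_extratags(grid, "nan" if is_float else None)
    photometric = "rgb" if (arr.dtype == np.uint8 and arr.shape[0] == 3) else "minisblack"
    # band-interleaved-by-pixel for RGB, separate planes otherwise
    if photometric == "rgb":
        out = np.moveaxis(arr, 0, -1)
        planarconfig = None
    else:
        out = arr[0] if arr.shape[0] == 1 else arr
        planarconfig = "separate" if arr.shape[0] > 1 else None
    tifffile.imwrite(
        path,
        out,
        photometric=photometric,
        planarconfig=planarconfig,
        extratags=extratags,
        description=description,
        metadata=None,
    )


def read_geotiff(path) -> tuple[np.ndarray, GridSpec, str]:
    """Read a GeoTIFF written by :func:`write_geotiff`.

    Returns ``(data, grid, description)`` with data shaped (bands, rows, cols).
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = tif.asarray()
        scale = page.tags[_MODEL_PIXEL_SCALE].value
        tiepoint = page.tags[_MODEL_TIEPOINT].value
        desc_tag = page.tags.get("ImageDescription")
        description = desc_tag.value if desc_tag is not None else ""
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
        arr = np.moveaxis(arr, -1, 0)  # RGB pixel-interleaved -> band-major
    grid = GridSpec(
        rows=arr.shape[1],
        cols=arr.shape[2],
        x_origin=float(tiepoint[3]),
        y_origin=float(tiepoint[4]),
        cell_size=float(scale[0]),
    )
    return arr, grid, description
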