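"""Raster layers and stacks: reading, writing, alignment, and cell geometry.

All spatial conventions for the package live here.  Grids are on WGS84
decimal degrees, edge-registered, with row 0 the northernmost row and
square cells.  Cell (r, c) spans the half-open box
``[x_min + c*s, x_min + (c+1)*s) x (y_max - (r+1)*s, y_max - r*s]``.

Two on-disk formats are supported: ESRI ASCII grid (the
NCOLS/NROWS/XLLCORNER/YLLCORNER/CELLSIZE/NODATA_VALUE header dialect) and
GeoTIFF (plain TIFF carrying the ModelPixelScale, ModelTiepoint and
GDAL_NODATA tags).  Geometry mismatches between layers are errors; this
module never resamples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

EARTH_RADIUS_KM = 6371.0088

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0

#: Layer labels used for the bioclimatic + soil variable set; free-form
#: names are equally legal, these are just the conventional codes.
STANDARD_LAYER_NAMES = (
    [f"BIO{i}" for i in range(1, 20)] + ["AWC", "OM", "pH", "Elevation"]
)


class GridFormatError(ValueError):
    """Raised when a raster file does not parse in the named format."""


class AlignmentError(ValueError):
    """Raised when layer geometries that must match do not."""


@dataclass
class Grid:
    """One georeferenced raster layer.

    Parameters
    ----------
    values
        2-D float array, shape (n_rows, n_cols).  Cells equal to
        ``nodata`` are missing.
    x_min, y_max
        Western and northern outer edges, decimal degrees (WGS84).
    cell_size
        Degrees per (square) cell.
    nodata
        Sentinel for missing cells.
    name
        Layer label, e.g. ``"BIO11"``.
    """

    values: np.ndarray
    x_min: float
    y_max: float
    cell_size: float
    nodata: float = DEFAULT_NODATA
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.cell_size

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata (or non-finite)."""
        return ~np.isfinite(self.values) | (self.values == self.nodata)

    def geometry(self) -> tuple[int, int, float, float, float]:
        return (self.n_rows, self.n_cols, self.x_min, self.y_max, self.cell_size)

    def same_geometry(self, other: "Grid") -> bool:
        a, b = self.geometry(), other.geometry()
        return a[:2] == b[:2] and all(
            math.isclose(x, y, rel_tol=0, abs_tol=1e-9) for x, y in zip(a[2:], b[2:])
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Return (row, col) containing the point, or None if outside.

        Half-open convention: a point on a shared edge belongs to the
        cell east/south of it.
        """
        c = math.floor((lon - self.x_min) / self.cell_size)
        r = math.floor((self.y_max - lat) / self.cell_size)
        if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
            return r, c
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.x_min + (col + 0.5) * self.cell_size
        lat = self.y_max - (row + 0.5) * self.cell_size
        return lon, lat

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row's cell centers, north to south."""
        r = np.arange(self.n_rows)
        return self.y_max - (r + 0.5) * self.cell_size

    def lon_centers(self) -> np.ndarray:
        c = np.arange(self.n_cols)
        return self.x_min + (c + 0.5) * self.cell_size

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Grid":
        """Copy of this grid's geometry carrying new values."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            name=self.name if name is None else name,
        )


@dataclass
class LayerStack:
    """Named, spatially aligned grids for one time slice / scenario."""

    layers: dict[str, Grid] = field(default_factory=dict)
    scenario_tag: str = "current"

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        for g in grids[1:]:
            if not g.same_geometry(grids[0]):
                raise AlignmentError(
                    f"layer {g.name!r} geometry differs from {grids[0].name!r}"
                )

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> Grid:
        return next(iter(self.layers.values()))

    def common_mask(self) -> np.ndarray:
        """Union (elementwise OR) of every member's nodata mask."""
        m = np.zeros(self.template.values.shape, dtype=bool)
        for g in self.layers.values():
            m |= g.mask
        return m

    def value_table(self, rows: np.ndarray, cols: np.ndarray,
                    variables: list[str] | None = None) -> np.ndarray:
        """Stack layer values at cells into an (n_points, n_layers) array."""
        names = variables if variables is not None else self.names
        return np.column_stack([self.layers[n].values[rows, cols] for n in names])


def align_stack(grids: list[Grid], scenario_tag: str = "current") -> LayerStack:
    """Validate exact geometry agreement and assemble a LayerStack.

    Rejects (never resamples) mismatched grids, naming the offending
    fields.  Values are untouched; the stack-level nodata mask is the
    union of the member masks.
    """
    if not grids:
        raise ValueError("need at least one grid")
    ref = grids[0]
    fields = ("n_rows", "n_cols", "x_min", "y_max", "cell_size")
    for g in grids[1:]:
        bad = [
            f for f, a, b in zip(fields, ref.geometry(), g.geometry())
            if not math.isclose(a, b, rel_tol=0, abs_tol=1e-9)
        ]
        if bad:
            raise AlignmentError(
                f"grid {g.name!r} does not align with {ref.name!r}: "
                f"mismatched {', '.join(bad)}"
            )
    names = [g.name for g in grids]
    if len(set(names)) != len(names):
        raise ValueError("duplicate layer names in stack")
    return LayerStack({g.name: g for g in grids}, scenario_tag=scenario_tag)


def cell_area_km2(grid: Grid, row: int, nominal_km2: float | None = None) -> float:
    """Area of any cell in the given row, in km².

    Spherical-earth closed form ``A = R² · Δλ · (sin φ_top − sin φ_bot)``
    with R = 6371.0088 km; equatorial 2.5-arc-minute cells come out near
    21.5 km² and shrink with |latitude|.  Passing ``nominal_km2`` returns
    that constant instead (a fixed nominal area per cell), for
    sensitivity checks against per-cell-constant accounting.
    """
    if not 0 <= row < grid.n_rows:
        raise IndexError(f"row {row} out of bounds for {grid.n_rows} rows")
    if nominal_km2 is not None:
        return float(nominal_km2)
    lat_top = grid.y_max - row * grid.cell_size
    lat_bot = lat_top - grid.cell_size
    if lat_top > 90 + 1e-9 or lat_bot < -90 - 1e-9:
        raise ValueError("cell extends beyond +/-90 degrees latitude")
    dlon = math.radians(grid.cell_size)
    return (
        EARTH_RADIUS_KM ** 2
        * dlon
        * (math.sin(math.radians(lat_top)) - math.sin(math.radians(lat_bot)))
    )


def row_areas_km2(grid: Grid, nominal_km2: float | None = None) -> np.ndarray:
    """Vector of per-row cell areas (km²), north to south."""
    return np.array(
        [cell_area_km2(grid, r, nominal_km2=nominal_km2) for r in range(grid.n_rows)]
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

_ASCII_REQUIRED = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_esri_ascii(path: str, name: str) -> Grid:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (*_ASCII_REQUIRED, "nodata_value", "dx", "dy"):
                if len(parts) != 2:
                    raise GridFormatError(f"malformed header line {line!r} in {path}")
                try:
                    header[key] = float(parts[1])
                except ValueError as exc:
                    raise GridFormatError(
                        f"header field {key!r} is not numeric in {path}"
                    ) from exc
            else:
                data_lines.append(line)
    for k in _ASCII_REQUIRED:
        if k not in header:
            raise GridFormatError(f"missing header field {k!r} in {path}")
    if "dx" in header or "dy" in header:
        if header.get("dx") != header.get("dy"):
            raise GridFormatError(f"non-square cells (dx != dy) in {path}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    try:
        values = np.fromstring(" ".join(data_lines), sep=" ")
    except Exception as exc:  # pragma: no cover - numpy raises rarely here
        raise GridFormatError(f"unparseable data block in {path}") from exc
    if values.size != nrows * ncols:
        raise GridFormatError(
            f"data block has {values.size} values, expected {nrows * ncols} in {path}"
        )
    cell = header["cellsize"]
    return Grid(
        values=values.reshape(nrows, ncols),
        x_min=header["xllcorner"],
        y_max=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        nodata=nodata,
        name=name,
    )


def _write_esri_ascii(grid: Grid, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_min!r}\n")
        fh.write(f"yllcorner {grid.y_min!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GeoTIFF (via tifffile + standard geo tags)
# ---------------------------------------------------------------------------

def _read_geotiff(path: str, name: str) -> Grid:
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = page.tags
            scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
            tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
            nodata_tag = tags.get(_TAG_GDAL_NODATA)
            scale_v = None if scale is None else tuple(scale.value)
            tiepoint_v = None if tiepoint is None else tuple(tiepoint.value)
            nodata_v = None if nodata_tag is None else str(nodata_tag.value)
    except (tifffile.TiffFileError, OSError) as exc:
        raise GridFormatError(f"not a readable TIFF: {path} ({exc})") from exc
    if scale_v is None or tiepoint_v is None:
        raise GridFormatError(
            f"missing georeferencing tags (ModelPixelScale/ModelTiepoint) in {path}"
        )
    sx, sy = float(scale_v[0]), float(scale_v[1])
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise GridFormatError(f"non-square cells ({sx} x {sy}) in {path}")
    # tiepoint maps raster (i, j) = (0, 0) to the upper-left outer corner
    x_min, y_max = float(tiepoint_v[3]), float(tiepoint_v[4])
    nodata = float(nodata_v) if nodata_v is not None else DEFAULT_NODATA
    if values.ndim != 2:
        raise GridFormatError(f"expected single-band raster in {path}")
    return Grid(
        values=np.asarray(values, dtype=float),
        x_min=x_min,
        y_max=y_max,
        cell_size=sx,
        nodata=nodata,
        name=name,
    )


def _write_geotiff(grid: Grid, path: str) -> None:
    s = grid.cell_size
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x_min, grid.y_max, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)),
    ]
    tifffile.imwrite(path, grid.values.astype(np.float64), extratags=extratags)


# ---------------------------------------------------------------------------
# public read/write
# ---------------------------------------------------------------------------

_FORMATS = ("geotiff", "esri_ascii")


def _infer_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith((".tif", ".tiff")):
        return "geotiff"
    if p.endswith((".asc", ".txt", ".grd")):
        return "esri_ascii"
    raise GridFormatError(f"cannot infer raster format from extension of {path}")


def read_grid(path, format: str | None = None, name: str | None = None) -> Grid:
    """Read a raster layer from disk.

    ``format`` is ``"geotiff"`` or ``"esri_ascii"``; inferred from the
    file extension when omitted.  ``name`` defaults to the file stem.
    """
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    import os

    label = name if name is not None else os.path.splitext(os.path.basename(path))[0]
    if fmt == "esri_ascii":
        return _read_esri_ascii(str(path), label)
    return _read_geotiff(str(path), label)


def write_grid(grid: Grid, path, format: str | None = None):
    """Write a grid so that :func:`read_grid` recovers values + metadata."""
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "esri_ascii":
        _write_esri_ascii(grid, str(path))
    else:
        _write_geotiff(grid, str(path))
    return path
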