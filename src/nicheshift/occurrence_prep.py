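"""Occurrence-record cleaning and spatial thinning.

Presence records arrive as delimited text (GBIF-style exports) with a
species name and decimal-degree coordinates.  Cleaning flags — never
silently drops — unparseable or out-of-bounds coordinates, exact
duplicates, and records outside the study extent, then thins the kept
records to at most one per grid cell to reduce sampling bias ("one
record per cell" resampling).  Every record ends up with exactly one
flag, so flag counts always sum to the raw record count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid_io import Grid

FLAGS = ("kept", "duplicate", "out_of_extent", "thinned", "invalid")

# Darwin Core column names auto-detected when lon/lat columns not given
_AUTO_LON = ("decimalLongitude", "longitude", "lon", "x")
_AUTO_LAT = ("decimalLatitude", "latitude", "lat", "y")


@dataclass
class OccurrenceRecord:
    species: str
    lon: float
    lat: float
    source: str = ""
    flag: str = "kept"

    @property
    def retained(self) -> bool:
        return self.flag == "kept"


@dataclass
class OccurrenceSet:
    """Presence records for one species, each carrying a provenance flag."""

    records: list[OccurrenceRecord]
    species: str
    thinning_grid: tuple | None = None  # geometry of the grid used to thin

    @property
    def kept(self) -> list[OccurrenceRecord]:
        return [r for r in self.records if r.retained]

    def flag_counts(self) -> dict[str, int]:
        counts = {f: 0 for f in FLAGS}
        for r in self.records:
            counts[r.flag] += 1
        return counts

    def coords(self) -> np.ndarray:
        """(n_kept, 2) array of kept (lon, lat)."""
        return np.array([(r.lon, r.lat) for r in self.kept]).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species for r in self.records],
                "lon": [r.lon for r in self.records],
                "lat": [r.lat for r in self.records],
                "source": [r.source for r in self.records],
                "flag": [r.flag for r in self.records],
            }
        )


class SchemaError(KeyError):
    """A required column is missing from the input table."""


def _detect_column(columns, requested, candidates, kind):
    if requested is not None:
        if requested not in columns:
            raise SchemaError(f"{kind} column {requested!r} not found in input")
        return requested
    for c in candidates:
        for col in columns:
            if col.lower() == c.lower():
                return col
    raise SchemaError(f"could not auto-detect a {kind} column among {list(columns)}")


def load_occurrences(
    path,
    species: str | None = None,
    lon_col: str | None = None,
    lat_col: str | None = None,
    species_col: str | None = None,
    sep: str | None = None,
) -> OccurrenceSet:
    """Load records from CSV/TSV; unparseable coordinates are flagged.

    Records with non-numeric or out-of-range coordinates get the
    ``invalid`` flag (coordinates stored as NaN) rather than being
    dropped, so counts are conserved.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    lon_col = _detect_column(df.columns, lon_col, _AUTO_LON, "longitude")
    lat_col = _detect_column(df.columns, lat_col, _AUTO_LAT, "latitude")
    if species_col is None:
        species_col = next(
            (c for c in df.columns if c.lower() in ("species", "scientificname")), None
        )
    if species is None:
        if species_col is None or df.empty:
            species = "unknown"
        else:
            species = str(df[species_col].iloc[0])
    elif species_col is not None:
        df = df[df[species_col].astype(str) == species]

    lons = pd.to_numeric(df[lon_col], errors="coerce")
    lats = pd.to_numeric(df[lat_col], errors="coerce")
    records = []
    for i, (lo, la) in enumerate(zip(lons, lats)):
        ok = (
            np.isfinite(lo) and np.isfinite(la)
            and -180 <= lo <= 180 and -90 <= la <= 90
        )
        records.append(
            OccurrenceRecord(
                species=species,
                lon=float(lo) if np.isfinite(lo) else float("nan"),
                lat=float(la) if np.isfinite(la) else float("nan"),
                source=str(path),
                flag="kept" if ok else "invalid",
            )
        )
    return OccurrenceSet(records=records, species=species)


def dedupe_and_clip(occ: OccurrenceSet, extent=None, decimals: int = 6) -> OccurrenceSet:
    """Flag exact coordinate duplicates and records outside the extent.

    Coordinates are rounded to ``decimals`` places before duplicate
    comparison.  ``extent`` is (lon_min, lat_min, lon_max, lat_max) or a
    shapely geometry; records outside get ``out_of_extent``.  The first
    record at a coordinate wins; later copies are ``duplicate``.
    """
    seen: set[tuple[float, float]] = set()
    out: list[OccurrenceRecord] = []
    contains = _extent_predicate(extent)
    for r in occ.records:
        if not r.retained:
            out.append(r)
            continue
        if not contains(r.lon, r.lat):
            out.append(replace(r, flag="out_of_extent"))
            continue
        key = (round(r.lon, decimals), round(r.lat, decimals))
        if key in seen:
            out.append(replace(r, flag="duplicate"))
        else:
            seen.add(key)
            out.append(r)
    result = OccurrenceSet(out, occ.species, occ.thinning_grid)
    if not result.kept:
        import warnings

        warnings.warn("no records remain after dedupe/clip", stacklevel=2)
    return result


def _extent_predicate(extent):
    if extent is None:
        return lambda lon, lat: True
    if hasattr(extent, "contains"):  # shapely geometry
        from shapely.geometry import Point

        return lambda lon, lat: bool(extent.contains(Point(lon, lat)))
    lon_min, lat_min, lon_max, lat_max = extent
    return lambda lon, lat: lon_min <= lon <= lon_max and lat_min <= lat <= lat_max


def thin_to_grid(occ: OccurrenceSet, grid: Grid, seed: int) -> OccurrenceSet:
    """Thin kept records to one per occupied grid cell.

    Cell assignment uses the half-open edge convention of
    :meth:`Grid.cell_of`.  Within a cell the surviving record is chosen
    uniformly at random under ``seed``.  Records landing in nodata cells
    (or off the grid) are flagged ``out_of_extent``.  Idempotent: a
    thinned set thins to itself.
    """
    rng = np.random.default_rng(seed)
    mask = grid.mask
    by_cell: dict[tuple[int, int], list[int]] = {}
    out = list(occ.records)
    for i, r in enumerate(occ.records):
        if not r.retained:
            continue
        cell = grid.cell_of(r.lon, r.lat)
        if cell is None or mask[cell]:
            out[i] = replace(r, flag="out_of_extent")
            continue
        by_cell.setdefault(cell, []).append(i)
    for cell in sorted(by_cell):
        idx = by_cell[cell]
        survivor = idx[0] if len(idx) == 1 else idx[rng.integers(len(idx))]
        for i in idx:
            if i != survivor:
                out[i] = replace(out[i], flag="thinned")
    return OccurrenceSet(out, occ.species, thinning_grid=grid.geometry())


def occurrence_cells(occ: OccurrenceSet, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of kept records on ``grid`` (records off-grid error)."""
    rows, cols = [], []
    for r in occ.kept:
        cell = grid.cell_of(r.lon, r.lat)
        if cell is None:
            raise ValueError(f"kept record at ({r.lon}, {r.lat}) is off the grid")
        rows.append(cell[0])
        cols.append(cell[1])
    return np.array(rows, dtype=int), np.array(cols, dtype=int)
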