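"""Range-change accounting: suitability bands, areas, centroids, shifts.

Suitability maps are cut into five bands — (0, 0.10], (0.10, 0.20],
(0.20, 0.35], (0.35, 0.50], and strictly >0.50 ("highly suitable") —
and the highly-suitable band drives the headline metrics: its area
(spherical km²), the % change between a current and a future map, the
area common to both and the % of the current range retained, and the
geodesic displacement of the range centroid with its compass direction
and per-decade rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_io import EARTH_RADIUS_KM, Grid, row_areas_km2

BAND_EDGES = (0.10, 0.20, 0.35, 0.50)   # right-closed; band 5 is > 0.50
N_BANDS = 5

COMPASS_16 = (
    "N", "NNE", "NE", "ENE", "E", "ESE", "SE", "SSE",
    "S", "SSW", "SW", "WSW", "W", "WNW", "NW", "NNW",
)


@dataclass
class BandedMap:
    source: Grid                 # suitability in [0,1]
    bands: np.ndarray            # int band 1..5, 0 where nodata
    band_areas: dict[int, float]  # km² per band

    @property
    def band5_mask(self) -> np.ndarray:
        return self.bands == 5


def classify_bands(suitability: Grid, nominal_km2: float | None = None) -> BandedMap:
    """Assign each non-nodata cell to one of the five suitability bands.

    Band edges are closed on the right; a cell at exactly 0.50 falls in
    band 4 (band 5 is strictly >50%).  Values outside [0, 1] are a data
    error.
    """
    vals = suitability.values
    mask = suitability.mask
    good = vals[~mask]
    if good.size and (good.min() < 0 or good.max() > 1):
        raise ValueError(
            f"suitability outside [0,1]: range [{good.min()}, {good.max()}]"
        )
    bands = np.zeros(vals.shape, dtype=int)
    bands[~mask] = np.digitize(vals[~mask], BAND_EDGES, right=True) + 1
    areas = row_areas_km2(suitability, nominal_km2=nominal_km2)
    area_grid = np.broadcast_to(areas[:, None], vals.shape)
    band_areas = {
        b: float(area_grid[bands == b].sum()) for b in range(1, N_BANDS + 1)
    }
    return BandedMap(source=suitability, bands=bands, band_areas=band_areas)


def suitable_area(banded: BandedMap) -> float:
    """km² of the highly suitable (>0.50) band."""
    return banded.band_areas[N_BANDS]


def centroid(
    suitability: Grid, mode: str = "weighted", nominal_km2: float | None = None
) -> tuple[float, float]:
    """Geometric center of the range: (lon, lat).

    ``weighted``: mean of cell-center coordinates weighted by
    suitability x cell area over all non-nodata cells.  ``band5_area``:
    cell-area-weighted mean over the highly suitable cells only.
    """
    mask = suitability.mask
    areas = row_areas_km2(suitability, nominal_km2=nominal_km2)
    w = np.where(mask, 0.0, suitability.values) * areas[:, None]
    if mode == "band5_area":
        banded = classify_bands(suitability, nominal_km2=nominal_km2)
        w = np.where(banded.band5_mask, areas[:, None], 0.0)
    elif mode != "weighted":
        raise ValueError(f"unknown centroid mode {mode!r}")
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero weights: centroid undefined")
    lons = suitability.lon_centers()
    lats = suitability.lat_centers()
    lon = float((w.sum(axis=0) @ lons) / total)
    lat = float((w.sum(axis=1) @ lats) / total)
    return lon, lat


def geodesic_shift(a: tuple[float, float], b: tuple[float, float]):
    """Haversine distance (km), initial bearing (deg), and 16-wind label.

    ``a`` and ``b`` are (lon, lat).  Bearing is measured clockwise from
    north at ``a``; the compass rose has 16 sectors of 22.5° centered on
    N, NNE, NE, ...
    """
    lon1, lat1 = map(math.radians, a)
    lon2, lat2 = map(math.radians, b)
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = (
        math.sin(dlat / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    )
    distance = 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))
    y = math.sin(dlon) * math.cos(lat2)
    x = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon)
    bearing = math.degrees(math.atan2(y, x)) % 360.0
    sector = int((bearing + 11.25) // 22.5) % 16
    return distance, bearing, COMPASS_16[sector]


def rate_per_decade(distance_km: float, horizon_year: int, baseline_year: int) -> float:
    """Centroid shift rate, km per decade."""
    if horizon_year <= baseline_year:
        raise ValueError("horizon must be after baseline")
    return distance_km / ((horizon_year - baseline_year) / 10.0)


@dataclass
class RangeComparison:
    area_current: float
    area_future: float
    pct_change: float | None
    area_common: float
    pct_retained: float | None
    centroid_current: tuple[float, float]
    centroid_future: tuple[float, float]
    shift_km: float
    bearing_deg: float
    compass: str
    rate_km_per_decade: float
    horizon_year: int
    baseline_year: int
    undefined: bool = False   # percentages undefined (zero current area)

    def report_row(self) -> dict:
        """Rounded presentation: percentages to 2 decimals, rate to integer."""
        return {
            "area_current_km2": round(self.area_current),
            "area_future_km2": round(self.area_future),
            "pct_change": None if self.pct_change is None else round(self.pct_change, 2),
            "area_common_km2": round(self.area_common),
            "pct_retained": None if self.pct_retained is None else round(self.pct_retained, 2),
            "shift_km": round(self.shift_km),
            "compass": self.compass,
            "rate_km_per_decade": round(self.rate_km_per_decade),
        }


def compare_ranges(
    current: BandedMap,
    future: BandedMap,
    horizon_year: int,
    baseline_year: int = 2010,
    centroid_mode: str = "weighted",
    nominal_km2: float | None = None,
) -> RangeComparison:
    """Highly-suitable-range change between a current and a future map."""
    if not current.source.same_geometry(future.source):
        raise ValueError("current and future maps must share geometry")
    if horizon_year <= baseline_year:
        raise ValueError("baseline year must precede horizon year")
    area_c = suitable_area(current)
    area_f = suitable_area(future)
    areas = row_areas_km2(current.source, nominal_km2=nominal_km2)
    common_mask = current.band5_mask & future.band5_mask
    area_common = float(
        (np.broadcast_to(areas[:, None], common_mask.shape)[common_mask]).sum()
    )
    undefined = area_c <= 0
    pct_change = None if undefined else 100.0 * (area_f - area_c) / area_c
    pct_retained = None if undefined else 100.0 * area_common / area_c
    c_cur = centroid(current.source, mode=centroid_mode, nominal_km2=nominal_km2)
    c_fut = centroid(future.source, mode=centroid_mode, nominal_km2=nominal_km2)
    dist, bearing, compass = geodesic_shift(c_cur, c_fut)
    return RangeComparison(
        area_current=area_c,
        area_future=area_f,
        pct_change=pct_change,
        area_common=area_common,
        pct_retained=pct_retained,
        centroid_current=c_cur,
        centroid_future=c_fut,
        shift_km=dist,
        bearing_deg=bearing,
        compass=compass,
        rate_km_per_decade=rate_per_decade(dist, horizon_year, baseline_year),
        horizon_year=horizon_year,
        baseline_year=baseline_year,
        undefined=undefined,
    )


def _median(values) -> float:
    """Midpoint-convention median (mean of the two central order stats)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("median of empty list")
    mid = v.size // 2
    return float(v[mid]) if v.size % 2 else float(0.5 * (v[mid - 1] + v[mid]))


def summarize_scenarios(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Per-species and pooled medians (with min/max) across scenarios.

    ``comparisons`` needs columns ``species`` plus any of ``pct_change``,
    ``pct_retained``, ``rate_km_per_decade``.
    """
    if comparisons.empty:
        raise ValueError("no comparisons to summarize")
    metrics = [
        c for c in ("pct_change", "pct_retained", "rate_km_per_decade")
        if c in comparisons.columns
    ]
    rows = []
    groups = [("all", comparisons)] + [
        (sp, g) for sp, g in comparisons.groupby("species", sort=True)
    ]
    for label, g in groups:
        row = {"species": label, "n": len(g)}
        for m in metrics:
            vals = g[m].dropna()
            if len(vals):
                row[f"{m}_median"] = _median(vals)
                row[f"{m}_min"] = float(vals.min())
                row[f"{m}_max"] = float(vals.max())
        rows.append(row)
    return pd.DataFrame(rows)


def suitable_range_from_curve(
    curve: pd.DataFrame, threshold: float = 0.5
) -> list[tuple[float, float]]:
    """Maximal intervals of a response curve where suitability > threshold.

    Endpoints between curve points are linearly interpolated.  An empty
    list (never above threshold) is a valid result.
    """
    if len(curve) < 2:
        raise ValueError("curve needs at least 2 points")
    x = curve["value"].to_numpy(dtype=float)
    y = curve["suitability"].to_numpy(dtype=float)
    above = y > threshold
    intervals = []
    lo = None
    for i in range(len(x)):
        if above[i] and lo is None:
            if i == 0:
                lo = x[0]
            else:
                t = (threshold - y[i - 1]) / (y[i] - y[i - 1])
                lo = x[i - 1] + t * (x[i] - x[i - 1])
        elif not above[i] and lo is not None:
            t = (threshold - y[i - 1]) / (y[i] - y[i - 1])
            intervals.append((lo, x[i - 1] + t * (x[i] - x[i - 1])))
            lo = None
    if lo is not None:
        intervals.append((lo, x[-1]))
    return intervals
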