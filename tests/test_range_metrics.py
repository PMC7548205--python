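"""Suitability bands, range-change accounting, centroid shifts, medians."""

import numpy as np
import pandas as pd
import pytest

from nicheshift import datasets
from nicheshift.grid_io import Grid, cell_area_km2, row_areas_km2
from nicheshift.range_metrics import (
    classify_bands, centroid, compare_ranges, geodesic_shift, rate_per_decade,
    suitable_area, suitable_range_from_curve, summarize_scenarios, _median,
)


def _suit(values, **kw):
    values = np.asarray(values, dtype=float)
    kw.setdefault("x_min", 0.0)
    kw.setdefault("y_max", float(values.shape[0]))
    kw.setdefault("cell_size", 1.0)
    return Grid(values=values, **kw)


class TestBands:
    def test_band_assignments_at_boundaries(self):
        g = _suit([[0.55, 0.50, 0.0, 0.10, 0.101, 0.20, 0.35, 0.36]])
        b = classify_bands(g)
        assert b.bands.tolist()[0] == [5, 4, 1, 1, 2, 2, 3, 4]

    def test_histogram_matches_brute_force(self):
        rng = np.random.default_rng(0)
        g = _suit(rng.uniform(size=(30, 30)))
        b = classify_bands(g)
        edges = [0.0, 0.10, 0.20, 0.35, 0.50, 1.0]
        for band in range(1, 6):
            lo, hi = edges[band - 1], edges[band]
            brute = ((g.values > lo) & (g.values <= hi)).sum()
            if band == 1:
                brute = (g.values <= hi).sum()
            assert (b.bands == band).sum() == brute

    def test_out_of_range_value_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            classify_bands(_suit([[1.2]]))

    def test_band_areas_partition_total(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(size=(20, 20))
        vals[0, :5] = -9999.0
        g = _suit(vals, nodata=-9999.0)
        b = classify_bands(g)
        areas = row_areas_km2(g)
        total = sum(
            areas[r] for r in range(20) for c in range(20)
            if vals[r, c] != -9999.0
        )
        assert sum(b.band_areas.values()) == pytest.approx(total, rel=1e-12)


class TestSuitableArea:
    def test_none_above_half(self):
        assert suitable_area(classify_bands(_suit(np.full((4, 4), 0.3)))) == 0.0

    def test_all_above_half(self):
        g = _suit(np.full((4, 4), 0.9))
        assert suitable_area(classify_bands(g)) == pytest.approx(
            row_areas_km2(g).sum() * 4, rel=1e-12
        )

    def test_scattered_cells_match_closed_form_sum(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(size=(15, 15))
        g = _suit(vals, y_max=45.0, cell_size=1.0)
        area = suitable_area(classify_bands(g))
        oracle = sum(
            cell_area_km2(g, r)
            for r in range(15) for c in range(15) if vals[r, c] > 0.5
        )
        assert area == pytest.approx(oracle, rel=1e-12)

    def test_band5_area_invariant_under_edge_fixing_recalibration(self):
        rng = np.random.default_rng(3)
        g = _suit(rng.uniform(size=(10, 10)))
        base = suitable_area(classify_bands(g))
        # strictly monotone map fixing all band edges
        edges = np.array([0.0, 0.10, 0.20, 0.35, 0.50, 1.0])
        recal = _suit(np.interp(g.values, edges, edges**1.0) ** 1.0)
        warped = np.copy(g.values)
        inside = (warped > 0.5)
        warped[inside] = 0.5 + (warped[inside] - 0.5) ** 1.3 * 0.5 ** -0.3
        assert suitable_area(classify_bands(_suit(warped))) == pytest.approx(base)


class TestCompareRanges:
    def test_published_area_arithmetic_16_95(self):
        df = datasets.derived_range_metrics()
        row = df[(df.species == "Rhapidophyllum hystrix")
                 & (df.scenario == "2050-RCP2.6")].iloc[0]
        assert round(row["pct_change"], 2) == 16.95

    def test_published_retention_arithmetic_17_46(self):
        df = datasets.derived_range_metrics()
        row = df[(df.species == "Sabal etonia")
                 & (df.scenario == "2070-RCP8.5")].iloc[0]
        assert round(row.pct_retained, 2) == 17.46

    def test_identity_comparison(self):
        rng = np.random.default_rng(4)
        g = _suit(rng.uniform(size=(12, 12)))
        b = classify_bands(g)
        comp = compare_ranges(b, b, horizon_year=2070, baseline_year=2010)
        assert comp.pct_change == pytest.approx(0.0, abs=1e-12)
        assert comp.pct_retained == pytest.approx(100.0, abs=1e-12)
        assert comp.shift_km == pytest.approx(0.0, abs=1e-9)

    def test_common_area_symmetric_retention_not(self):
        rng = np.random.default_rng(5)
        a = classify_bands(_suit(rng.uniform(size=(12, 12))))
        b = classify_bands(_suit(rng.uniform(size=(12, 12))))
        ab = compare_ranges(a, b, 2070)
        ba = compare_ranges(b, a, 2070)
        assert ab.area_common == pytest.approx(ba.area_common, rel=1e-12)
        assert ab.pct_retained != ba.pct_retained
        assert ab.area_common <= min(ab.area_current, ab.area_future) + 1e-9

    def test_zero_current_area_flagged_not_nan(self):
        cur = classify_bands(_suit(np.full((5, 5), 0.2)))
        fut = classify_bands(_suit(np.full((5, 5), 0.9)))
        comp = compare_ranges(cur, fut, 2070)
        assert comp.undefined
        assert comp.pct_change is None and comp.pct_retained is None


class TestCentroid:
    def test_symmetric_about_meridian(self):
        vals = np.zeros((5, 5))
        vals[:, 1] = vals[:, 3] = 0.8
        lon, _ = centroid(_suit(vals))
        assert lon == pytest.approx(2.5)   # x_min=0, cells 1 deg; meridian at 2.5

    def test_two_cell_latitude_weighting(self):
        # equal suitability at lat centers 10.5 and 20.5: the centroid sits
        # slightly south of the midpoint because southern cells are larger
        vals = np.zeros((21, 1))
        vals[0, 0] = 1.0    # lat 20.5
        vals[10, 0] = 1.0   # lat 10.5
        g = _suit(vals, y_max=21.0)
        _, lat = centroid(g)
        a_north = cell_area_km2(g, 0)
        a_south = cell_area_km2(g, 10)
        oracle = (20.5 * a_north + 10.5 * a_south) / (a_north + a_south)
        assert lat == pytest.approx(oracle, rel=1e-12)
        assert lat < 15.5

    def test_single_positive_cell(self):
        vals = np.zeros((4, 4))
        vals[1, 2] = 0.7
        lon, lat = centroid(_suit(vals))
        assert (lon, lat) == (2.5, 2.5)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            centroid(_suit(np.zeros((3, 3))))


class TestGeodesics:
    def test_zero_distance(self):
        d, _, _ = geodesic_shift((-82.0, 28.0), (-82.0, 28.0))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_one_degree_north(self):
        d, bearing, compass = geodesic_shift((-82.0, 28.0), (-82.0, 29.0))
        assert d == pytest.approx(111.19, abs=0.01)
        assert bearing == pytest.approx(0.0, abs=1e-9)
        assert compass == "N"

    @pytest.mark.parametrize("bearing,label", [
        (0, "N"), (30, "NNE"), (44.9, "NE"), (90, "E"), (180, "S"),
        (270, "W"), (348.74, "NNW"), (348.76, "N"), (11.24, "N"), (11.26, "NNE"),
    ])
    def test_compass_sectors(self, bearing, label):
        from nicheshift.range_metrics import COMPASS_16
        sector = int((bearing + 11.25) // 22.5) % 16
        assert COMPASS_16[sector] == label

    def test_rates_from_published_distances(self):
        assert rate_per_decade(840, 2070, 2010) == pytest.approx(140)
        assert rate_per_decade(429, 2050, 2010) == pytest.approx(107.25, abs=0.01)
        assert round(rate_per_decade(429, 2050, 2010)) == 107
        assert rate_per_decade(0, 2070, 2010) == 0.0


class TestSummaries:
    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(6)
        for n in (1, 2, 5, 8, 20):
            vals = rng.normal(size=n)
            s = np.sort(vals)
            oracle = s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
            assert _median(vals) == pytest.approx(oracle, abs=1e-15)

    def test_single_row_median_is_value(self):
        df = pd.DataFrame({"species": ["x"], "pct_change": [7.5]})
        out = summarize_scenarios(df)
        pooled = out[out.species == "all"].iloc[0]
        assert pooled.pct_change_median == 7.5

    def test_palmetto_median_pct_change_is_21(self):
        df = datasets.derived_range_metrics()
        sp = df[df.species == "Sabal palmetto"]
        assert _median(sp["pct_change"]) == pytest.approx(21.0, abs=0.05)


class TestCurveIntervals:
    def test_flat_above_threshold_full_range(self):
        curve = pd.DataFrame({"value": [0, 1, 2, 3], "suitability": [0.6] * 4})
        assert suitable_range_from_curve(curve) == [(0.0, 3.0)]

    def test_unimodal_interpolated_crossings(self):
        curve = pd.DataFrame({
            "value": [0.0, 1.0, 2.0, 3.0, 4.0],
            "suitability": [0.1, 0.4, 0.8, 0.4, 0.1],
        })
        (lo, hi), = suitable_range_from_curve(curve, threshold=0.5)
        assert lo == pytest.approx(1.0 + (0.5 - 0.4) / (0.8 - 0.4))
        assert hi == pytest.approx(2.0 + (0.8 - 0.5) / (0.8 - 0.4))

    def test_never_above_threshold_empty(self):
        curve = pd.DataFrame({"value": [0, 1, 2], "suitability": [0.4] * 3})
        assert suitable_range_from_curve(curve) == []
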