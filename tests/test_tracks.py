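import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isotrack.grid import GridSpec
from isotrack.tracks import (
    DEFAULT_EQUINOX_WINDOWS,
    NORTH_SEA_BBOX,
    Fix,
    MoultWindow,
    RegionPolygon,
    Residency,
    Track,
    difference_surface,
    filter_equinox,
    filter_speed,
    haversine_km,
    kde_surface,
    moult_residency,
    nrd_bandwidth,
    overlap_percent,
    scale_surface,
)

from conftest import make_track


# ---------------------------------------------------------------------------
# equinox filtering


class TestFilterEquinox:
    def test_example_dates(self):
        track = make_track([(0, 55), (0, 55.1)], start=dt.date(2007, 10, 1),
                           step_days=19)  # 1 Oct and 20 Oct
        out = filter_equinox(track)
        assert [f.date for f in out.fixes] == [dt.date(2007, 10, 20)]

    def test_no_windows_is_identity(self):
        track = make_track([(0, 55), (1, 55)], start=dt.date(2007, 9, 15))
        out = filter_equinox(track, windows=[])
        assert out.fixes == track.fixes

    def test_empty_track(self):
        track = Track("b", "puffin", "2007/08", [])
        assert filter_equinox(track).fixes == []

    def test_full_year_count_against_calendar_oracle(self):
        # oracle: brute-force enumeration over a span with no leap day
        start = dt.date(2009, 7, 1)
        dates = [start + dt.timedelta(days=i) for i in range(365)]

        def oracle_removed(d):
            return (dt.date(d.year, 9, 10) <= d <= dt.date(d.year, 10, 18)) or (
                dt.date(d.year, 2, 20) <= d <= dt.date(d.year, 4, 2)
            )

        n_removed = sum(oracle_removed(d) for d in dates)
        assert n_removed == 39 + 42  # both windows, no leap day in range

        track = make_track([(0.0, 55.0)] * 365, start=start)
        out = filter_equinox(track)
        assert len(out) == 365 - n_removed == 284
        kept_oracle = [d for d in dates if not oracle_removed(d)]
        assert [f.date for f in out.fixes] == kept_oracle

    def test_wrapping_window(self):
        track = make_track([(0, 55)], start=dt.date(2007, 12, 25))
        out = filter_equinox(track, windows=[((12, 20), (1, 5))])
        assert out.fixes == []


# ---------------------------------------------------------------------------
# speed filtering


def speed_filter_oracle(track, max_kmday):
    """Independent forward great-circle scan."""
    if not track.fixes:
        return []
    kept = [track.fixes[0]]
    for fix in track.fixes[1:]:
        prev = kept[-1]
        d = haversine_km(prev.lon, prev.lat, fix.lon, fix.lat)
        if d / max((fix.date - prev.date).days, 1) <= max_kmday:
            kept.append(fix)
    return kept


class TestFilterSpeed:
    def test_obvious_exceedance(self):
        track = make_track([(0, 50), (0, 68)])  # ~2000 km in one day
        out = filter_speed(track, 500)
        assert len(out) == 1

    def test_stationary_unchanged(self):
        track = make_track([(1, 55)] * 5)
        assert filter_speed(track, 500).fixes == track.fixes

    def test_single_fix_unchanged(self):
        track = make_track([(1, 55)])
        assert filter_speed(track, 10).fixes == track.fixes

    def test_mid_sequence_outlier_matches_oracle(self):
        pts = [(0.0, 55.0), (0.5, 55.2), (10.0, 62.0), (1.0, 55.4), (1.5, 55.6)]
        track = make_track(pts)
        out = filter_speed(track, 500)
        assert out.fixes == speed_filter_oracle(track, 500)
        assert len(out) == 4  # only the big jump removed

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-10, 10, allow_nan=False),
                st.floats(45, 65, allow_nan=False),
            ),
            min_size=1,
            max_size=12,
        ),
        st.floats(50, 2000),
    )
    def test_contraction_and_idempotence(self, pts, max_kmday):
        track = make_track(pts)
        out = filter_speed(track, max_kmday)
        assert set(out.fixes) <= set(track.fixes)
        assert filter_speed(out, max_kmday).fixes == out.fixes
        assert out.fixes == speed_filter_oracle(track, max_kmday)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            filter_speed(make_track([(0, 55)]), 0)


class TestHaversine:
    def test_one_degree_latitude(self):
        assert haversine_km(0, 55, 0, 56) == pytest.approx(
            2 * math.pi * 6371 / 360, rel=1e-6
        )

    def test_symmetry(self):
        assert haversine_km(-3, 55, 5, 60) == haversine_km(5, 60, -3, 55)


# ---------------------------------------------------------------------------
# residency


class TestMoultResidency:
    window = MoultWindow("puffin", "body", frozenset({7, 8, 9}))

    def test_all_inside(self):
        track = make_track([(0, 55), (1, 56)], start=dt.date(2007, 7, 10))
        assert moult_residency(track, self.window, NORTH_SEA_BBOX) is Residency.RESIDENT

    def test_one_outside(self):
        track = make_track([(0, 55), (-8.0, 56)], start=dt.date(2007, 8, 1))
        assert (
            moult_residency(track, self.window, NORTH_SEA_BBOX)
            is Residency.NON_RESIDENT
        )

    def test_outside_window_months_ignored(self):
        # fix outside region, but in November -> irrelevant to this window
        track = make_track(
            [(0, 55), (-8.0, 56)], start=dt.date(2007, 8, 1), step_days=100
        )
        assert moult_residency(track, self.window, NORTH_SEA_BBOX) is Residency.RESIDENT

    def test_indeterminate(self):
        track = make_track([(0, 55)], start=dt.date(2007, 11, 5))
        assert (
            moult_residency(track, self.window, NORTH_SEA_BBOX)
            is Residency.INDETERMINATE
        )

    def test_empty_track_raises(self):
        with pytest.raises(ValueError):
            moult_residency(Track("b", "puffin", "w", []), self.window, NORTH_SEA_BBOX)

    def test_population_eligibility_count(self):
        """8 of 10 tracks fully resident in both moult seasons -> 8 eligible."""
        windows = [
            MoultWindow("puffin", "body", frozenset({7, 8, 9})),
            MoultWindow("puffin", "cheek", frozenset({1, 2, 3})),
        ]
        tracks = []
        for k in range(10):
            pts = [(1.0, 55.0), (2.0, 56.0)]
            if k >= 8:  # last two birds leave during cheek moult
                pts = [(1.0, 55.0), (-9.0, 50.0)]
            fixes = [
                Fix(f"b{k}", dt.date(2007, 8, 1), *pts[0]),
                Fix(f"b{k}", dt.date(2008, 2, 1), *pts[1]),
            ]
            tracks.append(Track(f"b{k}", "puffin", "2007/08", fixes))
        eligible = [
            t
            for t in tracks
            if all(
                moult_residency(t, w, NORTH_SEA_BBOX) is Residency.RESIDENT
                for w in windows
            )
        ]
        assert len(eligible) == 8


class TestRegionPolygon:
    def test_boundary_counts_as_inside(self):
        assert NORTH_SEA_BBOX.contains(-4.0, 55.0)

    def test_self_intersecting_rejected(self):
        with pytest.raises(ValueError):
            RegionPolygon("bowtie", [(0, 0), (1, 1), (1, 0), (0, 1)])


# ---------------------------------------------------------------------------
# bandwidth


class TestNrdBandwidth:
    def test_closed_form_on_seeded_sample(self, rng):
        x = rng.standard_normal(100)
        sd = np.std(x, ddof=1)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        expected = 1.06 * min(sd, iqr / 1.34) * 100 ** (-0.2)
        assert nrd_bandwidth(x) == pytest.approx(expected)
        # for a standard normal sample this is near 1.06 * n^(-1/5)
        assert nrd_bandwidth(x) == pytest.approx(1.06 * 100 ** (-0.2), rel=0.2)

    def test_scale_equivariance(self, rng):
        x = rng.normal(5, 2, 50)
        assert nrd_bandwidth(3.0 * x) == pytest.approx(3.0 * nrd_bandwidth(x))

    def test_degenerate_spread(self):
        with pytest.raises(ValueError, match="degenerate"):
            nrd_bandwidth([2.0, 2.0, 2.0])

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            nrd_bandwidth([1.0])


# ---------------------------------------------------------------------------
# KDE


def kde_oracle(lons, lats, bandwidth, grid):
    """Brute-force double-loop Gaussian kernel sum at cell centres."""
    out = np.zeros((grid.nrow, grid.ncol))
    norm = 1.0 / (len(lons) * 2 * math.pi * bandwidth**2)
    for i, y in enumerate(grid.lat_centers()):
        for j, x in enumerate(grid.lon_centers()):
            total = 0.0
            for lon, lat in zip(lons, lats):
                d2 = (x - lon) ** 2 + (y - lat) ** 2
                total += math.exp(-d2 / (2 * bandwidth**2))
            out[i, j] = total * norm
    return out


class TestKdeSurface:
    def test_single_fix_peak(self, small_grid):
        track = make_track([(5.2, 55.2)])
        s = kde_surface([track], 0.4, small_grid)
        i, j = np.unravel_index(np.argmax(s.values), s.values.shape)
        assert small_grid.lon_centers()[j] == pytest.approx(5.25)
        assert small_grid.lat_centers()[i] == pytest.approx(55.25)

    def test_two_separated_fixes_equal_modes(self):
        grid = GridSpec(0.0, 50.0, 0.25, 40, 40)
        track = make_track([(2.125, 52.125), (8.125, 58.125)])
        s = kde_surface([track], 0.3, grid)
        v = s.values
        top2 = np.sort(v.ravel())[-2:]
        assert top2[0] == pytest.approx(top2[1], rel=1e-9)

    def test_matches_bruteforce_oracle(self, rng, small_grid):
        lons = rng.uniform(1, 9, 50)
        lats = rng.uniform(51, 59, 50)
        track = make_track(list(zip(lons, lats)))
        s = kde_surface([track], 0.5, small_grid)
        expected = kde_oracle(lons, lats, 0.5, small_grid)
        np.testing.assert_allclose(s.values, expected, atol=1e-6)

    def test_integral_close_to_one(self, rng):
        grid = GridSpec(-10.0, 40.0, 0.2, 150, 150)
        lons = rng.uniform(0, 10, 30)
        lats = rng.uniform(50, 58, 30)
        s = kde_surface([make_track(list(zip(lons, lats)))], 0.4, grid)
        assert s.integral() == pytest.approx(1.0, abs=1e-3)
        assert (s.values >= 0).all()

    def test_empty_population(self, small_grid):
        with pytest.raises(ValueError, match="empty population"):
            kde_surface([Track("b", "puffin", "w", [])], 0.4, small_grid)


# ---------------------------------------------------------------------------
# scaled surfaces, differences, overlap


class TestScaleSurface:
    def test_example(self):
        s = GridSpec(0, 0, 1, 3, 1).empty()
        s.values[:] = [[0.0, 5.0, 10.0]]
        out = scale_surface(s)
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])

    def test_idempotent(self, rng):
        s = GridSpec(0, 0, 1, 6, 6).empty()
        s.values[:] = rng.uniform(3, 9, (6, 6))
        once = scale_surface(s)
        twice = scale_surface(once)
        np.testing.assert_allclose(once.values, twice.values)
        assert np.nanmin(once.values) == 0.0
        assert np.nanmax(once.values) == 1.0

    def test_constant_raises(self):
        s = GridSpec(0, 0, 1, 2, 2).empty(fill=3.0)
        with pytest.raises(ValueError, match="degenerate"):
            scale_surface(s)


class TestDifferenceSurface:
    def test_identical_gives_zero(self, rng):
        s = GridSpec(0, 0, 1, 4, 4).empty()
        s.values[:] = rng.uniform(0, 1, (4, 4))
        np.testing.assert_array_equal(
            difference_surface(s, s).values, np.zeros((4, 4))
        )

    def test_sign_convention_positive_is_late(self):
        late = GridSpec(0, 0, 1, 2, 1).empty(fill=1.0)
        early = GridSpec(0, 0, 1, 2, 1).empty(fill=0.0)
        out = difference_surface(late, early)
        assert (out.values == 1.0).all()

    def test_grid_mismatch(self):
        a = GridSpec(0, 0, 1, 2, 2).empty()
        b = GridSpec(0, 0, 1, 3, 2).empty()
        with pytest.raises(ValueError):
            difference_surface(a, b)


class TestOverlapPercent:
    def test_identical_is_100(self, rng):
        s = GridSpec(0, 0, 1, 5, 5).empty()
        s.values[:] = rng.uniform(0, 1, (5, 5))
        assert overlap_percent(s, s, 0.4) == 100.0

    def test_disjoint_is_0(self):
        a = GridSpec(0, 0, 1, 4, 1).empty()
        b = GridSpec(0, 0, 1, 4, 1).empty()
        a.values[:] = [[1.0, 1.0, 0.0, 0.0]]
        b.values[:] = [[0.0, 0.0, 1.0, 1.0]]
        assert overlap_percent(a, b, 0.4) == 0.0

    def test_denominator_is_reference(self):
        a = GridSpec(0, 0, 1, 4, 1).empty()
        b = GridSpec(0, 0, 1, 4, 1).empty()
        a.values[:] = [[1.0, 1.0, 1.0, 1.0]]
        b.values[:] = [[1.0, 1.0, 0.0, 0.0]]
        # intersection = 2 cells; |ref b| = 2; |ref a| = 4
        assert overlap_percent(a, b, 0.4) == 100.0
        assert overlap_percent(b, a, 0.4) == 50.0

    def test_counting_oracle(self, rng):
        a = GridSpec(0, 0, 1, 8, 8).empty()
        b = GridSpec(0, 0, 1, 8, 8).empty()
        a.values[:] = rng.uniform(0, 1, (8, 8))
        b.values[:] = rng.uniform(0, 1, (8, 8))
        thr = 0.4
        inter = sum(
            1
            for i in range(8)
            for j in range(8)
            if a.values[i, j] > thr and b.values[i, j] > thr
        )
        nref = sum(1 for i in range(8) for j in range(8) if b.values[i, j] > thr)
        assert overlap_percent(a, b, thr) == pytest.approx(100.0 * inter / nref)

    def test_empty_reference_raises(self):
        a = GridSpec(0, 0, 1, 2, 2).empty(fill=1.0)
        b = GridSpec(0, 0, 1, 2, 2).empty(fill=0.0)
        with pytest.raises(ValueError, match="reference"):
            overlap_percent(a, b, 0.4)
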