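"""Geodesy, residency clustering, event derivation and node filters."""

import numpy as np
import pandas as pd
import pytest

from phenosurf.config import AnalysisConfig
from phenosurf.geo import haversine_km, spherical_polygon_area_km2
from phenosurf.segmentation import (derive_migration_events,
                                    detect_stationary_sites, filter_nodes,
                                    mcp_home_range, summarize_migration)
from phenosurf.synthetic import AgentSpec, WorldSpec, simulate_tracks

from conftest import make_track


class TestGeo:
    def test_haversine_one_degree_latitude(self):
        # a degree of latitude is ~111.2 km everywhere on the sphere
        assert haversine_km(100.0, 40.0, 100.0, 41.0) == pytest.approx(111.2, abs=0.3)

    def test_haversine_longitude_shrinks_with_latitude(self):
        eq = haversine_km(100.0, 0.0, 101.0, 0.0)
        mid = haversine_km(100.0, 48.0, 101.0, 48.0)
        assert mid == pytest.approx(eq * np.cos(np.radians(48.0)), rel=1e-3)

    def test_polygon_area_matches_planar_oracle(self):
        # 1 deg x 1 deg square at 48N: planar cos-scaled approximation
        lons = [100.0, 101.0, 101.0, 100.0]
        lats = [48.0, 48.0, 49.0, 49.0]
        lat_km = haversine_km(100, 48, 100, 49)
        lon_km = haversine_km(100, 48.5, 101, 48.5)
        expected = lat_km * lon_km
        assert spherical_polygon_area_km2(lons, lats) == pytest.approx(
            expected, rel=0.01)


class TestMcp:
    def test_square_hull(self):
        hull, area = mcp_home_range([0.0, 1.0, 1.0, 0.0], [0.0, 0.0, 1.0, 1.0])
        assert len(hull.exterior.coords) - 1 == 4

    def test_interior_points_do_not_change_hull(self):
        _, a1 = mcp_home_range([0.0, 1.0, 1.0, 0.0], [0.0, 0.0, 1.0, 1.0])
        _, a2 = mcp_home_range([0.0, 1.0, 1.0, 0.0, 0.5, 0.3],
                               [0.0, 0.0, 1.0, 1.0, 0.5, 0.7])
        assert a1 == pytest.approx(a2)

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            mcp_home_range([0.0, 1.0], [0.0, 1.0])


def _stationary_rows(start_day, n_days, lon, lat, per_day=6, jitter=0.0):
    rows = []
    hours = np.linspace(0, 24, per_day, endpoint=False)
    for d in range(n_days):
        for h in hours:
            ts = pd.Timestamp("2021-01-01") + pd.Timedelta(days=start_day + d,
                                                           hours=float(h))
            rows.append((ts, lon + jitter, lat))
    return rows


class TestStationarySites:
    def test_three_day_pause_is_stopover_eligible(self):
        # transit ... 3.0-day pause within 5 km ... transit
        rows = []
        t0 = pd.Timestamp("2021-03-01")
        for i in range(12):  # 12h of 60 km/h transit, fix every hour
            rows.append((t0 + pd.Timedelta(hours=i), 100.0, 40.0 + 0.54 * i))
        pause_start = t0 + pd.Timedelta(hours=12)
        for i in range(int(3.0 * 24) + 1):
            rows.append((pause_start + pd.Timedelta(hours=i), 100.0, 46.5))
        after = pause_start + pd.Timedelta(days=3, hours=1)
        for i in range(12):
            rows.append((after + pd.Timedelta(hours=i), 100.0, 46.6 + 0.54 * i))
        tr = make_track(rows)
        sites = detect_stationary_sites(tr, radius_km=30.0, min_days=2.0)
        eligible = [s for s in sites if s.duration_days > 2.0]
        assert len(eligible) == 1
        assert eligible[0].lat == pytest.approx(46.5, abs=0.1)
        assert eligible[0].role == "stopover"

    def test_exactly_two_day_pause_is_brief(self):
        rows = []
        t0 = pd.Timestamp("2021-03-01")
        for i in range(6):
            rows.append((t0 + pd.Timedelta(hours=i), 100.0, 40.0 + 0.54 * i))
        p0 = t0 + pd.Timedelta(hours=6)
        for i in range(0, int(2.0 * 24) + 1, 4):   # exactly 2.0 days
            rows.append((p0 + pd.Timedelta(hours=i), 100.0, 44.0))
        q0 = p0 + pd.Timedelta(days=2, hours=1)
        for i in range(6):
            rows.append((q0 + pd.Timedelta(hours=i), 100.0, 44.6 + 0.54 * i))
        tr = make_track(rows)
        sites = detect_stationary_sites(tr, radius_km=30.0, min_days=2.0)
        pause = [s for s in sites if abs(s.lat - 44.0) < 0.2]
        assert pause and pause[0].role == "brief_stop"

    def test_continuous_transit_yields_no_multiday_site(self):
        rows = [(pd.Timestamp("2021-03-01") + pd.Timedelta(hours=i),
                 100.0, 30.0 + 0.54 * i) for i in range(72)]
        tr = make_track(rows)
        sites = detect_stationary_sites(tr, radius_km=30.0, min_days=2.0)
        assert all(s.duration_days <= 2.0 for s in sites)

    def test_subday_track_empty(self):
        rows = [(pd.Timestamp("2021-03-01") + pd.Timedelta(hours=i), 100.0, 40.0)
                for i in range(5)]
        assert detect_stationary_sites(make_track(rows)) == []


@pytest.fixture(scope="module")
def simulated():
    world = WorldSpec(temp_noise_sd=0.0, n_lat=20, n_lon=4)
    agents = AgentSpec(n_individuals=4, cue_lag_sd=0.0,
                       position_jitter_sd=0.0, site_lat_jitter=0.0,
                       site_lon_jitter=0.0, fix_rate=6.0)
    tracks, gt = simulate_tracks(world, agents, seed=5)
    return world, agents, tracks, gt


class TestDeriveEvents:
    def test_event_dates_match_ground_truth(self, simulated):
        world, agents, tracks, gt = simulated
        cfg = AnalysisConfig()
        for tr in tracks:
            sites = detect_stationary_sites(tr, cfg.residency_radius_km,
                                            cfg.stopover_min_days)
            events = derive_migration_events(tr, sites, cfg)
            assert {e.season for e in events} == {"spring", "autumn"}
            g = gt[gt.individual_id == tr.individual_id]
            for ev in events:
                if ev.season == "spring":
                    true_dep = g[(g.season == "spring")
                                 & (g.role == "wintering")].depart_doy.iloc[0]
                    true_arr = g[(g.season == "spring")
                                 & (g.role == "breeding")].arrive_doy.iloc[0]
                else:
                    true_dep = g[(g.season == "autumn")
                                 & (g.role == "breeding")].depart_doy.iloc[0]
                    true_arr = g[(g.season == "autumn")
                                 & (g.role == "wintering")].arrive_doy.iloc[0]
                from phenosurf.types import doy
                assert doy(ev.departure_date) == pytest.approx(true_dep, abs=1.0)
                assert doy(ev.arrival_date) == pytest.approx(true_arr, abs=1.0)
                assert ev.complete

    def test_truncated_track_incomplete(self, simulated):
        world, agents, tracks, gt = simulated
        tr = tracks[0]
        # cut the track mid-spring-migration (after leaving, before breeding)
        g = gt[gt.individual_id == tr.individual_id]
        dep = g[(g.season == "spring") & (g.role == "wintering")].depart_doy.iloc[0]
        cut = pd.Timestamp("2021-01-01", tz="UTC") + pd.Timedelta(days=dep + 8)
        from phenosurf.types import Track
        fixes = [f for f in tr.fixes if pd.Timestamp(f.timestamp, tz="UTC") < cut]
        short = Track(tr.individual_id, tr.species, tr.group, fixes)
        sites = detect_stationary_sites(short, 30.0, 2.0)
        events = derive_migration_events(short, sites, AnalysisConfig())
        assert len(events) == 1
        ev = events[0]
        assert ev.season == "spring" and not ev.complete
        assert ev.arrival_date is None

    def test_moult_relocation_becomes_autumn_origin(self):
        world = WorldSpec(temp_noise_sd=0.0, n_lat=20, n_lon=4)
        agents = AgentSpec(n_individuals=3, cue_lag_sd=0.0,
                           position_jitter_sd=0.0, site_lat_jitter=0.0,
                           site_lon_jitter=0.0, moult_fraction=1.0,
                           moult_distance_km=200.0)
        tracks, gt = simulate_tracks(world, agents, seed=7)
        cfg = AnalysisConfig()
        tr = tracks[0]
        sites = detect_stationary_sites(tr, cfg.residency_radius_km,
                                        cfg.stopover_min_days)
        events = derive_migration_events(tr, sites, cfg)
        autumn = [e for e in events if e.season == "autumn"][0]
        origin = autumn.nodes[0]
        breeding_lat = gt[(gt.individual_id == tr.individual_id)
                          & (gt.role == "breeding")].lat.iloc[0]
        assert origin.role == "moulting"
        assert origin.lat > breeding_lat + 1.0  # ~200 km north


class TestFilterNodes:
    def _events(self, simulated):
        world, agents, tracks, gt = simulated
        cfg = AnalysisConfig()
        evs = []
        for tr in tracks:
            sites = detect_stationary_sites(tr, cfg.residency_radius_km,
                                            cfg.stopover_min_days)
            evs.extend(derive_migration_events(tr, sites, cfg))
        return evs, cfg

    def test_south_of_boundary_removed(self, simulated):
        evs, cfg = self._events(simulated)
        high = filter_nodes(evs, AnalysisConfig(isotherm_boundary_lat=33.0))
        higher = filter_nodes(evs, AnalysisConfig(isotherm_boundary_lat=40.0))
        assert len(higher) < len(high)
        assert (higher.lat >= 40.0).all()

    def test_all_north_unchanged(self, simulated):
        evs, cfg = self._events(simulated)
        a = filter_nodes(evs, AnalysisConfig(isotherm_boundary_lat=33.0))
        b = filter_nodes(evs, AnalysisConfig(isotherm_boundary_lat=1.0))
        assert len(a) == len(b)  # every node is already north of 33N

    def test_low_fix_rate_record_excluded(self, simulated):
        evs, cfg = self._events(simulated)
        strict = AnalysisConfig(min_fixes_per_day=99.0)
        assert filter_nodes(evs, strict).empty

    def test_spring_uses_arrival_autumn_uses_departure(self, simulated):
        evs, cfg = self._events(simulated)
        nodes = filter_nodes(evs, cfg)
        sp = nodes[nodes.season == "spring"]
        au = nodes[nodes.season == "autumn"]
        assert np.allclose(sp.dobs, sp.first_doy)
        assert np.allclose(au.dobs, au.last_doy)


class TestSummary:
    def test_mean_and_sd(self, simulated):
        world, agents, tracks, gt = simulated
        cfg = AnalysisConfig()
        evs = []
        for tr in tracks:
            sites = detect_stationary_sites(tr, cfg.residency_radius_km,
                                            cfg.stopover_min_days)
            evs.extend(derive_migration_events(tr, sites, cfg))
        summary = summarize_migration(evs)
        spring = summary[summary.season == "spring"].iloc[0]
        g = gt[(gt.season == "spring") & (gt.role == "wintering")]
        assert spring["departure_mean"] == pytest.approx(g.depart_doy.mean(),
                                                         abs=1.0)
        assert spring["n_records"] == agents.n_individuals

    def test_two_events_hand_computed(self):
        from phenosurf.types import MigrationEvent
        evs = [MigrationEvent("a", "SG", "E", "spring", 2021,
                              pd.Timestamp("2021-03-16"), pd.Timestamp("2021-04-10"),
                              True, [], 6.0),
               MigrationEvent("b", "SG", "E", "spring", 2021,
                              pd.Timestamp("2021-03-18"), pd.Timestamp("2021-04-10"),
                              True, [], 6.0)]
        s = summarize_migration(evs).iloc[0]
        assert s["departure_mean"] == pytest.approx(76.0)
        assert s["departure_sd"] == pytest.approx(np.sqrt(2.0))
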