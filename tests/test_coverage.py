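"""Great-circle distance, nearest-laboratory assignment and coverage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tierplan as tp
from tierplan.coverage import pairwise_distances

latitudes = st.floats(-89.0, 89.0, allow_nan=False)
longitudes = st.floats(-179.0, 179.0, allow_nan=False)


def _labs(rows):
    return pd.DataFrame(
        rows,
        columns=["id", "latitude", "longitude", "district_id", "tier",
                 "instrument_capacity_per_day", "offers_general_pathology"],
    )


def _facilities(rows):
    return pd.DataFrame(
        rows,
        columns=["id", "name", "category", "district_id", "latitude", "longitude",
                 "annual_volume"],
    )


class TestGreatCircle:
    def test_identical_points_are_zero(self):
        assert tp.great_circle_km((-26.2, 28.0), (-26.2, 28.0)) == 0.0

    def test_johannesburg_to_pretoria(self):
        # frozen against an independent geodesic calculation (R geosphere,
        # haversine on the 6371.0088 km sphere): 53.891 km
        d = tp.great_circle_km((-26.2041, 28.0473), (-25.7479, 28.2293))
        assert d == pytest.approx(53.9, abs=0.3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(lat1=latitudes, lon1=longitudes, lat2=latitudes, lon2=longitudes)
    def test_symmetric_and_nonnegative(self, lat1, lon1, lat2, lon2):
        d_ab = tp.great_circle_km((lat1, lon1), (lat2, lon2))
        d_ba = tp.great_circle_km((lat2, lon2), (lat1, lon1))
        assert d_ab == pytest.approx(d_ba, abs=1e-9)
        assert d_ab >= 0.0

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(tp.ValidationError):
            tp.great_circle_km((95.0, 0.0), (0.0, 0.0))

    def test_planar_close_to_haversine_at_short_range(self):
        a = pd.DataFrame({"latitude": [-26.2], "longitude": [28.0]})
        b = pd.DataFrame({"latitude": [-26.5], "longitude": [28.4]})
        hav = pairwise_distances(a, b, "haversine")[0, 0]
        pla = pairwise_distances(a, b, "planar")[0, 0]
        assert pla == pytest.approx(hav, rel=0.01)


class TestAssignNearest:
    def test_far_facility_assigned_but_uncovered(self, schedule):
        facilities = _facilities([("F1", "f", "phc", "D1", -26.0, 28.0, 100)])
        labs = _labs([("L1", -26.0, 29.5, "D2", "unassigned", 384, True)])
        out = tp.assign_nearest(facilities, labs, schedule)
        assert out.loc[0, "lab_id"] == "L1"
        assert out.loc[0, "distance_km"] > schedule.radius_km
        assert not out.loc[0, "covered"]

    def test_exact_tie_goes_to_smallest_lab_id(self, schedule):
        facilities = _facilities([("F1", "f", "phc", "D1", 0.0, 0.0, 10)])
        labs = _labs(
            [
                ("B", 0.0, 1.0, "D1", "unassigned", 100, True),
                ("A", 0.0, -1.0, "D1", "unassigned", 100, True),
            ]
        )
        out = tp.assign_nearest(facilities, labs, schedule)
        assert out.loc[0, "lab_id"] == "A"

    def test_empty_lab_registry_rejected(self, schedule):
        facilities = _facilities([("F1", "f", "phc", "D1", 0.0, 0.0, 10)])
        with pytest.raises(tp.ValidationError, match="empty"):
            tp.assign_nearest(facilities, _labs([]), schedule)

    def test_matches_brute_force_on_random_instances(self, schedule):
        rng = np.random.default_rng(42)
        for _ in range(5):
            nf, nl = rng.integers(5, 51), rng.integers(1, 6)
            facilities = _facilities(
                [
                    (f"F{i}", "f", "phc", "D1",
                     rng.uniform(-35, -22), rng.uniform(17, 32), 10)
                    for i in range(nf)
                ]
            )
            labs = _labs(
                [
                    (f"L{i}", rng.uniform(-35, -22), rng.uniform(17, 32), "D1",
                     "unassigned", 100, True)
                    for i in range(nl)
                ]
            )
            out = tp.assign_nearest(facilities, labs, schedule)
            for k, fac in facilities.iterrows():
                best = min(
                    (
                        (tp.great_circle_km(
                            (fac["latitude"], fac["longitude"]),
                            (lab["latitude"], lab["longitude"]),
                        ), lab["id"])
                        for _, lab in labs.iterrows()
                    ),
                )
                assert out.loc[k, "lab_id"] == best[1]
                assert out.loc[k, "distance_km"] == pytest.approx(best[0], abs=1e-9)


class TestCoverageReport:
    def test_everything_nearby_gives_full_coverage(self, schedule):
        facilities = _facilities(
            [(f"F{i}", "f", "phc", "D1", -26.0 + i * 0.001, 28.0, 50) for i in range(4)]
        )
        labs = _labs([("L1", -26.0, 28.0, "D1", "unassigned", 384, True)])
        asg = tp.assign_nearest(facilities, labs, schedule)
        rep = tp.coverage_report(asg, facilities, labs, schedule)
        assert rep.fraction_covered == 1.0
        assert rep.fraction_covered_volume == 1.0
        assert rep.uncovered_ids == []

    def test_covered_plus_uncovered_counts_conserved(self, full_network, full_assignments, schedule):
        facilities, labs, _ = full_network
        rep = tp.coverage_report(full_assignments, facilities, tp.cd4_labs(labs), schedule)
        n_covered = int(full_assignments["covered"].sum())
        assert n_covered + len(rep.uncovered_ids) == len(facilities)

    def test_coverage_monotone_in_radius(self, full_network, schedule):
        facilities, labs, _ = full_network
        cd4 = tp.cd4_labs(labs)
        fracs = []
        for radius in (50.0, 100.0, 200.0):
            sched = tp.load_tier_schedule({"radius_km": radius})
            asg = tp.assign_nearest(facilities, cd4, sched)
            fracs.append(tp.coverage_report(asg, facilities, cd4, sched).fraction_covered)
        assert fracs[0] <= fracs[1] <= fracs[2]

    def test_adding_a_lab_never_reduces_coverage(self, small_network, schedule):
        facilities, labs, districts = small_network
        cd4 = tp.cd4_labs(labs)
        asg_all = tp.assign_nearest(facilities, cd4, schedule)
        frac_all = asg_all["covered"].mean()
        for drop in range(len(cd4)):
            subset = cd4.drop(index=drop).reset_index(drop=True)
            asg = tp.assign_nearest(facilities, subset, schedule)
            assert asg["covered"].mean() <= frac_all + 1e-12

    def test_overserviced_pairs_flagged(self, schedule):
        labs = _labs(
            [
                ("L1", -26.0, 28.0, "D1", "unassigned", 768, True),
                ("L2", -26.1, 28.1, "D1", "unassigned", 768, True),
                ("L3", -30.0, 22.0, "D2", "unassigned", 768, True),
            ]
        )
        facilities = _facilities([("F1", "f", "phc", "D1", -26.0, 28.0, 10)])
        asg = tp.assign_nearest(facilities, labs, schedule)
        rep = tp.coverage_report(asg, facilities, labs, schedule)
        assert [(a, b) for a, b, _ in rep.overserviced_pairs] == [("L1", "L2")]

    def test_default_network_uncovered_fraction_matches_calibration(self, schedule):
        # seed sweep: the generator is calibrated so that roughly a tenth of
        # facilities sit beyond the 100 km precinct radius (0.10 +/- 0.03)
        for seed in range(3):
            facilities, labs, _ = tp.generate_network(tp.NetworkConfig(seed=seed))
            cd4 = tp.cd4_labs(labs)
            asg = tp.assign_nearest(facilities, cd4, schedule)
            uncovered = 1.0 - asg["covered"].mean()
            assert 0.07 <= uncovered <= 0.13


class TestPrecinctExport:
    def test_geojson_circles(self):
        labs = _labs([("L1", -26.0, 28.0, "D1", "unassigned", 768, True)])
        gj = tp.precincts_geojson(labs, radius_km=100.0, n_segments=64)
        assert gj["type"] == "FeatureCollection"
        ring = gj["features"][0]["geometry"]["coordinates"][0]
        assert len(ring) == 65 and ring[0] == ring[-1]
        # every vertex is ~100 km from the centre
        for lon, lat in ring[:-1]:
            d = tp.great_circle_km((-26.0, 28.0), (lat, lon))
            assert d == pytest.approx(100.0, rel=0.01)
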