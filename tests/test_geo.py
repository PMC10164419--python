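"""Geocoding, haversine, the ANN statistic, buffering, recommendation."""

import math

import numpy as np
import pytest

from vaxsent.geo import (
    ANNResult,
    BufferQuery,
    EARTH_RADIUS_KM,
    GeoPoint,
    PointPattern,
    VaccineCenter,
    ann_statistic,
    buffer_centers,
    confidence_level,
    geocode,
    haversine_km,
    read_points_geojson,
    recommend_centers,
    write_points_geojson,
    z_critical,
)
from vaxsent.synth import PatternSpec, gen_point_pattern


class TestGeoPoint:
    def test_validation(self):
        with pytest.raises(ValueError):
            GeoPoint(91, 0)
        with pytest.raises(ValueError):
            GeoPoint(0, -180)  # open at -180, closed at +180
        GeoPoint(0, 180)

    def test_tolerant_equality(self):
        assert GeoPoint(1, 2) == GeoPoint(1 + 1e-10, 2 - 1e-10)
        assert GeoPoint(1, 2) != GeoPoint(1 + 1e-6, 2)


class TestGeocode:
    GAZETTEER = {"Naples, Italy": GeoPoint(40.8518, 14.2681)}

    def test_lookup(self):
        assert geocode("Naples, Italy", self.GAZETTEER) == GeoPoint(40.8518, 14.2681)

    def test_normalization(self):
        assert geocode("  NAPLES,   italy ", self.GAZETTEER) == GeoPoint(
            40.8518, 14.2681
        )

    def test_miss_is_none(self):
        assert geocode("Atlantis", self.GAZETTEER) is None


class TestHaversine:
    def test_identity(self):
        assert haversine_km(GeoPoint(12.3, 45.6), GeoPoint(12.3, 45.6)) == 0.0

    def test_half_circumference(self):
        assert haversine_km(GeoPoint(0, 0), GeoPoint(0, 180)) == pytest.approx(
            math.pi * EARTH_RADIUS_KM, abs=1e-6
        )

    def test_one_degree_on_equator(self):
        assert haversine_km(GeoPoint(0, 0), GeoPoint(0, 1)) == pytest.approx(
            2 * math.pi * EARTH_RADIUS_KM / 360, abs=1e-6
        )

    def test_symmetry(self):
        a, b = GeoPoint(40.85, 14.27), GeoPoint(51.51, -0.13)
        assert haversine_km(a, b) == pytest.approx(haversine_km(b, a), abs=1e-12)


class TestAnnStatistic:
    def test_two_point_hand_oracle(self):
        """DO = 1, DE = 0.5/sqrt(2), ANN = 2*sqrt(2) for 2 points in 1 km²."""
        pattern = PointPattern(
            coords=np.array([[0.0, 0.0], [1.0, 0.0]]), planar=True, study_area=1.0
        )
        result = ann_statistic(pattern)
        assert result.do == pytest.approx(1.0)
        assert result.de == pytest.approx(0.5 / math.sqrt(2))
        assert result.ann == pytest.approx(2 * math.sqrt(2))

    def test_regular_grid_is_dispersed_with_ann_2(self):
        pattern = gen_point_pattern(PatternSpec(kind="grid", n=100, bbox=(0, 0, 10, 10)))
        result = ann_statistic(pattern)
        assert result.ann == pytest.approx(2.0, abs=1e-12)
        assert result.pattern_call == "dispersed"

    def test_clustered_simulation_is_clustered(self):
        pattern = gen_point_pattern(PatternSpec(kind="clustered", seed=42))
        result = ann_statistic(pattern)
        assert result.ann < 1
        assert result.pattern_call == "clustered"
        assert result.confidence_pct >= 95

    def test_planar_scale_invariance(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 10, size=(50, 2))
        base = ann_statistic(PointPattern(coords=coords, planar=True, study_area=100.0))
        scaled = ann_statistic(
            PointPattern(coords=coords * 3.0, planar=True, study_area=100.0 * 9.0)
        )
        assert scaled.ann == pytest.approx(base.ann, abs=1e-12)

    def test_csr_mean_ann_near_one(self):
        """200 CSR replicates of n=500: mean ANN ≈ 1, ~5% false alarms."""
        anns, rejects = [], 0
        for seed in range(200):
            pattern = gen_point_pattern(
                PatternSpec(kind="csr", n=500, bbox=(0, 0, 100, 100), seed=seed)
            )
            result = ann_statistic(pattern)
            anns.append(result.ann)
            if abs(result.z) > 1.96:
                rejects += 1
        assert 0.97 <= np.mean(anns) <= 1.03
        # 5% nominal rate, binomial tolerance for 200 replicates
        assert 0.005 <= rejects / 200 <= 0.12

    def test_geodesic_input_uses_km(self):
        # two points 1 degree apart on the equator, area supplied in km²
        pattern = PointPattern(
            coords=np.array([[0.0, 0.0], [0.0, 1.0]]), planar=False, study_area=111.195**2
        )
        result = ann_statistic(pattern)
        assert result.do == pytest.approx(111.195, abs=1e-2)

    def test_errors(self):
        with pytest.raises(ValueError):
            ann_statistic(PointPattern(coords=np.array([[0.0, 0.0]]), planar=True))
        with pytest.raises(ValueError):
            PointPattern(coords=np.zeros((3, 2)), planar=True, study_area=-5.0)
        with pytest.raises(ValueError, match="degenerate"):
            ann_statistic(
                PointPattern(coords=np.array([[0.0, 0.0], [0.0, 0.0]]), planar=True)
            )


class TestConfidenceLevel:
    @pytest.mark.parametrize(
        "p, z, expected",
        [
            (0.005, -3.0, 99),
            (0.03, 2.1, 95),
            (0.5, 0.2, 0),
            (0.08, -1.7, 90),
            (0.005, 2.0, 95),   # small p but moderate |z|: drops a row
            (0.2, 3.0, 0),      # large p blocks every row
        ],
    )
    def test_joint_rule(self, p, z, expected):
        assert confidence_level(p, z) == expected

    def test_monotone_in_p_at_fixed_large_z(self):
        levels = [confidence_level(p, 5.0) for p in (0.5, 0.09, 0.04, 0.009)]
        assert levels == sorted(levels)
        assert levels == [0, 90, 95, 99]

    def test_critical_values_two_decimals(self):
        assert round(z_critical(95), 2) == 1.96
        assert round(z_critical(99), 2) == 2.58


def _centers_on_equator():
    return (
        VaccineCenter("near", GeoPoint(0, 0.05), ("Moderna",)),
        VaccineCenter("far", GeoPoint(0, 0.2), ("Moderna",)),
        VaccineCenter("mid", GeoPoint(0, 0.08), ("Pfizer/BioNTech",)),
    )


class TestBuffering:
    def test_closed_ball_membership(self):
        query = BufferQuery(
            user=GeoPoint(0, 0), centers=_centers_on_equator(), radius_km=10
        )
        names = [c.name for c, _ in buffer_centers(query)]
        assert names == ["near", "mid"]  # ~5.56 km and ~8.90 km; 22.2 km excluded

    def test_boundary_point_included(self):
        d = haversine_km(GeoPoint(0, 0), GeoPoint(0, 0.05))
        query = BufferQuery(
            user=GeoPoint(0, 0),
            centers=(VaccineCenter("edge", GeoPoint(0, 0.05), ("Moderna",)),),
            radius_km=d,
        )
        assert [c.name for c, _ in buffer_centers(query)] == ["edge"]

    def test_radius_monotone_nesting(self, fixtures):
        _, centers = fixtures
        user = GeoPoint(40.8518, 14.2681)
        previous: set = set()
        for radius in (1, 3, 5, 10, 50, 500, 5000):
            query = BufferQuery(user=user, centers=tuple(centers), radius_km=radius)
            names = {c.name for c, _ in buffer_centers(query)}
            assert previous <= names
            previous = names

    def test_empty_center_list(self):
        query = BufferQuery(user=GeoPoint(0, 0), centers=(), radius_km=10)
        assert buffer_centers(query) == []


class TestRecommend:
    def test_higher_share_ranks_first(self):
        query = BufferQuery(user=GeoPoint(0, 0), centers=_centers_on_equator()[:1] + _centers_on_equator()[2:], radius_km=10)
        ranked = recommend_centers(query, {"Moderna": 0.8, "Pfizer/BioNTech": 0.4})
        assert [r.center.name for r in ranked] == ["near", "mid"]
        assert ranked[0].score == 0.8

    def test_equal_shares_nearer_first(self):
        query = BufferQuery(
            user=GeoPoint(0, 0), centers=_centers_on_equator(), radius_km=10
        )
        ranked = recommend_centers(query, {"Moderna": 0.6, "Pfizer/BioNTech": 0.6})
        assert [r.center.name for r in ranked] == ["near", "mid"]

    def test_missing_brand_defaults_to_half(self):
        query = BufferQuery(
            user=GeoPoint(0, 0), centers=_centers_on_equator()[:1], radius_km=10
        )
        ranked = recommend_centers(query, {})
        assert ranked[0].score == 0.5
        assert "default" in ranked[0].score_source

    def test_no_center_in_radius_is_empty(self):
        query = BufferQuery(
            user=GeoPoint(50, 50), centers=_centers_on_equator(), radius_km=10
        )
        assert recommend_centers(query, {}) == []


class TestGeoJson:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "points.geojson"
        points = [GeoPoint(40.85, 14.27), GeoPoint(41.9, 12.5)]
        assert write_points_geojson(path, points) == 2
        pattern = read_points_geojson(path)
        assert pattern.n == 2
        np.testing.assert_allclose(pattern.coords[0], [40.85, 14.27])
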