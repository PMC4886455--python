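"""Geometry core: buffers, intersections, crop-index profiles, GeoJSON."""

import json
import math

import numpy as np
import pytest
from shapely.geometry import Polygon, box

import croprisk as cr
from croprisk.landcover import validate_landcover

from conftest import make_random_scene


class TestMakeBuffer:
    def test_area_is_pi_r_squared(self):
        for r in (1.0, 250.0, 1000.0, 5000.0):
            buf = cr.make_buffer((3.0, -7.0), cr.BufferSpec(radius=r))
            assert buf.area == pytest.approx(math.pi * r**2, rel=1e-12)

    def test_one_percent_of_1km_buffer_is_3_14_hectares(self):
        buf = cr.make_buffer((0.0, 0.0), cr.BufferSpec(radius=1000.0))
        assert round(buf.area * 0.01 / 10_000.0, 2) == 3.14

    def test_centered_on_center(self):
        buf = cr.make_buffer((123.0, 456.0))
        c = buf.centroid
        assert c.x == pytest.approx(123.0, abs=1e-9)
        assert c.y == pytest.approx(456.0, abs=1e-9)

    @pytest.mark.parametrize("radius", [0.0, -5.0, float("nan"), float("inf")])
    def test_bad_radius_rejected(self, radius):
        with pytest.raises(cr.InvalidInputError):
            cr.BufferSpec(radius=radius)

    def test_too_few_segments_rejected(self):
        with pytest.raises(cr.InvalidInputError):
            cr.BufferSpec(n_segments=16)

    def test_non_finite_center_rejected(self):
        with pytest.raises(cr.InvalidInputError):
            cr.make_buffer((float("nan"), 0.0))


class TestIntersectArea:
    def test_disjoint_squares(self, unit_square):
        far = box(10.0, 10.0, 11.0, 11.0)
        assert cr.intersect_area(unit_square, far) == 0.0

    def test_identical_unit_square(self, unit_square):
        assert cr.intersect_area(unit_square, unit_square) == pytest.approx(1.0)

    def test_symmetric_and_bounded(self, unit_square):
        other = box(0.5, 0.25, 3.0, 3.0)
        a1 = cr.intersect_area(unit_square, other)
        a2 = cr.intersect_area(other, unit_square)
        assert a1 == a2
        assert 0 <= a1 <= min(unit_square.area, other.area)

    def test_half_plane_clip_of_unit_circle(self):
        """Clipping the r=1 buffer at x >= 0 leaves exactly half its area."""
        circle = cr.make_buffer((0.0, 0.0), cr.BufferSpec(radius=1.0))
        half_plane = box(0.0, -10.0, 10.0, 10.0)
        assert cr.intersect_area(circle, half_plane) == pytest.approx(math.pi / 2, rel=1e-9)

    def test_degenerate_input_returns_zero(self, unit_square):
        degenerate = Polygon([(0, 0), (1, 0), (0, 0)])
        assert cr.intersect_area(unit_square, degenerate) == 0.0


class TestCropProfile:
    def test_empty_map_all_zero(self):
        prof = cr.crop_profile((0.0, 0.0), cr.LandCoverMap("r", []))
        assert prof.global_percent == 0.0
        assert all(v == 0.0 for v in prof.per_class_percent.values())

    def test_buffer_inside_one_polygon_gives_full_cover(self):
        big = cr.LandCoverPolygon("big", box(-5000, -5000, 5000, 5000), "irrigated")
        prof = cr.crop_profile((0.0, 0.0), cr.LandCoverMap("r", [big]))
        assert prof.per_class_percent["irrigated"] == pytest.approx(100.0)
        assert prof.global_percent == pytest.approx(100.0)

    def test_half_plane_vineyards_cover_half(self):
        half = cr.LandCoverPolygon("h", box(0, -50_000, 50_000, 50_000), "vineyards")
        prof = cr.crop_profile((0.0, 0.0), cr.LandCoverMap("r", [half]))
        assert prof.per_class_percent["vineyards"] == pytest.approx(50.0, abs=1e-6)
        assert prof.global_percent == pytest.approx(50.0, abs=1e-6)

    def test_other_class_contributes_nothing(self):
        other = cr.LandCoverPolygon("o", box(-5000, -5000, 5000, 5000), "other")
        prof = cr.crop_profile((0.0, 0.0), cr.LandCoverMap("r", [other]))
        assert prof.global_percent == 0.0

    def test_holes_reduce_coverage(self):
        """A hole in a crop polygon is uncovered land, not crop."""
        outer = [(-5000, -5000), (5000, -5000), (5000, 5000), (-5000, 5000)]
        hole = [(-500, -500), (500, -500), (500, 500), (-500, 500)]
        poly = cr.LandCoverPolygon.from_ring("holed", outer, "olives", holes=[hole])
        prof = cr.crop_profile((0.0, 0.0), cr.LandCoverMap("r", [poly]))
        expected = 100.0 * (math.pi * 1e6 - 1e6) / (math.pi * 1e6)
        assert prof.per_class_percent["olives"] == pytest.approx(expected, rel=1e-6)

    def test_overlapping_agricultural_polygons_rejected(self):
        a = cr.LandCoverPolygon("a", box(-1000, -1000, 1000, 1000), "irrigated")
        b = cr.LandCoverPolygon("b", box(-500, -500, 1500, 1500), "fruits")
        with pytest.raises(cr.DataQualityError):
            cr.crop_profile((0.0, 0.0), cr.LandCoverMap("r", [a, b]))
        with pytest.raises(cr.DataQualityError):
            validate_landcover(cr.LandCoverMap("r", [a, b]))

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        scene = make_random_scene(rng)
        base = cr.crop_profile((100.0, -200.0), scene)
        for dx, dy in [(1e4, -3e4), (5e6, 5e6)]:
            moved = cr.LandCoverMap(
                "moved",
                [
                    cr.LandCoverPolygon(
                        p.polygon_id,
                        Polygon(np.asarray(p.geometry.exterior.coords) + [dx, dy]),
                        p.crop_class,
                    )
                    for p in scene.polygons
                ],
            )
            prof = cr.crop_profile((100.0 + dx, -200.0 + dy), moved)
            for c in cr.CROP_CLASSES:
                assert prof.per_class_percent[c] == pytest.approx(
                    base.per_class_percent[c], rel=1e-9, abs=1e-9
                )

    def test_adding_polygon_never_decreases_global(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            scene = make_random_scene(rng, n_polygons=5)
            pt = tuple(rng.uniform(-1500, 1500, 2))
            before = cr.crop_profile(pt, scene).global_percent
            # add a fresh disjoint agricultural cell outside the grid
            extra = cr.LandCoverPolygon(
                "extra", box(2000, 2000, 2800, 2800), "olives"
            )
            after = cr.crop_profile(pt, cr.LandCoverMap("r", scene.polygons + [extra])).global_percent
            assert after >= before - 1e-12

    def test_area_conservation_with_other_in_accounting(self):
        """On a fully tiled scene, crop % + other % = 100 inside the buffer."""
        rng = np.random.default_rng(3)
        cell = 800.0
        polys = []
        for i in range(-3, 3):
            for j in range(-3, 3):
                cls = rng.choice(list(cr.ALL_CLASSES))
                polys.append(
                    cr.LandCoverPolygon(
                        f"t{i}_{j}", box(i * cell, j * cell, (i + 1) * cell, (j + 1) * cell), cls
                    )
                )
        scene = cr.LandCoverMap("tiled", polys)
        pt, spec = (37.0, -12.0), cr.BufferSpec()
        prof = cr.crop_profile(pt, scene, spec)
        buf = cr.make_buffer(pt, spec)
        other_pct = 100.0 * sum(
            cr.intersect_area(buf, p.geometry) for p in scene.polygons if p.crop_class == "other"
        ) / spec.area
        assert prof.global_percent + other_pct == pytest.approx(100.0, abs=1e-6)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(21)
        scene = make_random_scene(rng, n_polygons=8)
        pts = rng.uniform(-2000, 2000, size=(15, 2))
        arr = cr.crop_profiles(pts, scene)
        for i, (x, y) in enumerate(pts):
            prof = cr.crop_profile((x, y), scene)
            expect = [prof.per_class_percent[c] for c in cr.CROP_CLASSES] + [prof.global_percent]
            np.testing.assert_allclose(arr[i], expect, rtol=1e-9, atol=1e-9)

    def test_monte_carlo_oracle_agreement(self):
        """Exact overlay vs point-sampling estimate on a few random scenes."""
        rng = np.random.default_rng(99)
        n_mc = 100_000
        for _ in range(5):
            scene = make_random_scene(rng, n_polygons=8)
            pt = tuple(rng.uniform(-1000, 1000, 2))
            prof = cr.crop_profile(pt, scene)
            mc = cr.monte_carlo_profile(pt, scene, n_points=n_mc, rng=rng)
            for c in cr.CROP_CLASSES:
                p = prof.per_class_percent[c] / 100.0
                sd = 100.0 * math.sqrt(max(p * (1 - p), 1e-12) / n_mc)
                assert abs(mc[c] - prof.per_class_percent[c]) <= 3 * sd + 1e-9


class TestGeoJSON:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        scene = make_random_scene(rng)
        path = tmp_path / "lc.geojson"
        cr.write_landcover_geojson(scene, path)
        back = cr.read_landcover_geojson(path, "scene")
        assert len(back.polygons) == len(scene.polygons)
        for a, b in zip(scene.polygons, back.polygons):
            assert a.crop_class == b.crop_class
            assert a.geometry.equals(b.geometry)

    def test_geographic_crs_rejected(self, tmp_path):
        doc = {
            "type": "FeatureCollection",
            "crs": {"type": "name", "properties": {"name": "urn:ogc:def:crs:OGC:1.3:CRS84"}},
            "features": [],
        }
        path = tmp_path / "geo.geojson"
        path.write_text(json.dumps(doc))
        with pytest.raises(cr.InvalidInputError, match="lon/lat"):
            cr.read_landcover_geojson(path)

    def test_missing_crop_class_rejected(self, tmp_path):
        doc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 0]]]},
                    "properties": {},
                }
            ],
        }
        path = tmp_path / "bad.geojson"
        path.write_text(json.dumps(doc))
        with pytest.raises(cr.InvalidInputError, match="crop_class"):
            cr.read_landcover_geojson(path)
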