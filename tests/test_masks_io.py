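import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doee import (
    ContourSet,
    ContourSlice,
    PixelGeometry,
    PairingError,
    SchemaError,
    ValidationError,
    pair_masks,
    rasterize_contours,
    read_contours_json,
    read_mask_volume,
    write_contours_json,
    write_mask_volume,
)


def shoelace(poly):
    x, y = np.asarray(poly, float).T
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def mask_area(stack, geom):
    return stack.sum() * geom.pixel_area


def contour_set(polys, geom=PixelGeometry(1, 1), index=0):
    return ContourSet([ContourSlice(index, [np.asarray(p, float) for p in polys])], geom)


class TestRasterize:
    def test_axis_aligned_square_area(self):
        square = [(0, 0), (10, 0), (10, 10), (0, 10)]
        stack, g = rasterize_contours(contour_set([square]), (12, 12))
        assert stack.shape == (1, 60, 60)
        # within one fine-pixel-row of the analytic 100 mm^2
        assert abs(mask_area(stack, g) - 100.0) <= 10 * 0.2

    def test_right_triangle_area_within_2pct(self):
        tri = [(0, 0), (10, 0), (0, 10)]
        stack, g = rasterize_contours(contour_set([tri]), (12, 12))
        # hypotenuse centers count as inside, so the error is exactly 2%
        assert abs(mask_area(stack, g) - shoelace(tri)) <= 0.02 * shoelace(tri) + 1e-9

    def test_empty_contour_set_gives_empty_stack(self):
        stack, _ = rasterize_contours(ContourSet([], PixelGeometry(1, 1)), (4, 4), n_slices=2)
        assert stack.shape == (2, 20, 20) and not stack.any()

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValidationError):
            ContourSlice(0, [np.array([(0, 0), (1, 1)])])

    def test_out_of_bounds_vertex_rejected(self):
        with pytest.raises(ValidationError):
            rasterize_contours(contour_set([[(0, 0), (20, 0), (0, 5)]]), (10, 10))

    def test_translation_equivariance_integer_shift(self):
        tri = np.array([(1.2, 1.7), (6.3, 2.1), (3.5, 7.8)])
        base, _ = rasterize_contours(contour_set([tri]), (16, 16))
        shifted, _ = rasterize_contours(contour_set([tri + np.array([3, 2])]), (16, 16))
        assert np.array_equal(np.roll(base, (2 * 5, 3 * 5), axis=(1, 2)), shifted)

    def test_physical_area_invariant_to_upsampling(self):
        poly = [(0.5, 0.5), (9.5, 1.0), (8.0, 9.0), (1.0, 8.0)]
        areas = []
        for f in (1, 2, 5, 8):
            stack, g = rasterize_contours(contour_set([poly]), (11, 11), upsample=f)
            areas.append(mask_area(stack, g))
        assert np.allclose(areas, shoelace(poly), rtol=0.08)

    @settings(deadline=None, max_examples=25)
    @given(st.data())
    def test_convex_polygon_converges_to_shoelace(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        # random convex polygon: hull of random points in a 3..17 box
        from scipy.spatial import ConvexHull

        pts = rng.uniform(3, 17, size=(12, 2))
        hull = ConvexHull(pts)
        poly = pts[hull.vertices]
        target = shoelace(poly)
        if target < 1.0:  # below 25 fine pixels, outside the stated floor
            return
        stack, g = rasterize_contours(contour_set([poly]), (20, 20))
        assert mask_area(stack, g) == pytest.approx(target, rel=0.05)

    def test_self_intersecting_resolved_even_odd(self, caplog):
        bowtie = [(0, 0), (10, 10), (10, 0), (0, 10)]
        with caplog.at_level("WARNING"):
            stack, g = rasterize_contours(contour_set([bowtie]), (12, 12))
        assert "self-intersecting" in caplog.text
        # even-odd bowtie covers two triangles of total area 50
        assert mask_area(stack, g) == pytest.approx(50.0, rel=0.05)


class TestContourJson:
    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 5),
                st.lists(
                    st.lists(
                        st.tuples(
                            st.floats(0, 50, allow_nan=False, width=32),
                            st.floats(0, 50, allow_nan=False, width=32),
                        ),
                        min_size=3,
                        max_size=8,
                    ),
                    max_size=3,
                ),
            ),
            max_size=4,
            unique_by=lambda t: t[0],
        )
    )
    def test_round_trip_identity(self, tmp_path_factory, slices):
        cs = ContourSet(
            [ContourSlice(i, [np.asarray(p, float) for p in polys]) for i, polys in slices],
            PixelGeometry(0.94, 0.94),
        )
        path = tmp_path_factory.mktemp("json") / "c.json"
        write_contours_json(cs, path)
        back = read_contours_json(path)
        assert back.geometry == cs.geometry
        assert len(back.slices) == len(cs.slices)
        for a, b in zip(back.slices, cs.slices):
            assert a.index == b.index
            assert len(a.polygons) == len(b.polygons)
            for pa, pb in zip(a.polygons, b.polygons):
                assert np.array_equal(pa, pb)  # bitwise-lossless coordinates

    def test_empty_set_round_trips(self, tmp_path):
        path = tmp_path / "empty.json"
        write_contours_json(ContourSet([], PixelGeometry(1, 1)), path)
        assert read_contours_json(path).slices == []

    def test_two_vertex_polygon_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            json.dumps(
                {"geometry": {"dx": 1, "dy": 1}, "slices": [{"index": 0, "polygons": [[[0, 0], [1, 1]]]}]}
            )
        )
        with pytest.raises(SchemaError, match="slices\\[0\\]"):
            read_contours_json(path)

    @pytest.mark.parametrize(
        "doc,field",
        [
            ({"slices": []}, "geometry"),
            ({"geometry": {"dx": 1, "dy": 1}}, "slices"),
            ({"geometry": {"dx": 1}, "slices": []}, "dy"),
        ],
    )
    def test_missing_keys_named(self, tmp_path, doc, field):
        path = tmp_path / "m.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match=field):
            read_contours_json(path)

    def test_malformed_json(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text("{not json")
        with pytest.raises(SchemaError):
            read_contours_json(path)


class TestMaskVolumes:
    def test_nifti_round_trip_and_header_geometry(self, tmp_path):
        mask = np.zeros((3, 8, 9), bool)
        mask[1, 2:5, 3:6] = True
        path = tmp_path / "m.nii.gz"
        write_mask_volume(mask, PixelGeometry(0.94, 0.94), path)
        back, geom = read_mask_volume(path)
        assert np.array_equal(back, mask)
        assert geom.dx == pytest.approx(0.94) and geom.dy == pytest.approx(0.94)

    def test_all_zero_volume(self, tmp_path):
        path = tmp_path / "z.nii"
        write_mask_volume(np.zeros((2, 4, 4), bool), PixelGeometry(1, 1), path)
        back, _ = read_mask_volume(path)
        assert not back.any()

    def test_explicit_geometry_wins_with_warning(self, tmp_path, caplog):
        path = tmp_path / "m.nii"
        write_mask_volume(np.zeros((1, 4, 4), bool), PixelGeometry(0.94, 0.94), path)
        with caplog.at_level("WARNING"):
            _, geom = read_mask_volume(path, PixelGeometry(2.0, 2.0))
        assert geom == PixelGeometry(2.0, 2.0)
        assert "overridden" in caplog.text

    def test_shape_mismatch_pairing_error(self):
        with pytest.raises(PairingError):
            pair_masks(np.zeros((1, 4, 4), bool), np.zeros((1, 5, 5), bool), PixelGeometry(1, 1))

    def test_missing_slices_padded_as_background(self):
        r1 = np.ones((3, 4, 4), bool)
        r2 = np.ones((2, 4, 4), bool)
        pair = pair_masks(r1, r2, PixelGeometry(1, 1))
        assert pair.shape == (3, 4, 4)
        assert not pair.rater2[2].any()

    def test_png_stack_directory(self, tmp_path):
        from imageio.v3 import imwrite

        for i, v in enumerate((0, 255)):
            imwrite(tmp_path / f"slice{i}.png", np.full((6, 6), v, np.uint8))
        mask, geom = read_mask_volume(tmp_path, PixelGeometry(1, 1))
        assert mask.shape == (2, 6, 6)
        assert not mask[0].any() and mask[1].all()

    def test_non_binary_mask_rejected(self):
        from doee import RaterMaskPair

        arr = np.zeros((1, 4, 4), np.int8)
        arr[0, 0, 0] = 3
        with pytest.raises(ValidationError):
            RaterMaskPair(arr, arr, PixelGeometry(1, 1))
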