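"""Geometry of the contour-aligned (s, t) coordinate transform."""

import numpy as np
import pytest
from scipy import ndimage

from ribsuppress.st_transform import (
    Contour, ContourError, STPoint,
    compute_centerline, forward_map, forward_map_many,
    inverse_map, inverse_map_many, mirror_position, sample_to_st,
    splat_to_image,
)
from tests.conftest import regular_polygon


class TestContour:
    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ContourError):
            Contour([(0, 0), (1, 1)])
        with pytest.raises(ContourError):
            Contour([(0, 0), (0, 0), (1, 1), (0, 1)])
        with pytest.raises(ContourError):  # bow-tie self-intersection
            Contour([(0, 0), (10, 10), (10, 0), (0, 10)])

    def test_arc_length_consistency(self, thin_rect_contour):
        c = thin_rect_contour
        assert c.total_length == pytest.approx(220.0)
        assert np.allclose(c.cum_lengths, [0, 100, 110, 210, 220])
        assert c.total_length == pytest.approx(c.edge_lengths.sum())

    def test_inward_normals_point_inside(self, square_contour):
        mid = square_contour.vertices + 0.5 * square_contour.edge_vectors
        probes = mid + 0.5 * square_contour.inward_normals
        assert square_contour.contains(probes[:, 0], probes[:, 1]).all()

    def test_orientation_independent_interior(self):
        cw = Contour([(0, 0), (0, 10), (10, 10), (10, 0)])
        assert cw.orientation == "cw"
        assert forward_map(cw, (3, 2)).s == pytest.approx(2.0)


class TestForwardInverse:
    def test_perpendicular_projection_onto_straight_edge(self, square_contour):
        p = forward_map(square_contour, (3, 2))
        assert (p.s, p.t) == (pytest.approx(2.0), pytest.approx(3.0))

    def test_points_on_contour_have_zero_offset(self, square_contour):
        p = forward_map(square_contour, (5, 0))
        assert (p.s, p.t) == (pytest.approx(0.0), pytest.approx(5.0))

    def test_inverse_of_contour_points_is_identity(self, thin_rect_contour):
        for t in (0.0, 5.0, 104.0, 215.0):
            x, y = inverse_map(thin_rect_contour, STPoint(0.0, t))
            s, t2 = forward_map_many(thin_rect_contour, [(x, y)])
            assert abs(s[0]) < 1e-9
            assert t2[0] == pytest.approx(t, abs=1e-9)

    def test_inverse_simple_edge(self, square_contour):
        assert inverse_map(square_contour, STPoint(2.0, 3.0)) == (
            pytest.approx(3.0), pytest.approx(2.0))

    def test_polar_limit_on_64gon(self):
        contour = regular_polygon(64, 5.0)
        theta = 1.0
        q = (3 * np.cos(theta), 3 * np.sin(theta))
        p = forward_map(contour, q)
        t_exact = theta / (2 * np.pi) * contour.total_length
        assert p.s == pytest.approx(2.0, abs=0.02)
        assert p.t == pytest.approx(t_exact, abs=0.15)

    def test_polar_error_decreases_with_vertex_count(self):
        thetas = np.array([0.3, 1.2, 2.5, 4.0])
        errors = []
        for n in (16, 32, 64, 128):
            contour = regular_polygon(n, 5.0)
            pts = np.column_stack([3 * np.cos(thetas), 3 * np.sin(thetas)])
            s, t = forward_map_many(contour, pts)
            t_exact = thetas / (2 * np.pi) * contour.total_length
            errors.append(max(np.abs(s - 2.0).max(), np.abs(t - t_exact).max()))
        assert all(a > b for a, b in zip(errors, errors[1:]))

    def test_round_trip_within_half_pixel(self, single_rib_phantom, rng):
        """In-band round trip, sampled away from the centerline singularity."""
        contour = single_rib_phantom.contours[0]
        mask = single_rib_phantom.masks[0]
        c, valid = compute_centerline(contour, mask, dt=1.0)
        cols = np.nonzero(valid)[0]
        pick = rng.choice(cols, size=200)
        t0 = pick * 1.0 + rng.uniform(0, 1, 200)
        s0 = rng.uniform(0.05, 0.75, 200) * np.maximum(c[pick] - 0.75, 0.5)
        pts = inverse_map_many(contour, s0, t0)
        s1, t1 = forward_map_many(contour, pts)
        dt = np.abs(t1 - t0) % contour.total_length
        dt = np.minimum(dt, contour.total_length - dt)
        assert np.abs(s1 - s0).max() < 0.5
        assert dt.max() < 0.5

    def test_ties_break_to_lowest_edge_index(self, square_contour):
        # the center is equidistant from all four edges
        p = forward_map(square_contour, (5, 5))
        assert p.s == pytest.approx(5.0)
        assert 0 <= p.t < 10.0   # edge 0 owns it


class TestMirror:
    def test_mid_thickness_is_self_symmetric(self, thin_rect_contour):
        m = mirror_position(thin_rect_contour, forward_map(thin_rect_contour, (50, 5)))
        assert m is not None and m.s == pytest.approx(5.0)

    def test_near_wall_mirrors_to_opposite_wall(self, thin_rect_contour):
        m = mirror_position(thin_rect_contour, forward_map(thin_rect_contour, (50, 2)))
        assert m is not None and m.s == pytest.approx(8.0)  # thickness - s

    def test_outside_polygon_is_undefined(self, thin_rect_contour):
        m = mirror_position(thin_rect_contour, forward_map(thin_rect_contour, (50, -3)))
        assert m is None


class TestCenterline:
    def test_rectangle_mid_thickness(self, thin_rect_contour):
        mask = np.zeros((20, 110), dtype=bool)
        mask[0:11, 0:101] = True
        c, valid = compute_centerline(thin_rect_contour, mask, dt=1.0)
        long_side = np.arange(20, 80)
        assert np.allclose(c[long_side], 5.0, atol=0.3)

    def test_circle_reaches_center(self):
        contour = regular_polygon(180, 30.0, center=(40, 40))
        yy, xx = np.mgrid[0:80, 0:80]
        mask = (xx - 40) ** 2 + (yy - 40) ** 2 <= 30 ** 2
        c, valid = compute_centerline(contour, mask, dt=2.0)
        assert valid.all()
        assert np.allclose(c, 30.0, atol=1.0)

    def test_curved_band_matches_distance_transform(self, single_rib_phantom):
        """At the medial axis the distance to the boundary equals c(t)."""
        contour = single_rib_phantom.contours[0]
        mask = single_rib_phantom.masks[0]
        c, valid = compute_centerline(contour, mask, dt=1.0)
        edt = ndimage.distance_transform_edt(mask)
        cols = np.nonzero(valid)[0][::7]
        pts = inverse_map_many(contour, c[cols], cols.astype(float))
        xi = np.clip(np.rint(pts[:, 0]).astype(int), 0, mask.shape[1] - 1)
        yi = np.clip(np.rint(pts[:, 1]).astype(int), 0, mask.shape[0] - 1)
        assert np.abs(edt[yi, xi] - c[cols]).max() <= 1.0 + 0.5


class TestSampleToST:
    def test_constant_image_samples_constant(self, thin_rect_contour):
        mask = np.zeros((20, 110), dtype=bool)
        mask[0:11, 0:101] = True
        st = sample_to_st(np.full((20, 110), 3.25), thin_rect_contour, mask=mask)
        assert st.valid.any()
        assert np.all(st.values[st.valid] == 3.25)
        assert np.isfinite(st.values[st.valid]).all()

    def test_shape_contract(self, thin_rect_contour):
        st = sample_to_st(np.zeros((20, 110)), thin_rect_contour,
                          ds=1.0, dt=1.0, s_max=4.0)
        assert st.values.shape == (5, 220)   # ceil(s_max/ds)+1, ceil(Clen/dt)

    def test_linear_field_reproduced_exactly(self, thin_rect_contour):
        """Bilinear sampling of a linear field along a straight edge gives s."""
        img = np.tile(np.arange(20.0)[:, None], (1, 110))   # value = y
        st = sample_to_st(img, thin_rect_contour, ds=1.0, dt=1.0, s_max=4.0)
        bottom = slice(10, 90)   # t along the bottom edge, inward +y
        for i in range(5):
            sel = st.valid[i, bottom]
            assert np.allclose(st.values[i, bottom][sel], float(i), atol=1e-9)

    def test_matches_independent_bilinear_oracle(self, rng, thin_rect_contour):
        img = ndimage.gaussian_filter(rng.random((20, 110)), 2.0)
        st = sample_to_st(img, thin_rect_contour, ds=1.0, dt=1.0, s_max=4.0)
        si = rng.integers(0, st.values.shape[0], 50)
        tj = rng.integers(0, st.values.shape[1], 50)
        pts = inverse_map_many(thin_rect_contour, si * st.ds, tj * st.dt)
        for (x, y), i, j in zip(pts, si, tj):
            if not st.valid[i, j]:
                continue
            x0, y0 = int(np.floor(x)), int(np.floor(y))
            fx, fy = x - x0, y - y0
            ref = (img[y0, x0] * (1 - fx) * (1 - fy)
                   + img[y0, min(x0 + 1, 109)] * fx * (1 - fy)
                   + img[min(y0 + 1, 19), x0] * (1 - fx) * fy
                   + img[min(y0 + 1, 19), min(x0 + 1, 109)] * fx * fy)
            assert st.values[i, j] == pytest.approx(ref, abs=1e-9)

    def test_lead_in_rows_lie_outside(self, thin_rect_contour):
        st = sample_to_st(np.ones((20, 110)), thin_rect_contour,
                          ds=1.0, dt=1.0, s_max=4.0, s_min=-2.0)
        assert st.s_coords[0] == -2.0
        assert st.values.shape[0] == 7


class TestSplat:
    def test_round_trips_smooth_band(self, single_rib_phantom):
        """sample -> splat reproduces a smooth field inside the band."""
        bone = single_rib_phantom.bone
        contour = single_rib_phantom.contours[0]
        mask = single_rib_phantom.masks[0]
        st = sample_to_st(bone, contour, ds=0.5, dt=0.5, mask=mask)
        out = splat_to_image(st, bone.shape, fill_mask=mask)
        inner = ndimage.binary_erosion(mask, iterations=2)
        assert np.abs(out[inner] - bone[inner]).max() < 0.02
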