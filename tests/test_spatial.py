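import numpy as np
import pytest
from shapely.geometry import Polygon

from condyn.errors import InvalidParameterError, UndefinedDistanceError
from condyn.io import MaskImage, Trajectory
from condyn.spatial import (
    BoundarySet,
    center_of_trajectory,
    density_map,
    distance_to_boundary,
    estimate_viscosity,
    extract_boundaries,
    manders_coefficients,
    mobile_fraction,
    point_in_boundary,
    predict_diffusion,
)
from condyn.synthetic import add_localization_noise, simulate_brownian, spawn_seeds

from conftest import make_traj


def boundary_from_vertices(vertices, closed=True):
    v = np.asarray(vertices, dtype=float)
    if closed and not np.allclose(v[0], v[-1]):
        v = np.vstack([v, v[0]])
    return BoundarySet(contours=(v,), closed=(closed,), is_hole=(False,),
                       pixel_size=117.0)


class TestDensityMap:
    def test_mass_conservation_both_rules(self, rng):
        trajs = [simulate_brownian(20, 0.05, 2.0, seed=s)[0]
                 for s in spawn_seeds(40, 7)]
        assert density_map(trajs, rule="trajectory-mean").total == 7
        assert density_map(trajs, rule="per-frame").total == 7 * 20

    def test_edge_point_assigned_to_higher_cell(self):
        # representative exactly on the cell edge at x = spacing
        sp_um = 0.0585
        t = make_traj([(sp_um, 0.0), (sp_um, 0.0)])
        dm = density_map([t], spacing=58.5, origin=(0.0, 0.0), shape=(2, 3))
        assert dm.counts[0, 1] == 1
        assert dm.counts[0, 0] == 0

    def test_two_grid_cells_per_camera_pixel(self):
        # 58.5 nm grid on 117 nm pixels: pixel-center neighbours land
        # exactly 2 cells apart
        t1 = make_traj([(0.0, 0.0)] * 2)
        t2 = make_traj([(0.117, 0.0)] * 2)
        dm = density_map([t1, t2], spacing=58.5, origin=(0.0, 0.0), shape=(1, 4))
        assert dm.counts[0, 0] == 1 and dm.counts[0, 2] == 1

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            density_map([], spacing=58.5)
        t = make_traj([(0, 0), (1, 1)])
        with pytest.raises(InvalidParameterError):
            density_map([t], spacing=0.0)


class TestExtractBoundaries:
    def test_rectangle_contour_area_within_half_pixel(self):
        m = np.zeros((20, 30), dtype=bool)
        m[5:10, 8:18] = True  # 10 x 5 px
        bset = extract_boundaries(MaskImage(data=m, pixel_size=1000.0))
        assert len(bset) == 1 and bset.closed[0] and not bset.is_hole[0]
        area = Polygon(bset.contours[0]).area  # um^2 at 1 um/px
        assert area == pytest.approx(50.0, abs=1.0)

    def test_disjoint_blobs_give_two_contours(self):
        m = np.zeros((30, 30), dtype=bool)
        m[3:8, 3:8] = True
        m[20:26, 20:26] = True
        bset = extract_boundaries(MaskImage(data=m, pixel_size=117.0))
        assert len(bset) == 2

    def test_full_frame_foreground_gives_single_border_contour(self):
        m = np.ones((12, 12), dtype=bool)
        bset = extract_boundaries(MaskImage(data=m, pixel_size=117.0))
        assert len(bset) == 1 and bset.closed[0]

    def test_hole_flagged_by_orientation(self):
        m = np.zeros((40, 40), dtype=bool)
        m[5:35, 5:35] = True
        m[15:25, 15:25] = False
        bset = extract_boundaries(MaskImage(data=m, pixel_size=117.0))
        assert sorted(bset.is_hole) == [False, True]

    def test_empty_mask_gives_empty_set(self):
        bset = extract_boundaries(MaskImage(data=np.zeros((5, 5), bool),
                                            pixel_size=117.0))
        assert len(bset) == 0


class TestPointInBoundary:
    SQUARE = [(0, 0), (4, 0), (4, 4), (0, 4)]

    def test_center_inside_far_point_outside(self):
        bset = boundary_from_vertices(self.SQUARE)
        assert point_in_boundary((2, 2), bset) == "inside"
        assert point_in_boundary((9, 9), bset) == "outside"

    def test_point_on_vertex_counts_inside(self):
        bset = boundary_from_vertices(self.SQUARE)
        assert point_in_boundary((4.0, 4.0), bset) == "inside"

    def test_point_in_hole_is_outside(self):
        m = np.zeros((40, 40), dtype=bool)
        m[5:35, 5:35] = True
        m[15:25, 15:25] = False
        bset = extract_boundaries(MaskImage(data=m, pixel_size=1000.0))
        assert point_in_boundary((10.0, 10.0), bset) == "inside"
        assert point_in_boundary((20.0, 20.0), bset) == "outside"

    def test_agrees_with_ray_casting_oracle(self, rng):
        # random star-shaped polygon vs an independent even-odd ray cast
        angles = np.sort(rng.uniform(0, 2 * np.pi, 12))
        radii = rng.uniform(1.0, 3.0, 12)
        verts = np.column_stack([radii * np.cos(angles) + 4,
                                 radii * np.sin(angles) + 4])
        bset = boundary_from_vertices(verts)

        def ray_cast(px, py):
            inside = False
            v = np.vstack([verts, verts[0]])
            for (x1, y1), (x2, y2) in zip(v[:-1], v[1:]):
                if (y1 > py) != (y2 > py):
                    xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if xint > px:
                        inside = not inside
            return inside

        pts = rng.uniform(0, 8, size=(1000, 2))
        for px, py in pts:
            expected = "inside" if ray_cast(px, py) else "outside"
            assert point_in_boundary((px, py), bset) == expected

    def test_open_contours_only_warns_outside(self):
        v = np.array([(0.0, 0.0), (1.0, 0.0), (2.0, 1.0)])
        bset = BoundarySet(contours=(v,), closed=(False,), is_hole=(False,),
                           pixel_size=117.0)
        assert point_in_boundary((1.0, 0.2), bset) == "outside"


class TestDistanceToBoundary:
    def test_circle_distance(self):
        theta = np.linspace(0, 2 * np.pi, 2000)
        circle = np.column_stack([3 * np.cos(theta), 3 * np.sin(theta)])
        bset = boundary_from_vertices(circle)
        assert distance_to_boundary((5.0, 0.0), bset) == pytest.approx(2000.0, abs=1.0)

    def test_point_on_contour_is_zero(self):
        bset = boundary_from_vertices([(0, 0), (2, 0), (2, 2), (0, 2)])
        assert distance_to_boundary((1.0, 0.0), bset) == pytest.approx(0.0, abs=1e-9)

    def test_matches_dense_resampling_oracle_within_1nm(self, rng):
        # oracle: resample every contour segment at 1 nm and take the
        # nearest vertex; segment-based distances must agree to 1 nm
        for _ in range(5):
            verts = rng.uniform(0, 5, size=(8, 2))
            bset = boundary_from_vertices(verts)
            v = np.vstack([verts, verts[0]])
            dense = []
            for a, b in zip(v[:-1], v[1:]):
                seg_len_nm = np.linalg.norm(b - a) * 1000
                n = max(2, int(np.ceil(seg_len_nm)))
                frac = np.linspace(0, 1, n)[:, None]
                dense.append(a + frac * (b - a))
            dense = np.vstack(dense)
            for p in rng.uniform(-1, 6, size=(40, 2)):
                oracle_nm = np.min(np.linalg.norm(dense - p, axis=1)) * 1000
                assert distance_to_boundary(tuple(p), bset) == pytest.approx(
                    oracle_nm, abs=1.0)

    def test_empty_set_is_undefined(self):
        bset = BoundarySet(contours=(), closed=(), is_hole=(), pixel_size=117.0)
        with pytest.raises(UndefinedDistanceError):
            distance_to_boundary((0, 0), bset)


class TestCenterOfTrajectory:
    def test_static_trajectory_returns_its_position(self):
        t = make_traj([(2.5, 1.5)] * 5)
        assert center_of_trajectory(t) == pytest.approx((2.5, 1.5))

    def test_symmetric_oscillation_centers_on_midpoint(self):
        pos = [(2 + (-1) ** i * 0.5, 2 - (-1) ** i * 0.5) for i in range(26)]
        t = make_traj(pos, dt=2.0)
        assert center_of_trajectory(t) == pytest.approx((2.0, 2.0))

    def test_only_first_interval_is_averaged(self):
        # 26 frames at dt=2 s: frames within the first 50 s sit at (1, 1),
        # the later excursion to (9, 9) must not contribute
        pos = [(1.0, 1.0)] * 26 + [(9.0, 9.0)] * 10
        t = make_traj(pos, dt=2.0)
        assert center_of_trajectory(t, interval=50.0) == pytest.approx((1.0, 1.0))

    def test_short_span_uses_full_trajectory(self):
        t = make_traj([(0, 0), (2, 2)], dt=2.0)
        assert center_of_trajectory(t, interval=50.0) == pytest.approx((1.0, 1.0))


class TestManders:
    def test_identical_images_give_unit_coefficients(self, rng):
        img = rng.random((20, 20))
        res = manders_coefficients(img, img, threshold_policy=(0.5, 0.5))
        assert res.m1 == pytest.approx(1.0)
        assert res.m2 == pytest.approx(1.0)

    def test_disjoint_foregrounds_give_zero(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[:5] = 1.0
        b[6:] = 1.0
        res = manders_coefficients(a, b, threshold_policy="zero")
        assert res.m1 == 0.0 and res.m2 == 0.0

    def test_half_overlap_counting(self):
        a = np.zeros((20, 20))
        b = np.zeros((20, 20))
        a[0:10, 0:10] = 1.0   # 100 px
        b[5:15, 0:10] = 1.0   # overlaps 50 of them
        res = manders_coefficients(a, b, threshold_policy="zero")
        assert res.m1 == pytest.approx(0.5)
        assert res.m2 == pytest.approx(0.5)

    def test_all_zero_channel_is_undefined_not_zero(self):
        a = np.zeros((8, 8))
        b = np.ones((8, 8))
        res = manders_coefficients(a, b, threshold_policy="zero")
        assert np.isnan(res.m1)

    def test_invariant_to_uniform_rescaling(self, rng):
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        r1 = manders_coefficients(a, b, threshold_policy=(0.4, 0.6))
        r2 = manders_coefficients(5 * a, b, threshold_policy=(2.0, 0.6))
        assert r1.m1 == pytest.approx(r2.m1)
        assert r1.m2 == pytest.approx(r2.m2)


class TestStokesEinstein:
    def test_water_like_viscosity_roundtrip_values(self):
        # r = 20 nm, eta = 1 mPa s, T = 310 K -> D ~ 11.35 um^2/s
        assert predict_diffusion(20.0, 1e-3, 310.0) == pytest.approx(11.35, abs=0.01)
        est = estimate_viscosity(11.35, 20.0, 310.0)
        assert est.viscosity == pytest.approx(1.00e-3, rel=0.01)

    def test_slow_probe_implies_viscous_medium(self):
        est = estimate_viscosity(0.5, 20.0, 310.0)
        assert est.viscosity == pytest.approx(0.0227, rel=0.01)

    def test_doubling_d_halves_viscosity(self):
        a = estimate_viscosity(1.0, 20.0).viscosity
        b = estimate_viscosity(2.0, 20.0).viscosity
        assert a == pytest.approx(2 * b, rel=1e-12)

    def test_pair_are_exact_inverses(self):
        for r, eta, T in [(20.0, 1e-3, 310.0), (110.0, 0.05, 298.0)]:
            D = predict_diffusion(r, eta, T)
            assert estimate_viscosity(D, r, T).viscosity == pytest.approx(eta, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            estimate_viscosity(0.0, 20.0)
        with pytest.raises(InvalidParameterError):
            predict_diffusion(-1.0, 1e-3)


def test_boundary_records_roundtrip_vertices():
    from condyn.spatial import boundary_records
    m = np.zeros((20, 20), dtype=bool)
    m[4:10, 4:12] = True
    bset = extract_boundaries(MaskImage(data=m, pixel_size=117.0))
    (rec,) = boundary_records(bset)
    assert rec["type"] == "Polygon" and rec["closed"] and not rec["is_hole"]
    assert np.allclose(rec["coordinates"], bset.contours[0])


class TestMobileFraction:
    def test_all_static_is_zero_all_walkers_is_one(self):
        static = [make_traj([(i, i)] * 5, track_id=i) for i in range(3)]
        walkers = [make_traj([(0.1 * j + i, 0) for j in range(5)], track_id=i)
                   for i in range(3)]
        assert mobile_fraction(static)["fraction"] == 0.0
        assert mobile_fraction(walkers)["fraction"] == 1.0

    def test_mixed_population_fraction(self):
        trajs = []
        # 500 frames per track: the static+noise mean step (28.4 nm) then
        # resolves well below the 30 nm threshold (SE ~ 0.7 nm)
        seeds = spawn_seeds(41, 100)
        n = 500
        for i in range(30):
            t = Trajectory(track_id=i, frames=np.arange(n),
                           x=np.zeros(n), y=np.zeros(n), dt=2.0)
            trajs.append(add_localization_noise(t, 16.0, seed=seeds[i]))
        for i in range(30, 100):
            t, _ = simulate_brownian(n, 0.1, 2.0, seed=seeds[i], track_id=i)
            trajs.append(add_localization_noise(t, 16.0, seed=seeds[i].spawn(1)[0]))
        res = mobile_fraction(trajs)
        assert res["fraction"] == pytest.approx(0.70, abs=0.05)
        assert res["n_total"] == 100
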