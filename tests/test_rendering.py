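import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arlabels.geometry import RigidTransform, TriangleMesh
from arlabels.primitives import icosphere
from arlabels.rendering import (
    CameraModel,
    DepthMap,
    VisibilityState,
    project_point,
    render_chromadepth,
    render_instrument_masks,
    render_label_map,
    visibility,
)
from arlabels.synth import analytic_sphere_silhouette

CAM = CameraModel(fx=500.0, fy=500.0, cx=320.0, cy=240.0, width=640, height=480)
CAM_F1000 = CameraModel(fx=1000.0, fy=1000.0, cx=320.0, cy=240.0, width=640, height=480)
IDENT = RigidTransform.identity()


def square(z, half, name="sq"):
    v = [[-half, -half, z], [half, -half, z], [half, half, z], [-half, half, z]]
    return TriangleMesh(v, [[0, 1, 2], [0, 2, 3]], name=name)


class TestProjectPoint:
    def test_optical_axis(self):
        assert project_point(CAM, [0, 0, 100.0]) == (CAM.cx, CAM.cy)

    def test_closed_form_offset(self):
        u, v = project_point(CAM_F1000, [10.0, 0.0, 100.0])
        assert (u, v) == (320.0 + 100.0, 240.0)

    def test_behind_camera(self):
        assert project_point(CAM, [0, 0, -50.0]) is None
        assert project_point(CAM, [0, 0, 0.0]) is None

    def test_distortion_matches_independent_oracle(self, rng):
        cam = CameraModel(fx=450.0, fy=460.0, cx=300.0, cy=250.0, width=640, height=480,
                          k1=-0.2, k2=0.05, p1=1e-3, p2=-5e-4, k3=0.01)

        def oracle(p):
            # independently coded Brown-Conrady forward model
            x, y = p[0] / p[2], p[1] / p[2]
            r2 = x * x + y * y
            rad = 1 + cam.k1 * r2 + cam.k2 * r2 * r2 + cam.k3 * r2 * r2 * r2
            xd = x * rad + 2 * cam.p1 * x * y + cam.p2 * (r2 + 2 * x * x)
            yd = y * rad + cam.p1 * (r2 + 2 * y * y) + 2 * cam.p2 * x * y
            return cam.fx * xd + cam.cx, cam.fy * yd + cam.cy

        for _ in range(100):
            p = np.array([rng.uniform(-40, 40), rng.uniform(-30, 30), rng.uniform(60, 300)])
            got = project_point(cam, p)
            exp = oracle(p)
            assert abs(got[0] - exp[0]) < 1e-6 and abs(got[1] - exp[1]) < 1e-6


class TestRenderLabelMap:
    def test_empty_scene(self):
        lm, dm = render_label_map(CAM, [])
        assert not lm.pixels.any() and not dm.pixels.any()

    def test_sphere_silhouette_area(self):
        mesh = icosphere(10.0, 4, center=(0, 0, 100.0), name="s")
        lm, _ = render_label_map(CAM, [(mesh, IDENT, 1)])
        area = int((lm.pixels == 1).sum())
        _, _, expected = analytic_sphere_silhouette(CAM, [0, 0, 100.0], 10.0)
        assert abs(area - expected) / expected < 0.01

    def test_z_order(self):
        near, far = square(50.0, 5.0, "near"), square(100.0, 20.0, "far")
        lm, dm = render_label_map(CAM, [(near, IDENT, 1), (far, IDENT, 2)])
        # overlap region (near square spans +-50 px about centre): label 1 wins
        assert lm.pixels[240, 320] == 1
        assert (lm.pixels[216:264, 296:344] == 1).all()
        assert lm.pixels[240, 320 + 70] == 2

    def test_label_depth_consistent(self):
        mesh = icosphere(10.0, 3, center=(5, -5, 120.0))
        lm, dm = render_label_map(CAM, [(mesh, IDENT, 7)])
        assert np.array_equal(lm.pixels > 0, dm.pixels > 0)
        assert (dm.pixels[dm.pixels > 0] > 0).all()

    def test_deterministic(self):
        mesh = icosphere(8.0, 3, center=(0, 0, 90.0))
        a = render_label_map(CAM, [(mesh, IDENT, 3)])
        b = render_label_map(CAM, [(mesh, IDENT, 3)])
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)

    def test_shrinking_never_grows(self):
        base = icosphere(12.0, 3, center=(0, 0, 100.0))
        count_prev = None
        for scale in (1.0, 0.8, 0.5, 0.2):
            centroid = base.centroid()
            shrunk = TriangleMesh(centroid + scale * (base.vertices - centroid), base.faces)
            lm, _ = render_label_map(CAM, [(shrunk, IDENT, 1)])
            count = int((lm.pixels == 1).sum())
            if count_prev is not None:
                assert count <= count_prev
            count_prev = count

    def test_near_plane_clipping(self):
        mesh = icosphere(10.0, 2, center=(0, 0, -30.0))
        lm, dm = render_label_map(CAM, [(mesh, IDENT, 1)])
        assert not lm.pixels.any()

    def test_distorted_sphere_still_renders(self):
        cam = CameraModel(fx=500.0, fy=500.0, cx=320.0, cy=240.0, width=640, height=480, k1=-0.3)
        mesh = icosphere(10.0, 3, center=(15, 5, 100.0))
        lm, _ = render_label_map(cam, [(mesh, IDENT, 1)])
        assert (lm.pixels == 1).sum() > 1000


class TestInstrumentMasks:
    def _depth(self):
        mesh = icosphere(15.0, 3, center=(0, 0, 100.0))
        return render_label_map(CAM, [(mesh, IDENT, 1)])[1]

    def test_outside_frustum_empty(self):
        depth = self._depth()
        inst = [dict(name="g", valid=True, tip_cam=np.array([500.0, 0, 100.0]),
                     entry_cam=np.array([600.0, 0, 50.0]), tool_radius=3.0)]
        masks = render_instrument_masks(CAM, inst, depth, amodal=True)
        assert not masks["g"].pixels.any()
        vis = visibility(CAM, [500.0, 0, 100.0], depth)
        assert vis.state == VisibilityState.OFF_SCREEN

    def test_capsule_silhouette_area(self):
        # on-axis capsule pointing away from the camera: silhouette is close
        # to a disc of angular radius r/z plus the swept rectangle
        depth = DepthMap(np.zeros((480, 640), dtype=np.float32))
        r, z0 = 4.0, 80.0
        inst = [dict(name="g", valid=True, tip_cam=np.array([0.0, 0, z0]),
                     entry_cam=np.array([0.0, 0, z0 + 60.0]), tool_radius=r)]
        masks = render_instrument_masks(CAM, inst, depth, amodal=True)
        area = int(masks["g"].pixels.sum())
        expected = np.pi * (CAM.fx * r / z0) ** 2  # dominated by the near cap disc
        assert abs(area - expected) / expected < 0.05

    def test_amodal_vs_visible(self):
        depth = self._depth()  # sphere front face at z=85
        inst = [dict(name="g", valid=True, tip_cam=np.array([0.0, 0, 130.0]),
                     entry_cam=np.array([0.0, -80.0, 150.0]), tool_radius=3.0)]
        amodal = render_instrument_masks(CAM, inst, depth, amodal=True)["g"]
        modal = render_instrument_masks(CAM, inst, depth, amodal=False)["g"]
        assert amodal.pixels.sum() > modal.pixels.sum()
        # every visible pixel is part of the amodal silhouette
        assert not (modal.pixels & ~amodal.pixels).any()

    def test_invalid_pose(self):
        depth = self._depth()
        masks = render_instrument_masks(CAM, [dict(name="g", valid=False)], depth)
        assert not masks["g"].valid and not masks["g"].pixels.any()


class TestVisibility:
    def test_behind_camera(self):
        assert visibility(CAM, [0, 0, -50.0]).state == VisibilityState.BEHIND_CAMERA

    def test_off_screen(self):
        assert visibility(CAM, [1000.0, 0, 100.0]).state == VisibilityState.OFF_SCREEN

    def test_occluded_behind_sphere(self):
        mesh = icosphere(15.0, 3, center=(0, 0, 100.0))
        _, depth = render_label_map(CAM, [(mesh, IDENT, 1)])
        vis = visibility(CAM, [0, 0, 150.0], depth)
        assert vis.state == VisibilityState.ON_SCREEN and vis.occluded
        vis2 = visibility(CAM, [0, 0, 50.0], depth)
        assert vis2.state == VisibilityState.ON_SCREEN and not vis2.occluded


class TestChromadepth:
    def test_near_is_red(self):
        depth = DepthMap(np.array([[50.0]], dtype=np.float32))
        rgb = render_chromadepth(depth, 50.0, 150.0)
        assert tuple(rgb[0, 0]) == (255, 0, 0)

    def test_midpoint_is_green(self):
        depth = DepthMap(np.array([[100.0]], dtype=np.float32))
        rgb = render_chromadepth(depth, 50.0, 150.0)
        assert tuple(rgb[0, 0]) == (0, 255, 0)

    def test_far_is_blue_and_clamped(self):
        depth = DepthMap(np.array([[150.0, 500.0]], dtype=np.float32))
        rgb = render_chromadepth(depth, 50.0, 150.0)
        assert tuple(rgb[0, 0]) == (0, 0, 255)
        assert tuple(rgb[0, 1]) == (0, 0, 255)

    def test_background_black(self):
        depth = DepthMap(np.zeros((2, 2), dtype=np.float32))
        rgb = render_chromadepth(depth, 50.0, 150.0)
        assert not rgb.any()

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            render_chromadepth(DepthMap(np.zeros((1, 1), dtype=np.float32)), 10.0, 10.0)

    @given(st.lists(st.floats(1.0, 400.0), min_size=2, max_size=30))
    @settings(max_examples=40, deadline=None)
    def test_deeper_never_redder(self, depths):
        arr = np.array(depths, dtype=np.float32).reshape(1, -1)
        rgb = render_chromadepth(DepthMap(arr), 20.0, 300.0).astype(int)
        order = np.argsort(arr[0], kind="stable")
        reds = rgb[0, order, 0]
        assert (np.diff(reds) <= 0).all()


class TestSphereSilhouetteOracle:
    def test_on_axis_closed_form(self):
        center, radius, area = analytic_sphere_silhouette(CAM, [0, 0, 100.0], 10.0)
        expected_r = 500.0 * 10.0 / np.sqrt(100.0**2 - 10.0**2)
        assert abs(radius - expected_r) < 1e-9
        assert abs(area - np.pi * expected_r**2) < 1e-6
        assert center == (320.0, 240.0)

    def test_small_radius_limit(self):
        _, _, area = analytic_sphere_silhouette(CAM, [0, 0, 100.0], 1e-4)
        assert area < 1e-3

    def test_doubling_distance_halves_radius(self):
        _, r1, _ = analytic_sphere_silhouette(CAM, [0, 0, 500.0], 5.0)
        _, r2, _ = analytic_sphere_silhouette(CAM, [0, 0, 1000.0], 5.0)
        assert abs(r1 / r2 - 2.0) < 0.01

    def test_off_axis_matches_numeric_projection(self, rng):
        center = np.array([30.0, -20.0, 150.0])
        r = 12.0
        _, _, area = analytic_sphere_silhouette(CAM, center, r)
        # numeric oracle: project many surface points, take the convex hull area
        from scipy.spatial import ConvexHull

        pts = rng.normal(size=(20000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        world = center + r * pts
        uv, behind = CAM.project(world)
        hull = ConvexHull(uv[~behind])
        assert abs(hull.volume - area) / area < 0.01

    def test_camera_inside_sphere(self):
        with pytest.raises(ValueError):
            analytic_sphere_silhouette(CAM, [0, 0, 5.0], 10.0)
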