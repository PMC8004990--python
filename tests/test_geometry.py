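"""Gaze-ray geometry: angles, poses, ray casting, camera projection."""

import numpy as np
import pytest

from gaze3d.geometry import (
    Box,
    CameraModel,
    Pose,
    Quad,
    SceneCollider,
    Sphere,
    angular_distance,
    cast_ray,
    load_scene,
    project_to_image,
    save_scene,
)

from oracles import cast_ray_bruteforce


def random_unit(rng, n=1):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestAngularDistance:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ((0, 0, 1), (0, 0, 1), 0.0),
            ((0, 0, 1), (1, 0, 0), 90.0),
            ((0, 0, 1), (0, 0, -1), 180.0),
            ((0, 0, 2.5), (0, 0, 1), 0.0),  # magnitude-invariant
        ],
    )
    def test_reference_angles(self, u, v, expected):
        assert angular_distance(u, v) == pytest.approx(expected)

    def test_one_degree_closed_form(self):
        v = (0.0, np.tan(np.radians(1.0)), 1.0)
        assert angular_distance((0, 0, 1), v) == pytest.approx(1.0, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angular_distance((0, 0, 0), (0, 0, 1))

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(200):
            u, v, w = random_unit(rng, 3)
            duv = angular_distance(u, v)
            assert duv == pytest.approx(angular_distance(v, u))
            assert duv <= angular_distance(u, w) + angular_distance(w, v) + 1e-9


class TestPose:
    def test_local_world_round_trip_identity(self, rng):
        for _ in range(50):
            pose = Pose(
                position=rng.normal(size=3),
                rotation=rng.uniform(-180, 180, size=3),
                scale=rng.uniform(0.2, 3.0, size=3),
            )
            pts = rng.normal(size=(10, 3))
            back = pose.inverse_transform_points(pose.transform_points(pts))
            np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_yaw_turns_forward_toward_x(self):
        pose = Pose(rotation=(0, 90, 0))
        np.testing.assert_allclose(
            pose.transform_directions(np.array([[0, 0, 1.0]]))[0],
            [1, 0, 0],
            atol=1e-12,
        )

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            Pose(scale=(1, 0, 1))


class TestCastRay:
    def test_sphere_hit_front_surface(self):
        scene = [SceneCollider("s", Sphere(0.5), Pose(position=(0, 0, 2)))]
        hit = cast_ray((0, 0, 0), (0, 0, 1), scene)
        assert hit.hit
        np.testing.assert_allclose(hit.point, [0, 0, 1.5], atol=1e-12)
        assert hit.distance == pytest.approx(1.5)
        assert hit.object_name == "s"

    def test_miss_returns_no_hit(self):
        scene = [SceneCollider("s", Sphere(0.5), Pose(position=(0, 2, 0)))]
        assert not cast_ray((0, 0, 0), (0, 0, 1), scene).hit

    def test_nearest_of_two_spheres(self):
        scene = [
            SceneCollider("far", Sphere(0.5), Pose(position=(0, 0, 3.5))),
            SceneCollider("near", Sphere(0.5), Pose(position=(0, 0, 2.0))),
        ]
        hit = cast_ray((0, 0, 0), (0, 0, 1), scene)
        assert hit.object_name == "near"
        assert hit.distance == pytest.approx(1.5)

    def test_quad_hit_from_both_sides(self):
        scene = [SceneCollider("q", Quad(1, 1), Pose(position=(0, 0, 2)))]
        assert cast_ray((0, 0, 0), (0, 0, 1), scene).hit
        assert cast_ray((0, 0, 4), (0, 0, -1), scene).hit

    def test_aoi_layer_is_separate(self):
        scene = [
            SceneCollider("wall", Quad(4, 4), Pose(position=(0, 0, 2))),
            SceneCollider("aoi", Sphere(0.2), Pose(position=(0, 0, 1)), is_aoi=True),
        ]
        aoi_hit = cast_ray((0, 0, 0), (0, 0, 1), scene, aoi_only=True)
        assert aoi_hit.object_name == "aoi"

    def test_local_point_respects_pose(self):
        pose = Pose(position=(1, 2, 3), rotation=(0, 90, 0))
        scene = [SceneCollider("b", Box((0.5, 0.5, 0.5)), pose)]
        hit = cast_ray((1, 2, 0), (0, 0, 1), scene)
        assert hit.hit
        np.testing.assert_allclose(
            pose.transform_points(hit.local_point[np.newaxis])[0], hit.point, atol=1e-9
        )

    def test_matches_bruteforce_on_random_scenes(self, rng):
        shapes = [
            lambda: Sphere(rng.uniform(0.1, 0.8)),
            lambda: Box(rng.uniform(0.1, 0.8, size=3)),
            lambda: Quad(rng.uniform(0.2, 1.5), rng.uniform(0.2, 1.5)),
        ]
        for trial in range(20):
            scene = [
                SceneCollider(
                    f"c{k}",
                    shapes[rng.integers(3)](),
                    Pose(
                        position=rng.normal(scale=2.0, size=3),
                        rotation=rng.uniform(-180, 180, size=3),
                        scale=rng.uniform(0.5, 2.0, size=3),
                    ),
                    is_aoi=bool(rng.integers(2)),
                )
                for k in range(rng.integers(1, 10))
            ]
            for _ in range(50):
                origin = rng.normal(scale=3.0, size=3)
                direction = random_unit(rng)[0]
                for aoi_only in (False, True):
                    hit = cast_ray(origin, direction, scene, aoi_only=aoi_only)
                    expected = cast_ray_bruteforce(origin, direction, scene, aoi_only)
                    if expected is None:
                        assert not hit.hit
                    else:
                        assert hit.hit
                        assert hit.distance == pytest.approx(expected[0], abs=1e-7)
                        assert hit.object_name == expected[1]


class TestProjection:
    camera = CameraModel(focal=(1000.0, 1000.0), principal=(960.0, 540.0))

    def test_optical_axis_maps_to_principal_point(self):
        p = project_to_image((0, 0, 2.0), self.camera)
        assert (p.u, p.v) == (960.0, 540.0)
        assert p.in_bounds

    def test_point_behind_camera_is_none(self):
        assert project_to_image((0, 0, -1.0), self.camera) is None

    def test_pinhole_formula(self):
        p = project_to_image((0.1, 0, 1.0), self.camera)
        assert p.u == pytest.approx(1060.0)

    def test_out_of_bounds_flagged(self):
        p = project_to_image((5.0, 0, 1.0), self.camera)
        assert p is not None and not p.in_bounds

    def test_camera_center_rejected(self):
        with pytest.raises(ValueError):
            project_to_image((0, 0, 0), self.camera)

    def test_head_pose_moves_camera(self):
        # head turned 90 deg to the right: a point on world +x is on-axis
        p = project_to_image((2, 0, 0), self.camera, head_pose=Pose(rotation=(0, 90, 0)))
        assert p.u == pytest.approx(960.0, abs=1e-6)


class TestSceneFiles:
    def test_scene_round_trip(self, tmp_path):
        scene = [
            SceneCollider("s", Sphere(0.25), Pose(position=(0, 1, 2)), is_aoi=True),
            SceneCollider("q", Quad(1.5, 0.8), Pose(rotation=(0, 45, 0))),
            SceneCollider("b", Box((0.1, 0.2, 0.3))),
        ]
        path = tmp_path / "scene.yaml"
        save_scene(scene, path)
        loaded = load_scene(path)
        assert [c.name for c in loaded] == ["s", "q", "b"]
        assert loaded[0].is_aoi and not loaded[1].is_aoi
        assert loaded[2].shape.half_extents.tolist() == [0.1, 0.2, 0.3]
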