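"""Marker pose, silhouette cones, two-view sphere fit, pair validity."""

import numpy as np
import pytest

from fluoroplan import (
    CircleCandidate,
    Cone,
    Pose,
    Sphere,
    camera_frame,
    cone_from_silhouette,
    estimate_marker_pose,
    fit_sphere_two_views,
    make_scene,
    render_features,
    select_best_pair,
    validate_pair,
)
from fluoroplan.errors import (
    DegenerateGeometry,
    GeometryError,
    InsufficientFeatures,
    NoValidPair,
)
from fluoroplan.evaluation import reconstruct_scene, rotation_error_deg


@pytest.fixture(scope="module")
def recon_zero():
    scene = make_scene(seed=21)
    return scene, reconstruct_scene(scene, noise_sigma_px=0.0, seed=21)


class TestMarkerPose:
    def test_zero_noise_recovers_ground_truth(self, recon_zero):
        _, rec = recon_zero
        for est, truth in zip(rec.pose_estimates, rec.true_poses):
            assert rotation_error_deg(est, truth) < np.degrees(1e-5)
            assert np.linalg.norm(est.pose.translation - truth.translation) < 1e-4
            assert est.rms_residual < 1e-6

    def test_two_holes_insufficient(self, scene, marker):
        fs = render_features(scene, 0, noise_sigma_px=0.0, seed=0)
        crippled = fs.__class__.__new__(fs.__class__)
        object.__setattr__(crippled, "image_id", fs.image_id)
        object.__setattr__(crippled, "hole_features", fs.hole_features[:2])
        object.__setattr__(crippled, "head_circle", fs.head_circle)
        object.__setattr__(crippled, "noise_sigma", 0.0)
        canonical, _ = camera_frame(scene.cameras[0])
        with pytest.raises(InsufficientFeatures):
            estimate_marker_pose(crippled, marker, canonical)

    def test_asymmetric_marker_pose_is_unambiguous(self, marker):
        """The fixture's asymmetric hole triangle breaks the two-fold
        circle-pose ambiguity: no AmbiguousPose over many scenes."""
        for seed in range(10):
            scene = make_scene(seed=300 + seed)
            fs = render_features(scene, 0, noise_sigma_px=0.3, seed=seed)
            canonical, _ = camera_frame(scene.cameras[0])
            estimate_marker_pose(fs, scene.marker, canonical)  # must not raise


class TestCone:
    def test_principal_circle_closed_form(self, scene):
        """Circle at the principal point: axis = principal ray, half-angle
        arctan(r_px * spacing / SDD)."""
        cam, _ = camera_frame(scene.cameras[0])
        r_px = 90.0
        cone = cone_from_silhouette(
            cam, CircleCandidate(center=cam.principal_pixel, radius=r_px), Pose.identity()
        )
        expected = np.arctan(r_px * cam.pixel_spacing / cam.source_detector_distance)
        assert cone.half_angle == pytest.approx(expected, abs=1e-9)
        assert np.allclose(cone.axis, [0, 0, 1], atol=1e-9)
        assert np.allclose(cone.apex, cam.source, atol=1e-12)

    def test_zero_radius_circle_rejected(self, scene):
        cam, _ = camera_frame(scene.cameras[0])
        with pytest.raises(GeometryError):
            cone_from_silhouette(
                cam, CircleCandidate(center=cam.principal_pixel, radius=0.0), Pose.identity()
            )

    def test_zero_noise_cone_is_tangent_to_truth(self, recon_zero):
        scene, rec = recon_zero
        for i, (est, cam) in enumerate(zip(rec.pose_estimates, scene.cameras)):
            fs = render_features(scene, i, noise_sigma_px=0.0, seed=21)
            canonical, _ = camera_frame(cam)
            cone = cone_from_silhouette(canonical, fs.head_circle, est)
            d = np.linalg.norm(scene.sphere.center - cone.apex)
            assert abs(np.sin(cone.half_angle) * d - scene.sphere.radius) < 1e-3


class TestSphereFit:
    def test_zero_noise_recovers_sphere(self, recon_zero):
        scene, rec = recon_zero
        assert np.linalg.norm(rec.sphere_fit.sphere.center - scene.sphere.center) < 1e-3
        assert abs(rec.sphere_fit.sphere.radius - scene.sphere.radius) < 1e-3

    def test_fifty_zero_noise_scenes_recover_sphere(self):
        """End-to-end zero-noise identity over 50 random 30-degree scenes."""
        for seed in range(50):
            scene = make_scene(seed=7000 + seed)
            rec = reconstruct_scene(scene, noise_sigma_px=0.0, seed=seed)
            assert np.linalg.norm(rec.sphere_fit.sphere.center - scene.sphere.center) < 1e-3
            assert abs(rec.sphere_fit.sphere.radius - scene.sphere.radius) < 1e-3
            for est, truth in zip(rec.pose_estimates, rec.true_poses):
                assert rotation_error_deg(est, truth) < np.degrees(1e-5)

    def test_identical_cones_degenerate(self):
        c = Cone(apex=[0, 0, -600.0], axis=[0, 0, 1.0], half_angle=0.04)
        with pytest.raises(DegenerateGeometry):
            fit_sphere_two_views(c, c)

    def test_symmetric_cones_give_center_on_bisector_plane(self):
        """Two cones mirrored across the y-z plane: the fitted center has
        zero signed distance to the bisector plane."""
        ha = np.arcsin(24.0 / 600.0)
        s, c15 = np.sin(np.radians(15)), np.cos(np.radians(15))
        ca = Cone(apex=[-600 * s, 0, -600 * c15], axis=[s, 0, c15], half_angle=ha)
        cb = Cone(apex=[600 * s, 0, -600 * c15], axis=[-s, 0, c15], half_angle=ha)
        fit = fit_sphere_two_views(ca, cb)
        assert abs(fit.sphere.center[0]) < 1e-6
        assert fit.sphere.radius == pytest.approx(24.0, abs=1e-6)

    def test_candidates_sorted_by_residual(self):
        """Two-view fit reports its local minima ranked by residual."""
        ha = np.arcsin(24.0 / 610.0)
        s15, c15 = np.sin(np.radians(15)), np.cos(np.radians(15))
        ca = Cone(apex=[-610 * s15, 2.0, -610 * c15], axis=[s15, 0, c15], half_angle=ha)
        cb = Cone(apex=[610 * s15, -1.0, -605 * c15], axis=[-s15, 0.003, c15], half_angle=ha * 1.02)
        fit = fit_sphere_two_views(ca, cb)
        residuals = [r for _, r in fit.candidates]
        assert residuals == sorted(residuals)
        assert np.allclose(fit.candidates[0][0].center, fit.sphere.center)

    def test_narrow_pairs_degrade_monotonically(self):
        """Median sphere-center error at 15-20 deg exceeds 30-35 deg on
        matched seeds (the geometric rationale of the validity rule)."""
        med = {}
        for angle in (15.0, 20.0, 30.0, 35.0):
            errs = []
            for seed in range(12):
                scene = make_scene(view_angle_deg=angle, seed=5000 + seed)
                rec = reconstruct_scene(scene, noise_sigma_px=0.5, seed=seed)
                errs.append(np.linalg.norm(rec.sphere_fit.sphere.center - scene.sphere.center))
            med[angle] = float(np.median(errs))
        assert min(med[15.0], med[20.0]) > max(med[30.0], med[35.0]) * 0.999
        assert med[15.0] > med[35.0]


class TestPairValidity:
    @staticmethod
    def _pair(angle):
        scene = make_scene(view_angle_deg=angle, seed=77)
        return scene, (Pose.identity(), Pose.identity())

    def test_thirty_degree_pair_is_valid(self):
        scene, poses = self._pair(30.0)
        v = validate_pair(*poses, *scene.cameras, reference=scene.sphere.center)
        assert v.valid and v.angle_deg == pytest.approx(30.0, abs=1e-6)

    def test_exact_threshold_is_invalid(self):
        """Strict inequality: exactly 15.0 degrees does not pass."""
        scene, poses = self._pair(15.0)
        v = validate_pair(*poses, *scene.cameras, reference=scene.sphere.center)
        assert not v.valid

    def test_nineteen_degrees_is_valid(self):
        """The smallest clinically accepted pair angle."""
        scene, poses = self._pair(19.0)
        v = validate_pair(*poses, *scene.cameras, reference=scene.sphere.center)
        assert v.valid and v.angle_deg == pytest.approx(19.0, abs=1e-6)


class TestSelectBestPair:
    @staticmethod
    def _images(angles_from_ap):
        """Cameras fanned at given angles from a common reference direction."""
        from fluoroplan.simulate import _make_camera, _rotate_about

        ref = np.array([5.0, -3.0, 52.0])
        w0 = np.array([0.0, 0.0, 1.0])
        axis = np.array([0.0, 1.0, 0.0])
        out = []
        for i, a in enumerate(angles_from_ap):
            w = _rotate_about(w0, axis, np.radians(a))
            cam = _make_camera(ref, w, 600.0, 1000.0, 0.4, (64, 64), 0.0)
            out.append((f"im{i}", Pose.identity(), cam))
        return ref, out

    def test_picks_largest_angle(self):
        ref, images = self._images([0.0, 10.0, 34.0])  # pairwise 10, 24, 34
        ida, idb, v = select_best_pair(images, reference=ref)
        assert {ida, idb} == {"im0", "im2"}
        assert v.angle_deg == pytest.approx(34.0, abs=1e-6)

    def test_all_narrow_raises_no_valid_pair(self):
        ref, images = self._images([0.0, 7.0, 14.0])
        with pytest.raises(NoValidPair):
            select_best_pair(images, reference=ref)

    def test_equal_angles_tie_break_by_image_id(self):
        """im2 duplicates im0: pairs (im0,im1) and (im1,im2) both span 40
        degrees; the lexicographically earlier pair wins."""
        ref, images = self._images([0.0, 40.0, 0.0])
        ida, idb, v = select_best_pair(images, reference=ref)
        assert (ida, idb) == ("im0", "im1")
        assert v.angle_deg == pytest.approx(40.0, abs=1e-6)
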