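"""Screw-length truncation, TJD arithmetic and plate-offset geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from fluoroplan import (
    Pose,
    Sphere,
    length_difference,
    offset_difference,
    plan_screws,
    plate_offset,
    pose_compose,
    tjd_abs_error,
)
from fluoroplan.errors import InvalidStatus
from fluoroplan.implant import ImplantGeometry, ScrewSpec
from fluoroplan.planning import PlateOffset, achieved_tjd


def single_screw_implant(seat, direction, lengths, label="D7"):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # plate axes perpendicular to the screw direction
    a = np.cross(d, [0.0, 1.0, 0.0])
    if np.linalg.norm(a) < 1e-6:
        a = np.cross(d, [1.0, 0.0, 0.0])
    a = a / np.linalg.norm(a)
    b = np.cross(d, a)
    return ImplantGeometry(
        screws=(ScrewSpec(label, np.asarray(seat, float), d, tuple(lengths), central=True),),
        clip_to_plate=Pose.identity(),
        plate_axes=(a, b),
    )


class TestPlanScrews:
    def test_diameter_hand_construction(self):
        """Seat 30 mm before entry of a r=25 sphere along a diameter:
        raw = 30 + 50 - 5 = 75, catalog in 2 mm steps -> 74, achieved 6."""
        imp = single_screw_implant([0, 0, 0], [0, 0, 1], range(16, 82, 2))
        sphere = Sphere([0, 0, 55.0], 25.0)
        (plan,) = plan_screws(sphere, imp, target_tjd_mm=5.0)
        assert plan.status == "ok"
        assert plan.raw_length == pytest.approx(75.0, abs=1e-9)
        assert plan.suggested_length == 74.0
        assert achieved_tjd(plan) == pytest.approx(6.0, abs=1e-9)
        assert np.allclose(plan.entry_point, [0, 0, 30.0])
        assert np.allclose(plan.exit_point, [0, 0, 80.0])

    def test_missing_sphere_is_out_of_head(self):
        imp = single_screw_implant([0, 0, 0], [0, 0, 1], range(16, 62, 2))
        (plan,) = plan_screws(Sphere([100.0, 0, 50.0], 20.0), imp)
        assert plan.status == "out_of_head"
        assert plan.suggested_length is None
        with pytest.raises(InvalidStatus):
            achieved_tjd(plan)

    def test_zero_target_continuous_puts_tip_on_sphere(self):
        imp = single_screw_implant([1.0, -2.0, 0], [0.1, 0.05, 1.0], range(16, 62, 2))
        sphere = Sphere([2.0, 0.0, 48.0], 23.0)
        (plan,) = plan_screws(sphere, imp, target_tjd_mm=0.0, continuous=True)
        tip = plan.trajectory.origin + plan.suggested_length * plan.trajectory.direction
        assert abs(np.linalg.norm(tip - sphere.center) - sphere.radius) < 1e-9

    def test_short_trajectory_no_catalog_fit(self):
        imp = single_screw_implant([0, 0, 0], [0, 0, 1], [40.0, 44.0])
        (plan,) = plan_screws(Sphere([0, 0, 20.0], 10.0), imp, target_tjd_mm=5.0)
        # raw = 30 - 5 = 25 below the shortest catalog entry (40)
        assert plan.status == "no_catalog_fit"

    def test_achieved_tjd_matches_norm_oracle(self, implant, rng):
        for _ in range(20):
            sphere = Sphere(rng.normal([5, -3, 52], 3.0), rng.uniform(20, 28))
            for plan in plan_screws(sphere, implant):
                if plan.status != "ok":
                    continue
                tip = plan.trajectory.origin + plan.suggested_length * plan.trajectory.direction
                oracle = np.linalg.norm(plan.exit_point - tip)
                assert achieved_tjd(plan) == pytest.approx(oracle, abs=1e-9)
                assert (plan.exit_point - tip) @ plan.trajectory.direction > 0  # tip short of exit

    def test_no_perforation_invariant_randomized(self, implant, rng):
        """ok screws: tip strictly inside; achieved in [target, target + increment)."""
        checked = 0
        for _ in range(112):  # ~1000 screw plans over the 9-screw fixture
            sphere = Sphere(rng.normal([5, -3, 52], 3.0), rng.uniform(20, 28))
            target = rng.uniform(0.0, 8.0)
            for plan in plan_screws(sphere, implant, target_tjd_mm=target):
                if plan.status != "ok":
                    continue
                checked += 1
                tip = plan.trajectory.origin + plan.suggested_length * plan.trajectory.direction
                assert np.linalg.norm(tip - sphere.center) < sphere.radius
                cat = np.asarray(implant.screw(plan.label).available_lengths)
                nxt = cat[cat > plan.suggested_length]
                inc = (nxt[0] - plan.suggested_length) if len(nxt) else np.inf
                assert target - 1e-9 <= plan.achieved_tjd < target + inc
        assert checked > 900

    def test_increasing_target_never_lengthens_screws(self, implant):
        sphere = Sphere([5.0, -3.0, 52.0], 24.0)
        prev = None
        for target in (0.0, 2.0, 5.0, 8.0):
            lengths = {
                p.label: p.suggested_length
                for p in plan_screws(sphere, implant, target_tjd_mm=target)
                if p.status == "ok"
            }
            if prev is not None:
                for label, ln in lengths.items():
                    assert ln <= prev[label]
            prev = lengths

    def test_frame_invariance(self, implant, rng):
        """Rigidly moving sphere and plate together changes nothing."""
        sphere = Sphere([5.0, -3.0, 52.0], 24.0)
        base_plans = plan_screws(sphere, implant)
        base_off = plate_offset(sphere, implant)
        T = Pose(Rotation.random(rng=rng).as_matrix(), rng.normal(0, 40, 3))
        moved_sphere = Sphere(T.apply(sphere.center), sphere.radius)
        moved_plans = plan_screws(moved_sphere, implant, plate_pose=T)
        moved_off = plate_offset(moved_sphere, implant, plate_pose=T)
        for a, b in zip(base_plans, moved_plans):
            assert a.status == b.status
            if a.status == "ok":
                assert a.raw_length == pytest.approx(b.raw_length, abs=1e-9)
                assert a.achieved_tjd == pytest.approx(b.achieved_tjd, abs=1e-9)
        assert base_off.dv == pytest.approx(moved_off.dv, abs=1e-9)
        assert base_off.cc == pytest.approx(moved_off.cc, abs=1e-9)

    def test_rounding_nearest_mode(self):
        imp = single_screw_implant([0, 0, 0], [0, 0, 1], range(16, 82, 2))
        sphere = Sphere([0, 0, 55.0], 25.0)  # raw 75 -> nearest of {74, 76}
        (plan,) = plan_screws(sphere, imp, rounding="nearest")
        assert plan.suggested_length in (74.0, 76.0)


class TestScalarOps:
    def test_tjd_abs_error_examples(self):
        assert tjd_abs_error(5.8, 5.0) == pytest.approx(0.8)
        assert tjd_abs_error(5.0, 5.0) == 0.0

    def test_tjd_abs_error_vectorized_matches_elementwise(self, rng):
        tjds = rng.uniform(0, 12, 48)
        out = np.array([tjd_abs_error(t, 5.0) for t in tjds])
        assert np.allclose(out, np.abs(tjds - 5.0))

    def test_length_difference_examples(self):
        assert length_difference(40.0, 48.0) == 8.0
        assert length_difference(36.0, 36.0) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(16, 80, allow_nan=False),
        st.floats(16, 80, allow_nan=False),
    )
    def test_length_difference_symmetric(self, a, b):
        assert length_difference(a, b) == length_difference(b, a) >= 0


class TestPlateOffset:
    def test_center_on_trajectory_gives_zero(self, implant):
        from fluoroplan import screw_trajectory_in_marker

        traj = screw_trajectory_in_marker(implant, "D7")
        off = plate_offset(Sphere(traj.point(30.0), 24.0), implant)
        assert off.dv == pytest.approx(0.0, abs=1e-9)
        assert off.cc == pytest.approx(0.0, abs=1e-9)

    def test_cranial_displacement_reads_plus_eight(self, implant):
        from fluoroplan import screw_trajectory_in_marker

        traj = screw_trajectory_in_marker(implant, "D7")
        cc_axis = implant.plate_to_marker().rotate(implant.plate_axes[1])
        off = plate_offset(Sphere(traj.point(30.0) + 8.0 * cc_axis, 24.0), implant)
        assert off.dv == pytest.approx(0.0, abs=1e-9)
        assert off.cc == pytest.approx(8.0, abs=1e-9)

    def test_orthogonal_decomposition_oracle(self, implant, rng):
        from fluoroplan import screw_trajectory_in_marker

        traj = screw_trajectory_in_marker(implant, "D7")
        for _ in range(20):
            sphere = Sphere(rng.normal([5, -3, 52], 5.0), 24.0)
            off = plate_offset(sphere, implant)
            u = sphere.center - traj.origin
            v = u - (u @ traj.direction) * traj.direction
            assert abs(v @ traj.direction) < 1e-9
            assert np.hypot(off.dv, off.cc) == pytest.approx(np.linalg.norm(v), abs=1e-9)

    def test_offset_difference_examples(self):
        assert offset_difference(PlateOffset(-1, 8), PlateOffset(9, 8)) == {
            "dv_diff": 10.0,
            "cc_diff": 0.0,
        }
        assert offset_difference(PlateOffset(4, 4), PlateOffset(0, 3)) == {
            "dv_diff": 4.0,
            "cc_diff": 1.0,
        }
        assert offset_difference(PlateOffset(2.5, -1.5), PlateOffset(2.5, -1.5)) == {
            "dv_diff": 0.0,
            "cc_diff": 0.0,
        }
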