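"""Capture classification: frame trichotomy, latching, exclusion rule."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from nanocapture.classify import (
    CaptureOutcome,
    ClassificationConfig,
    FrameClass,
    classify_frame,
    classify_trajectory,
)

PLANE = -0.5
MOUTH = 1.3


class TestClassifyFrame:
    def test_all_below_inside_pore(self, classification_config, geometry):
        cls, inside = classify_frame(
            [(0.1, 0, -0.6), (0.2, 0, -0.7)], classification_config, geometry
        )
        assert cls is FrameClass.BELOW_ALL
        assert inside

    def test_all_above(self, classification_config, geometry):
        cls, inside = classify_frame(
            [(0, 0, 0.2), (0, 0, 0.4)], classification_config, geometry
        )
        assert cls is FrameClass.ABOVE_ALL
        assert inside  # vacuously: nothing below the plane

    def test_straddling(self, classification_config, geometry):
        cls, _ = classify_frame(
            [(0, 0, -0.6), (0, 0, 0.1)], classification_config, geometry
        )
        assert cls is FrameClass.STRADDLING

    def test_atom_exactly_on_plane_counts_as_above(self,
                                                   classification_config,
                                                   geometry):
        cls, _ = classify_frame(
            [(0, 0, PLANE), (0, 0, PLANE - 0.2)],
            classification_config, geometry,
        )
        assert cls is FrameClass.STRADDLING

    def test_below_but_outside_mouth_not_inside(self, classification_config,
                                                geometry):
        cls, inside = classify_frame(
            [(3.0, 0, -0.6), (3.0, 0, -0.8)], classification_config, geometry
        )
        assert cls is FrameClass.BELOW_ALL
        assert not inside

    def test_empty_frame_rejected(self, classification_config, geometry):
        with pytest.raises(ValueError):
            classify_frame(np.empty((0, 3)), classification_config, geometry)

    def test_agrees_with_brute_force_loop(self, classification_config,
                                          geometry):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            coords = rng.uniform([-4, -4, -2], [4, 4, 2], size=(3, 3))
            cls, inside = classify_frame(coords, classification_config,
                                         geometry)
            below = [bool(z < PLANE) for _, _, z in coords]
            if all(below):
                expected = FrameClass.BELOW_ALL
            elif not any(below):
                expected = FrameClass.ABOVE_ALL
            else:
                expected = FrameClass.STRADDLING
            expected_inside = all(
                np.hypot(x, y) <= MOUTH
                for (x, y, z), b in zip(coords, below) if b
            )
            assert cls is expected
            assert inside == expected_inside


def path_trajectory(make_trajectory, zs, x=0.0):
    return make_trajectory([[x, 0.0, z] for z in zs])


class TestClassifyTrajectory:
    def test_monotone_descent_latches_at_first_below_frame(
        self, make_trajectory, classification_config, geometry
    ):
        zs = np.linspace(1.0, -1.5, 11)  # crosses fully below during descent
        traj = path_trajectory(make_trajectory, zs)
        out = classify_trajectory(traj, classification_config, geometry)
        assert out.label == "captured"
        first_below = next(
            i for i, z in enumerate(zs) if z + 0.25 < PLANE
        )
        assert out.latch_time == pytest.approx(traj.times[first_below])
        assert not out.translocated

    def test_below_plane_outside_mouth_is_excluded_failed(
        self, make_trajectory, classification_config, geometry
    ):
        # dips below the plane at radial 3 nm, then drifts away upward
        centre = [[3.0, 0, 0.5], [3.0, 0, -0.9], [3.0, 0, 0.3],
                  [3.0, 0, 1.0]]
        traj = make_trajectory(centre)
        out = classify_trajectory(traj, classification_config, geometry)
        assert out.label == "failed"
        assert out.excluded_outside_pore

    def test_final_frame_straddle_is_possible(self, make_trajectory,
                                              classification_config,
                                              geometry):
        traj = path_trajectory(make_trajectory, [1.0, 0.0, -0.45])
        out = classify_trajectory(traj, classification_config, geometry)
        assert out.label == "possible"
        assert out.latch_time is None

    def test_capture_is_absorbing(self, make_trajectory,
                                  classification_config, geometry):
        # descends fully below, then the path wanders back above the plane:
        # latched label must remain captured
        zs = [0.5, -0.9, -1.0, 0.5, 1.0]
        traj = path_trajectory(make_trajectory, zs)
        out = classify_trajectory(traj, classification_config, geometry)
        assert out.label == "captured"
        assert out.latch_time == pytest.approx(10.0)

    def test_final_frame_mode_differs_on_reentrant_path(
        self, make_trajectory, geometry
    ):
        zs = [0.5, -0.9, 0.5, 1.0]
        traj = path_trajectory(make_trajectory, zs)
        final_cfg = ClassificationConfig.from_geometry(
            geometry, evaluation="final_frame"
        )
        assert classify_trajectory(traj, final_cfg, geometry).label == "failed"

    def test_translocation_flag(self, make_trajectory, classification_config,
                                geometry):
        zs = np.linspace(1.0, -11.0, 25)
        traj = path_trajectory(make_trajectory, zs)
        out = classify_trajectory(traj, classification_config, geometry)
        assert out.label == "captured"
        assert out.translocated

    @settings(deadline=None, max_examples=60,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(
        steps=st.lists(st.floats(-0.8, 0.6), min_size=1, max_size=25),
        z0=st.floats(0.0, 3.0),
    )
    def test_trichotomy_and_latch_monotonicity(
        self, make_trajectory, classification_config, geometry, steps, z0
    ):
        zs = z0 - np.cumsum(np.concatenate([[0.0], steps]))
        traj = path_trajectory(make_trajectory, zs)
        out = classify_trajectory(traj, classification_config, geometry)
        assert out.label in ("captured", "possible", "failed")
        assert (out.latch_time is not None) == (out.label == "captured")
        if out.label == "captured":
            latch_idx = int(np.flatnonzero(
                traj.times == out.latch_time
            )[0])
            truncated = make_trajectory(
                [[0.0, 0.0, z] for z in zs[: latch_idx + 1]]
            )
            tout = classify_trajectory(truncated, classification_config,
                                       geometry)
            assert tout.label == "captured"
            assert tout.latch_time == out.latch_time


class TestCaptureOutcomeInvariants:
    def test_latch_time_requires_captured(self):
        with pytest.raises(ValueError):
            CaptureOutcome(label="possible", latch_time=10.0,
                           translocated=False, excluded_outside_pore=False)
        with pytest.raises(ValueError):
            CaptureOutcome(label="captured", latch_time=None,
                           translocated=False, excluded_outside_pore=False)

    def test_translocated_implies_captured(self):
        with pytest.raises(ValueError):
            CaptureOutcome(label="failed", latch_time=None,
                           translocated=True, excluded_outside_pore=False)

    def test_translocation_plane_ordering_enforced(self):
        with pytest.raises(ValueError):
            ClassificationConfig(capture_plane_z=-0.5,
                                 translocation_plane_z=-0.2)
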