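"""Synthetic generator: grid enumeration, Langevin limits, Bernoulli tier."""

import numpy as np
import pytest

from nanocapture.classify import ClassificationConfig, classify_trajectory
from nanocapture.io import ConditionSpec
from nanocapture.model import CaptureModelResults
from nanocapture.synthetic import (
    DesignGrid,
    GeneratorConfig,
    build_condition_grid,
    sample_outcomes,
    simulate_outcomes,
    simulate_trajectories,
    simulate_trajectory,
)


class TestConditionGrid:
    def test_default_design_enumerates_360_runs(self):
        assert len(build_condition_grid(DesignGrid())) == 360

    def test_minimal_design_is_one_spec(self):
        design = DesignGrid(heights=(1.0,), translations=(),
                            orientations=("up",), replicates=1)
        assert len(build_condition_grid(design)) == 1

    def test_same_master_seed_gives_identical_per_run_seeds(self):
        g1 = build_condition_grid(DesignGrid(), master_seed=42)
        g2 = build_condition_grid(DesignGrid(), master_seed=42)
        assert [s.seed for s in g1] == [s.seed for s in g2]
        g3 = build_condition_grid(DesignGrid(), master_seed=43)
        assert [s.seed for s in g1] != [s.seed for s in g3]

    def test_displacement_conditions_at_series_height(self):
        grid = build_condition_grid(DesignGrid())
        displaced = {(s.height, s.translation) for s in grid
                     if s.translation > 0}
        assert displaced == {(3.0, 0.5), (3.0, 1.0), (3.0, 1.5), (3.0, 2.0)}

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            DesignGrid(heights=()).validate()
        with pytest.raises(ValueError):
            DesignGrid(heights=(2.0, 1.0)).validate()
        with pytest.raises(ValueError):
            DesignGrid(replicates=0).validate()


class TestLangevinTier:
    def test_pure_drift_descends_monotonically_and_captures(self, geometry):
        spec = ConditionSpec(height=1.0, translation=0.0, orientation="down",
                             replicate=1, duration=5000.0, seed=1)
        config = GeneratorConfig(diffusion_coefficient=0.0,
                                 sticky_site_affinity=0.0)
        traj = simulate_trajectory(spec, geometry, config)
        z = traj.coordinates[:, traj.topology.solute_indices[0], 2]
        assert np.all(np.diff(z) <= 1e-12)
        outcome = classify_trajectory(
            traj, ClassificationConfig.from_geometry(geometry), geometry
        )
        assert outcome.label == "captured"

    def test_no_drift_no_diffusion_is_a_fixed_point(self, geometry):
        spec = ConditionSpec(height=2.0, translation=0.0, orientation="up",
                             replicate=1, duration=1000.0, seed=1)
        config = GeneratorConfig(diffusion_coefficient=0.0, drift_speed=0.0,
                                 orientation_drift_bonus=0.0,
                                 sticky_site_affinity=0.0)
        traj = simulate_trajectory(spec, geometry, config)
        assert np.allclose(traj.coordinates[0], traj.coordinates[-1])
        outcome = classify_trajectory(
            traj, ClassificationConfig.from_geometry(geometry), geometry
        )
        assert outcome.label == "failed"

    def test_same_seed_bit_identical(self, geometry):
        spec = ConditionSpec(height=2.0, translation=0.5, orientation="down",
                             replicate=1, duration=500.0, seed=77)
        t1 = simulate_trajectory(spec, geometry)
        t2 = simulate_trajectory(spec, geometry)
        assert np.array_equal(t1.coordinates, t2.coordinates)

    def test_batched_equals_single_run(self, geometry):
        specs = [
            ConditionSpec(height=2.0, translation=0.0, orientation="down",
                          replicate=r, duration=500.0, seed=100 + r)
            for r in (1, 2, 3)
        ]
        batched = simulate_trajectories(specs, geometry)
        for spec, btraj in zip(specs, batched):
            alone = simulate_trajectory(spec, geometry)
            assert np.array_equal(alone.coordinates, btraj.coordinates)

    def test_frameless_outcomes_agree_with_classifier(self, geometry):
        specs = [
            ConditionSpec(height=h, translation=t, orientation=o,
                          replicate=r, duration=2000.0, seed=31 * r + int(10 * h))
            for (h, t) in ((1.0, 0.0), (3.0, 1.0))
            for o in ("up", "down")
            for r in (1, 2, 3)
        ]
        frameless = simulate_outcomes(specs, geometry)
        cfg = ClassificationConfig.from_geometry(geometry)
        for i, traj in enumerate(simulate_trajectories(specs, geometry)):
            assert classify_trajectory(traj, cfg, geometry).label == \
                frameless["label"].iloc[i]

    def test_timestep_exceeding_frame_interval_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(timestep=20.0, frame_interval=10.0).validate()

    def test_capture_probability_declines_with_height(self, geometry):
        # 200 replicates per height: monotone within binomial sampling error
        design = DesignGrid(heights=(1.0, 2.0, 3.0, 4.0), translations=(),
                            orientations=("down",), replicates=200)
        out = simulate_outcomes(build_condition_grid(design, master_seed=2),
                                geometry)
        p = out.groupby("height")["label"].apply(
            lambda s: s.isin(["captured", "possible"]).mean()
        )
        n = 200
        for lo, hi in zip(p.index[:-1], p.index[1:]):
            se = np.sqrt(p[lo] * (1 - p[lo]) / n + p[hi] * (1 - p[hi]) / n)
            assert p[hi] <= p[lo] + 3 * max(se, 0.01)


class TestBernoulliTier:
    def test_certain_truth_gives_all_positive(self):
        grid = build_condition_grid(DesignGrid(replicates=5))
        truth = CaptureModelResults.from_coefficients(100.0, 0.0)
        out = sample_outcomes(truth, grid, seed=0)
        assert out["possible_capture"].all()

    def test_impossible_truth_gives_all_negative(self):
        grid = build_condition_grid(DesignGrid(replicates=5))
        truth = CaptureModelResults.from_coefficients(0.0, 0.0)
        out = sample_outcomes(truth, grid, seed=0)
        assert not out["possible_capture"].any()

    def test_proportions_converge_to_linear_truth(self):
        # Monte-Carlo oracle: at 10^4 reps/height the empirical proportion
        # lies within 3 binomial SEs of the generating line
        truth = CaptureModelResults.from_coefficients(93.0, 20.5)
        n = 10_000
        grid = [
            ConditionSpec(height=h, translation=0.0, orientation="down",
                          replicate=r)
            for h in (1.0, 1.5, 2.0, 3.0, 4.0)
            for r in range(1, n + 1)
        ]
        out = sample_outcomes(truth, grid, seed=0)
        for h, grp in out.groupby("height"):
            p_true = (93.0 - 20.5 * h) / 100.0
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(grp["possible_capture"].mean() - p_true) < 3 * se

    def test_orientation_specific_truths(self):
        grid = build_condition_grid(DesignGrid(replicates=3))
        truth = {
            "up": CaptureModelResults.from_coefficients(0.0, 0.0),
            "down": CaptureModelResults.from_coefficients(100.0, 0.0),
        }
        out = sample_outcomes(truth, grid, seed=1)
        assert not out.loc[out.orientation == "up", "possible_capture"].any()
        assert out.loc[out.orientation == "down", "possible_capture"].all()

    def test_reproducible_for_fixed_seed(self):
        grid = build_condition_grid(DesignGrid(replicates=4))
        truth = CaptureModelResults.from_coefficients(50.0, 0.0)
        a = sample_outcomes(truth, grid, seed=9)
        b = sample_outcomes(truth, grid, seed=9)
        assert a.equals(b)


def test_down_orientation_captures_at_least_as_often_as_up(geometry):
    # orientation drift bonus: phosphate-down leads at every condition,
    # within sampling error at 200 replicates
    design = DesignGrid(heights=(1.0, 3.0), translations=(1.0,),
                        replicates=200)
    out = simulate_outcomes(build_condition_grid(design, master_seed=4),
                            geometry)
    p = out.groupby(["height", "translation", "orientation"])["label"].apply(
        lambda s: s.isin(["captured", "possible"]).mean()
    ).unstack()
    n = 200
    for _, row in p.iterrows():
        se_diff = np.sqrt(
            row["down"] * (1 - row["down"]) / n
            + row["up"] * (1 - row["up"]) / n
        )
        assert row["down"] >= row["up"] - 3 * max(se_diff, 0.01)
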