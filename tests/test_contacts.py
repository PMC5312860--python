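"""Contact analysis: cutoffs, residence events, summaries, zone structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanocapture.contacts import (
    ContactConfig,
    build_contact_profile,
    detect_contacts,
    residence_events,
    summarize_contacts,
    zone_rollup,
)


class TestDetectContacts:
    def test_single_residue_within_cutoff(self, topology):
        coords = topology.reference_positions.copy()
        # place the solute 0.35 nm above one D45 pseudo-atom
        d45 = topology.select(residue_number=45)[0]
        sol = topology.solute_indices
        coords[sol] = coords[d45] + [0.0, 0.0, 0.35]
        hits = detect_contacts(coords, topology, ContactConfig(cutoff=0.4))
        assert ("ASP", 45) in hits

    def test_far_solute_has_no_contacts(self, topology):
        coords = topology.reference_positions.copy()
        coords[topology.solute_indices] = [0.0, 0.0, 10.0]
        assert detect_contacts(coords, topology, ContactConfig()) == set()

    def test_agrees_with_brute_force_all_pairs(self, topology):
        rng = np.random.default_rng(23)
        cfg = ContactConfig(cutoff=0.6)
        for _ in range(25):
            coords = topology.reference_positions.copy()
            coords[topology.solute_indices] = rng.uniform(
                [-3, -3, -2], [3, 3, 1], size=(3, 3)
            )
            hits = detect_contacts(coords, topology, cfg)
            brute = set()
            for i in topology.solute_indices:
                for j in topology.protein_indices:
                    if np.linalg.norm(coords[i] - coords[j]) <= cfg.cutoff:
                        brute.add(
                            (topology.residue_names[j],
                             int(topology.residue_numbers[j]))
                        )
            assert hits == brute


class TestResidenceEvents:
    def test_runs_become_events(self):
        events = residence_events([True, True, True, False, True], 10.0)
        assert [(e.start, e.duration) for e in events] == [(0.0, 30.0),
                                                           (40.0, 10.0)]

    def test_all_false_is_empty(self):
        assert residence_events([False] * 5, 10.0) == []

    def test_exactly_100ps_run_is_not_transient(self):
        cfg = ContactConfig()
        (event,) = residence_events([True] * 10, 10.0)
        assert event.duration == pytest.approx(100.0)
        assert not event.duration < cfg.transient_max_duration  # strict <

    def test_exactly_1ns_is_not_stable(self):
        cfg = ContactConfig()
        (event,) = residence_events([True] * 100, 10.0)
        assert event.duration == pytest.approx(1000.0)
        assert not event.duration > cfg.stable_min_duration  # strict >

    @settings(deadline=None, max_examples=100)
    @given(series=st.lists(st.booleans(), min_size=1, max_size=200),
           interval=st.sampled_from([1.0, 5.0, 10.0]))
    def test_duration_conservation(self, series, interval):
        events = residence_events(series, interval)
        total = sum(e.duration for e in events)
        assert total == pytest.approx(interval * sum(series))
        # events ordered, non-overlapping
        for a, b in zip(events, events[1:]):
            assert a.end < b.start + 1e-12 and a.end <= b.start


class TestSummaries:
    @pytest.fixture
    def profiles(self, make_trajectory):
        cfg = ContactConfig()
        paths = {
            # parked on a cap residue (D45 ring at r≈2.4) the whole run
            "run0": [[2.4, 0.0, 0.35]] * 50,
            # descends into the vestibule and dwells there
            "run1": [[0.4, 0.0, 1.5 - 0.12 * i] for i in range(50)],
        }
        return {
            rid: build_contact_profile(make_trajectory(path), cfg)
            for rid, path in paths.items()
        }

    def test_extended_flag_threshold(self, profiles, geometry):
        cfg = ContactConfig()
        summary = summarize_contacts(
            {"run0": profiles["run0"]}, {"run0": "failed"}, cfg, geometry
        )
        d45 = summary[(summary.residue_number == 45)
                      & (summary.label == "failed")]
        assert d45["extended"].iloc[0]

    def test_rare_contact_not_extended(self, make_trajectory, geometry):
        cfg = ContactConfig()
        # one contact frame out of 500 → fraction far below 5%
        path = [[0.0, 0.0, 5.0]] * 499 + [[2.4, 0.0, 0.35]]
        prof = build_contact_profile(make_trajectory(path), cfg)
        summary = summarize_contacts({"r": prof}, {"r": "failed"}, cfg,
                                     geometry)
        assert not summary[summary.residue_number == 45]["extended"].iloc[0]

    def test_permutation_invariance(self, profiles, geometry):
        cfg = ContactConfig()
        outcomes = {"run0": "failed", "run1": "captured"}
        s1 = summarize_contacts(profiles, outcomes, cfg, geometry)
        rev = dict(reversed(list(profiles.items())))
        s2 = summarize_contacts(rev, outcomes, cfg, geometry)
        assert s1.equals(s2)

    def test_key_mismatch_raises(self, profiles, geometry):
        with pytest.raises(KeyError, match="run1"):
            summarize_contacts(profiles, {"run0": "failed"}, ContactConfig(),
                               geometry)

    def test_mean_fraction_is_per_run_average(self, make_trajectory,
                                              geometry):
        cfg = ContactConfig()
        near = [[2.4, 0.0, 0.35]] * 10          # 100% contact with D45
        far = [[0.0, 0.0, 5.0]] * 10            # 0% contact
        profs = {
            "a": build_contact_profile(make_trajectory(near), cfg),
            "b": build_contact_profile(make_trajectory(far), cfg),
        }
        summary = summarize_contacts(profs, {"a": "failed", "b": "failed"},
                                     cfg, geometry)
        d45 = summary[summary.residue_number == 45]
        assert d45["mean_fraction"].iloc[0] == pytest.approx(0.5)


def test_captured_contacts_in_vestibule_failed_on_cap(geometry):
    """Zone-majority structure of the Langevin tier at 200 runs.

    Captured runs' extended contacts concentrate in vestibule zones;
    failed runs' contacts concentrate on the cap surface / rim, mirroring
    how D45/K46/N47 trap nucleotides outside the vestibule.
    """
    from nanocapture.classify import ClassificationConfig, classify_trajectory
    from nanocapture.synthetic import (DesignGrid, build_condition_grid,
                                       simulate_trajectories)

    design = DesignGrid(heights=(1.0, 3.0), translations=(2.0,),
                        orientations=("down",), replicates=34)
    specs = build_condition_grid(design, master_seed=6)
    assert len(specs) >= 100
    trajs = simulate_trajectories(specs, geometry)
    cfg = ContactConfig()
    cls_cfg = ClassificationConfig.from_geometry(geometry)
    profiles, labels = {}, {}
    for i, traj in enumerate(trajs):
        rid = f"run{i:03d}"
        profiles[rid] = build_contact_profile(traj, cfg)
        labels[rid] = classify_trajectory(traj, cls_cfg, geometry).label
    assert {"captured", "failed"} <= set(labels.values())

    summary = summarize_contacts(profiles, labels, cfg, geometry)

    # captured runs dwell inside: their *extended* residues sit in the
    # vestibule zones
    zones = zone_rollup(summary)
    cap_ext = zones[zones.label == "captured"]
    assert cap_ext[
        cap_ext.zone.isin(["vestibule_interior", "vestibule_rim"])
    ]["fraction"].sum() > 0.5

    # failed runs mostly never touch the protein, so none of their contacts
    # reach the extended threshold; what contact mass they do have sits on
    # the cap surface and entrance rim, not in the vestibule interior
    def zone_mass(label, zone_names):
        sel = summary[summary.label == label]
        total = sel["mean_fraction"].sum()
        return sel[sel.zone.isin(zone_names)]["mean_fraction"].sum() / total

    assert zone_mass("failed", ["cap_surface", "vestibule_rim"]) > 0.5
    assert zone_mass("captured", ["vestibule_interior", "vestibule_rim"]) > 0.5
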