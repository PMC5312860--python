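"""Synthetic stand-ins for the capture-region simulation campaign.

The study design this module emulates releases a mononucleotide (CMP) above
the vestibule mouth of alpha-hemolysin — at 10, 15, 20, 30 and 40 Å above
the K8 ring on axis, and at 5, 10, 15 and 20 Å lateral offsets at 30 Å
height — in phosphate-up and phosphate-down orientations, 20 replicates of
5 ns per condition: 360 runs in total.

Two tiers are provided:

* **Langevin tier** — full surrogate trajectories.  The solute is a rigid
  three-pseudo-atom cluster (phosphate / sugar / base) undergoing overdamped
  Langevin motion with a constant downward drift standing in for the applied
  electric field, reflecting boundaries at the cap surface, sticky pauses at
  the cap-surface binding sites (the D45/K46/N47 surrogate) and absorbing
  confinement below the capture plane once fully inside the pore mouth.
  This tier exercises the whole pipeline: trajectories → classification →
  contacts → statistics → model fit.
* **Bernoulli tier** — per-run binary possible-capture outcomes drawn
  directly from a known linear truth model.  This tier gives exact
  statistical control for parameter-recovery tests.

All randomness is reproducible: per-run seeds are derived from a master
seed via ``numpy.random.SeedSequence``, and a replicate simulated alone is
bit-identical to the same replicate inside a vectorised batch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import PoreGeometry, ZoneLabel, build_default_pore
from .io import ConditionSpec, Topology, Trajectory

__all__ = [
    "GeneratorConfig",
    "DesignGrid",
    "build_condition_grid",
    "build_synthetic_topology",
    "simulate_trajectory",
    "simulate_trajectories",
    "simulate_outcomes",
    "sample_outcomes",
    "SOLUTE_RESNAME",
]

SOLUTE_RESNAME = "CMP"

#: z offsets (nm) of the solute pseudo-atoms relative to the cluster centre,
#: by phosphate orientation.  "down" puts the phosphate closest to the
#: vestibule entrance (lowest z).
_SOLUTE_OFFSETS = {
    "down": {"P": -0.25, "C1'": 0.0, "N1": +0.25},
    "up": {"P": +0.25, "C1'": 0.0, "N1": -0.25},
}
_SOLUTE_HALF_HEIGHT = 0.25

_RESIDUE_NAMES = {
    1: "ALA", 2: "ASP", 3: "SER", 6: "ASN", 8: "LYS", 9: "THR", 10: "GLY",
    11: "THR", 13: "ASP", 15: "GLY", 16: "SER", 17: "ASN", 18: "THR",
    19: "THR", 20: "VAL", 45: "ASP", 46: "LYS", 47: "ASN", 293: "ASN",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the Langevin surrogate.

    diffusion_coefficient : nm²/ns
        Isotropic translational diffusion of the solute cluster.
    drift_speed : nm/ns
        Constant downward drift along the pore axis; plays the role of the
        applied transmembrane field.
    orientation_drift_bonus : nm/ns
        Extra drift for the phosphate-down orientation (the charged moiety
        leads), producing the higher capture rate seen for "down" releases.
    timestep, frame_interval, duration : ps
        Integration step, trajectory output interval and run length.
    sticky_site_affinity : in [0, 1]
        Per-step probability of pausing while in contact with the
        cap-surface binding region, emulating trapping by D45/K46/N47.
    """

    diffusion_coefficient: float = 0.4
    drift_speed: float = 0.3
    orientation_drift_bonus: float = 0.1
    timestep: float = 1.0
    frame_interval: float = 10.0
    duration: float = 5000.0
    sticky_site_affinity: float = 0.2
    sticky_zone_height: float = 0.12  # nm above the cap surface

    def validate(self) -> None:
        for name in ("diffusion_coefficient", "drift_speed",
                     "orientation_drift_bonus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.timestep > self.frame_interval:
            raise ValueError("timestep must not exceed frame_interval")
        ratio = self.frame_interval / self.timestep
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("timestep must divide frame_interval")
        if not 0.0 <= self.sticky_site_affinity <= 1.0:
            raise ValueError("sticky_site_affinity must lie in [0, 1]")

    def drift_for(self, orientation: str) -> float:
        bonus = self.orientation_drift_bonus if orientation == "down" else 0.0
        return self.drift_speed + bonus


@dataclass(frozen=True)
class DesignGrid:
    """The replication design: on-axis heights, lateral offsets, orientations."""

    heights: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0, 4.0)
    translations: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    displacement_height: float = 3.0
    orientations: tuple[str, ...] = ("up", "down")
    replicates: int = 20

    def validate(self) -> None:
        if not self.heights:
            raise ValueError("heights must be non-empty")
        for seq, name in ((self.heights, "heights"),
                          (self.translations, "translations")):
            if any(v <= 0 for v in seq):
                raise ValueError(f"{name} must be positive")
            if list(seq) != sorted(set(seq)):
                raise ValueError(f"{name} must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def conditions(self) -> list[tuple[float, float]]:
        """(height, translation) pairs: height series then displacement series."""
        conds = [(h, 0.0) for h in self.heights]
        conds += [(self.displacement_height, t) for t in self.translations]
        return conds


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """n reproducible per-run seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array(
        [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]
    )


def build_condition_grid(design: DesignGrid | None = None,
                         master_seed: int = 0,
                         duration: float = 5000.0) -> list[ConditionSpec]:
    """Enumerate the replication grid as ConditionSpecs, with derived seeds.

    Ordering is deterministic: orientation-major, then condition (height
    series before displacement series), then replicate.  The default design
    yields (5 heights + 4 translations) × 2 orientations × 20 replicates
    = 360 specs.
    """
    design = design or DesignGrid()
    design.validate()
    conds = design.conditions()
    n = len(conds) * len(design.orientations) * design.replicates
    seeds = derive_seeds(master_seed, n)
    specs = []
    i = 0
    for orientation in design.orientations:
        for height, translation in conds:
            for rep in range(1, design.replicates + 1):
                specs.append(
                    ConditionSpec(
                        height=height, translation=translation,
                        orientation=orientation, replicate=rep,
                        duration=duration, seed=int(seeds[i]),
                    )
                )
                i += 1
    return specs


# ---------------------------------------------------------------------------
# Surrogate topology
# ---------------------------------------------------------------------------

def build_synthetic_topology(geometry: PoreGeometry | None = None) -> Topology:
    """One Cα pseudo-atom per protomer copy of each zoned residue, plus CMP.

    Residues are laid out with heptameric symmetry: interior residues line
    the vestibule below the mouth, rim residues sit at the entrance edge and
    the cap-surface triplet (D45/K46/N47) sits on the cap top at increasing
    radius.  The solute is three pseudo-atoms (P, C1', N1) of residue CMP.
    """
    geometry = geometry or build_default_pore()
    n = geometry.k8_ring.member_count
    chains = [chr(ord("A") + (k % 26)) for k in range(n)]

    ids, names, elements, resnames, resnums, chain_ids, solute = (
        [], [], [], [], [], [], []
    )
    positions = []

    def add_ring(resnum: int, resname: str, ring_positions: np.ndarray) -> None:
        for k in range(ring_positions.shape[0]):
            ids.append(len(ids) + 1)
            names.append("CA")
            elements.append("C")
            resnames.append(resname)
            resnums.append(resnum)
            chain_ids.append(chains[k % n])
            solute.append(False)
            positions.append(ring_positions[k])

    add_ring(8, geometry.k8_ring.residue_name, geometry.k8_ring.positions)
    add_ring(17, geometry.n17_ring.residue_name, geometry.n17_ring.positions)

    def ring_at(radius: float, z: float, phase: float) -> np.ndarray:
        angles = 2.0 * np.pi * (np.arange(n) + phase) / n
        return np.column_stack(
            [radius * np.cos(angles), radius * np.sin(angles), np.full(n, z)]
        )

    interior = sorted(
        r for r, zl in geometry.zone_map.items()
        if zl is ZoneLabel.VESTIBULE_INTERIOR
    )
    rim = sorted(
        r for r, zl in geometry.zone_map.items()
        if zl is ZoneLabel.VESTIBULE_RIM and r not in (8, 17)
    )
    cap = sorted(
        r for r, zl in geometry.zone_map.items()
        if zl is ZoneLabel.CAP_SURFACE
    )
    for j, resnum in enumerate(interior):
        z = -0.8 - 1.2 * j / max(len(interior) - 1, 1)
        add_ring(resnum, _RESIDUE_NAMES.get(resnum, "GLY"),
                 ring_at(0.9, z, 0.5 * j))
    for j, resnum in enumerate(rim):
        z = 0.05 - 0.45 * j / max(len(rim) - 1, 1)
        add_ring(resnum, _RESIDUE_NAMES.get(resnum, "GLY"),
                 ring_at(geometry.pore_mouth_radius + 0.1, z, 0.3 * j))
    for j, resnum in enumerate(cap):
        radius = geometry.funnel_entry_radius + 0.2 + 0.3 * j
        add_ring(resnum, _RESIDUE_NAMES.get(resnum, "GLY"),
                 ring_at(radius, 0.15, 0.25 * j))

    for atom_name, element in (("P", "P"), ("C1'", "C"), ("N1", "N")):
        ids.append(len(ids) + 1)
        names.append(atom_name)
        elements.append(element)
        resnames.append(SOLUTE_RESNAME)
        resnums.append(500)
        chain_ids.append("X")
        solute.append(True)
        positions.append(np.zeros(3))

    top = Topology(
        atom_ids=np.array(ids), atom_names=names, elements=elements,
        residue_names=resnames, residue_numbers=np.array(resnums),
        chain_ids=chain_ids, solute_flag=np.array(solute),
    )
    top.reference_positions = np.asarray(positions, dtype=float)  # type: ignore[attr-defined]
    return top


def solute_offsets(orientation: str) -> np.ndarray:
    """(3, 3) pseudo-atom offsets (nm) from the cluster centre, P/C1'/N1 order."""
    off = _SOLUTE_OFFSETS[orientation]
    return np.array([[0.0, 0.0, off["P"]],
                     [0.0, 0.0, off["C1'"]],
                     [0.0, 0.0, off["N1"]]])


# ---------------------------------------------------------------------------
# Langevin stepping
# ---------------------------------------------------------------------------

def _step_centres(
    centres: np.ndarray,
    captured: np.ndarray,
    noise: np.ndarray,
    pause_u: np.ndarray,
    drift_step: float,
    sigma: float,
    geometry: PoreGeometry,
    config: GeneratorConfig,
) -> None:
    """Advance one timestep in place, for all replicates of one condition.

    Pre-capture: reflecting cap surface outside the funnel entry, radial
    reflection against the funnel wall (entry radius at the surface,
    narrowing to the mouth radius at the capture plane) while in the neck.
    Post-capture: confinement below the capture plane and inside the mouth
    radius (absorbing capture — no exits, by construction).
    """
    half = _SOLUTE_HALF_HEIGHT
    plane = geometry.capture_plane_z
    mouth = geometry.pore_mouth_radius
    entry = geometry.funnel_entry_radius

    disp = sigma * noise
    disp[:, 2] -= drift_step

    # sticky pauses at the cap-surface binding region
    r = np.hypot(centres[:, 0], centres[:, 1])
    z_low = centres[:, 2] - half
    sticky = (
        ~captured
        & (r > entry)
        & (r <= geometry.cap_outer_radius)
        & (z_low < config.sticky_zone_height)
        & (pause_u < config.sticky_site_affinity)
    )
    disp[sticky] = 0.0

    new = centres + disp
    r_new = np.hypot(new[:, 0], new[:, 1])

    # reflecting cap surface: lowest atom cannot cross z=0 outside the funnel
    free = ~captured
    hit_cap = free & (new[:, 2] - half < 0.0) & (r_new > entry)
    new[hit_cap, 2] = 2.0 * half - new[hit_cap, 2]

    # inside the funnel neck: stay within the funnel wall at this depth
    in_neck = free & ~hit_cap & (new[:, 2] - half < 0.0)
    wall = np.asarray(geometry.funnel_radius_at(new[:, 2]))
    _reflect_radially(new, r_new, in_neck & (r_new > wall), wall)

    # capture: all atoms below the plane, inside the mouth — latch
    r_new = np.hypot(new[:, 0], new[:, 1])
    newly = free & (new[:, 2] + half < plane) & (r_new <= mouth)
    captured |= newly

    # confinement below the plane once captured
    conf = captured
    over = conf & (new[:, 2] + half > plane)
    new[over, 2] = 2.0 * (plane - half) - new[over, 2]
    _reflect_radially(new, r_new, conf & (r_new > mouth), mouth)

    centres[:] = new


def _reflect_radially(points: np.ndarray, r: np.ndarray,
                      mask: np.ndarray, radius) -> None:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    r_sel = r[idx]
    rad = radius[idx] if np.ndim(radius) else np.full(idx.size, radius)
    r_target = np.clip(2.0 * rad - r_sel, 0.05, rad)
    scale = r_target / r_sel
    points[idx, 0] *= scale
    points[idx, 1] *= scale


def _presampled_noise(seed: int, n_steps: int) -> tuple[np.ndarray, np.ndarray]:
    # fixed draw order (all normals, then all uniforms) so single-run and
    # batched simulation consume identical streams
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_steps, 3)), rng.random(n_steps)


def _run_condition_batch(
    specs: list[ConditionSpec],
    geometry: PoreGeometry,
    config: GeneratorConfig,
    record_frames: bool,
) -> dict:
    """Simulate all replicates of one (height, translation, orientation)."""
    n_reps = len(specs)
    first = specs[0]
    n_steps = int(round(first.duration / config.timestep))
    dt_ns = config.timestep / 1000.0
    sigma = math.sqrt(2.0 * config.diffusion_coefficient * dt_ns)
    drift_step = config.drift_for(first.orientation) * dt_ns
    record_every = int(round(config.frame_interval / config.timestep))

    centres = np.tile(
        np.array([first.translation, 0.0, first.height]), (n_reps, 1)
    )
    captured = np.zeros(n_reps, dtype=bool)
    latch_step = np.full(n_reps, -1, dtype=int)
    translocated = np.zeros(n_reps, dtype=bool)

    normals = np.empty((n_reps, n_steps, 3))
    pauses = np.empty((n_reps, n_steps))
    for i, spec in enumerate(specs):
        normals[i], pauses[i] = _presampled_noise(spec.seed, n_steps)

    frames = [centres.copy()] if record_frames else None
    half = _SOLUTE_HALF_HEIGHT
    for t in range(n_steps):
        was = captured.copy()
        _step_centres(centres, captured, normals[:, t, :], pauses[:, t],
                      drift_step, sigma, geometry, config)
        latch_step[(~was) & captured] = t + 1
        translocated |= captured & (
            centres[:, 2] + half < geometry.barrel_exit_z
        )
        if record_frames and (t + 1) % record_every == 0:
            frames.append(centres.copy())

    z_low = centres[:, 2] - half
    z_high = centres[:, 2] + half
    plane = geometry.capture_plane_z
    labels = np.where(
        captured, "captured",
        np.where((z_low < plane) & (z_high >= plane), "possible", "failed"),
    )
    return {
        "labels": labels,
        "latch_time_ps": np.where(
            latch_step >= 0, latch_step * config.timestep, np.nan
        ),
        "translocated": translocated,
        "frames": None if frames is None else np.stack(frames),
    }


def simulate_trajectory(
    condition: ConditionSpec,
    geometry: PoreGeometry | None = None,
    config: GeneratorConfig | None = None,
    topology: Topology | None = None,
) -> Trajectory:
    """One full surrogate trajectory, reproducible from the condition seed.

    The returned trajectory contains the static protein pseudo-atoms plus
    the moving solute cluster, written at ``config.frame_interval``.
    """
    geometry = geometry or build_default_pore()
    config = config or GeneratorConfig()
    config.validate()
    topology = topology or build_synthetic_topology(geometry)

    out = _run_condition_batch([condition], geometry, config, record_frames=True)
    centres = out["frames"][:, 0, :]            # (n_frames, 3)
    n_frames = centres.shape[0]
    times = np.arange(n_frames) * config.frame_interval

    coords = np.broadcast_to(
        topology.reference_positions, (n_frames, topology.n_atoms, 3)
    ).copy()
    offsets = solute_offsets(condition.orientation)
    sol = topology.solute_indices
    coords[:, sol, :] = centres[:, None, :] + offsets[None, :, :]
    return Trajectory(
        topology=topology, times=times, coordinates=coords,
        frame_interval=config.frame_interval,
    )


def simulate_trajectories(
    specs: list[ConditionSpec],
    geometry: PoreGeometry | None = None,
    config: GeneratorConfig | None = None,
    topology: Topology | None = None,
    max_batch: int = 256,
) -> list[Trajectory]:
    """Full trajectories for many conditions, batched per condition.

    Bit-identical to calling :func:`simulate_trajectory` per spec (same
    per-replicate noise streams), but replicates sharing a condition are
    stepped together.  Returns trajectories in input order.
    """
    geometry = geometry or build_default_pore()
    config = config or GeneratorConfig()
    config.validate()
    topology = topology or build_synthetic_topology(geometry)

    out: list[Trajectory | None] = [None] * len(specs)
    groups: dict[tuple, list[int]] = {}
    for i, s in enumerate(specs):
        groups.setdefault(
            (s.height, s.translation, s.orientation, s.duration), []
        ).append(i)
    for indices in groups.values():
        for start in range(0, len(indices), max_batch):
            chunk = indices[start:start + max_batch]
            batch = _run_condition_batch(
                [specs[i] for i in chunk], geometry, config,
                record_frames=True,
            )
            frames = batch["frames"]                  # (n_frames, n_reps, 3)
            n_frames = frames.shape[0]
            times = np.arange(n_frames) * config.frame_interval
            sol = topology.solute_indices
            for j, i in enumerate(chunk):
                coords = np.broadcast_to(
                    topology.reference_positions,
                    (n_frames, topology.n_atoms, 3),
                ).copy()
                offsets = solute_offsets(specs[i].orientation)
                coords[:, sol, :] = (
                    frames[:, j, :][:, None, :] + offsets[None, :, :]
                )
                out[i] = Trajectory(
                    topology=topology, times=times, coordinates=coords,
                    frame_interval=config.frame_interval,
                )
    return out


def simulate_outcomes(
    specs: list[ConditionSpec],
    geometry: PoreGeometry | None = None,
    config: GeneratorConfig | None = None,
    max_batch: int = 256,
) -> pd.DataFrame:
    """Langevin-tier outcomes for a list of conditions, without storing frames.

    Replicates sharing a condition are stepped together (vectorised); the
    per-replicate noise streams are identical to ``simulate_trajectory``'s,
    so labels agree with classifying the recorded trajectories (capture is
    absorbing), with latch times resolved at step rather than frame
    granularity.
    """
    geometry = geometry or build_default_pore()
    config = config or GeneratorConfig()
    config.validate()

    rows: list[dict | None] = [None] * len(specs)
    groups: dict[tuple, list[int]] = {}
    for i, s in enumerate(specs):
        groups.setdefault(
            (s.height, s.translation, s.orientation, s.duration), []
        ).append(i)
    for key, indices in groups.items():
        for start in range(0, len(indices), max_batch):
            chunk = indices[start:start + max_batch]
            out = _run_condition_batch(
                [specs[i] for i in chunk], geometry, config, record_frames=False
            )
            for j, i in enumerate(chunk):
                s = specs[i]
                rows[i] = {
                    "height": s.height, "translation": s.translation,
                    "orientation": s.orientation, "replicate": s.replicate,
                    "seed": s.seed, "label": out["labels"][j],
                    "latch_time_ps": out["latch_time_ps"][j],
                    "translocated": bool(out["translocated"][j]),
                }
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bernoulli tier
# ---------------------------------------------------------------------------

def sample_outcomes(truth_model, grid: list[ConditionSpec],
                    seed: int = 0) -> pd.DataFrame:
    """Draw binary possible-capture outcomes from a linear truth model.

    ``truth_model`` is a fitted/constructed capture model (anything with a
    ``predict(height, translation)`` returning percent), or a mapping
    orientation → model.  Each run's outcome is Bernoulli with probability
    ``clamp(p/100, 0, 1)``.
    """
    rng = np.random.default_rng(seed)
    draws = rng.random(len(grid))
    p_cache: dict[tuple, float] = {}
    p_true = np.empty(len(grid))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, spec in enumerate(grid):
            key = (spec.height, spec.translation, spec.orientation)
            if key not in p_cache:
                model = (
                    truth_model[spec.orientation]
                    if isinstance(truth_model, dict) else truth_model
                )
                p = float(model.predict(spec.height, spec.translation))
                p_cache[key] = min(max(p / 100.0, 0.0), 1.0)
            p_true[i] = p_cache[key]
    return pd.DataFrame(
        {
            "height": [s.height for s in grid],
            "translation": [s.translation for s in grid],
            "orientation": [s.orientation for s in grid],
            "replicate": [s.replicate for s in grid],
            "p_true": p_true,
            "possible_capture": draws < p_true,
        }
    )
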