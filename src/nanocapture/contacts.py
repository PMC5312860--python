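"""Per-residue contact frequency and residence-duration analysis.

A residue is "in contact" with the nucleotide in a frame when the minimum
heavy-atom pair distance falls at or below the contact cutoff (default
0.4 nm, a standard molecular-dynamics van der Waals contact convention; the
threshold is configurable).  From the per-frame contact series this module
derives:

* per-residue contact fractions (fraction of frames in contact),
* residence events (maximal runs of consecutive in-contact frames, duration
  = run length × frame interval, no gap bridging),
* the field's duration classes — *transient* events last strictly less than
  100 ps, *stable* interactions persist strictly longer than 1 ns — and the
  *extended* flag for residues whose mean contact fraction across runs
  exceeds 5%,
* zone roll-ups (which pore zones the extended residues of each outcome
  group sit in).

A separate, tighter cutoff (default 0.35 nm donor–acceptor heavy-atom
distance, no angle criterion) stands in for hydrogen-bond detection and is
reported alongside the van der Waals contacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .geometry import PoreGeometry
from .io import Trajectory

__all__ = [
    "ContactConfig",
    "ResidenceEvent",
    "ContactProfile",
    "detect_contacts",
    "contact_series",
    "residence_events",
    "build_contact_profile",
    "summarize_contacts",
    "zone_rollup",
]

ResidueKey = tuple[str, int]


@dataclass(frozen=True)
class ContactConfig:
    cutoff: float = 0.4                     # nm, VdW contact threshold
    extended_fraction_threshold: float = 0.05
    transient_max_duration: float = 100.0   # ps, strict <
    stable_min_duration: float = 1000.0     # ps, strict >
    hbond_cutoff: float = 0.35              # nm, H-bond surrogate
    averaging: str = "per_run"              # "per_run" | "pooled"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.extended_fraction_threshold < 1:
            raise ValueError("extended_fraction_threshold must be in (0, 1)")
        if not self.transient_max_duration < self.stable_min_duration:
            raise ValueError(
                "transient_max_duration must be below stable_min_duration"
            )
        if self.averaging not in ("per_run", "pooled"):
            raise ValueError("averaging must be 'per_run' or 'pooled'")


class ResidenceEvent(NamedTuple):
    start: float     # ps
    end: float       # ps (start + duration)
    duration: float  # ps


@dataclass
class ContactProfile:
    """Per-run contact summary: fractions and residence events per residue."""

    residues: list[ResidueKey]
    contact_fraction: dict[ResidueKey, float]
    events: dict[ResidueKey, list[ResidenceEvent]]
    n_frames: int
    frame_interval: float
    hbond_fraction: dict[ResidueKey, float] | None = None

    def transient_only(self, residue: ResidueKey,
                       config: ContactConfig) -> bool:
        evs = self.events.get(residue, [])
        return bool(evs) and all(
            e.duration < config.transient_max_duration for e in evs
        )

    def has_stable(self, residue: ResidueKey, config: ContactConfig) -> bool:
        return any(
            e.duration > config.stable_min_duration
            for e in self.events.get(residue, [])
        )


def _residue_min_distances(
    frame_coords: np.ndarray, topology
) -> tuple[list[ResidueKey], np.ndarray]:
    """Min solute–residue heavy-atom distance per protein residue (one frame)."""
    keys, dmat = _series_min_distances(frame_coords[None, :, :], topology)
    return keys, dmat[0]


def _series_min_distances(
    coords: np.ndarray, topology
) -> tuple[list[ResidueKey], np.ndarray]:
    """(n_frames, n_residues) min distances between solute and each residue."""
    sol = topology.solute_indices
    prot = topology.protein_indices
    diff = coords[:, sol, None, :] - coords[:, None, prot, :]
    dist = np.linalg.norm(diff, axis=-1).min(axis=1)  # (n_frames, n_prot)

    keys: list[ResidueKey] = []
    key_index: dict[ResidueKey, int] = {}
    atom_group = np.empty(len(prot), dtype=int)
    for j, idx in enumerate(prot):
        key = (topology.residue_names[idx], int(topology.residue_numbers[idx]))
        if key not in key_index:
            key_index[key] = len(keys)
            keys.append(key)
        atom_group[j] = key_index[key]

    out = np.stack(
        [dist[:, atom_group == g].min(axis=1) for g in range(len(keys))],
        axis=1,
    )
    return keys, out


def detect_contacts(frame_coords, topology,
                    config: ContactConfig) -> set[ResidueKey]:
    """Residues whose minimum heavy-atom distance to the solute is ≤ cutoff."""
    coords = np.asarray(frame_coords, dtype=float)
    if coords.shape[0] != topology.n_atoms:
        raise ValueError("frame does not match topology atom count")
    keys, dmin = _residue_min_distances(coords, topology)
    return {k for k, d in zip(keys, dmin) if d <= config.cutoff}


def contact_series(
    traj: Trajectory, config: ContactConfig
) -> tuple[list[ResidueKey], np.ndarray]:
    """Boolean in-contact matrix, one row per frame, one column per residue."""
    keys, dmin = _series_min_distances(traj.coordinates, traj.topology)
    return keys, dmin <= config.cutoff


def residence_events(contact_series_1d, frame_interval: float
                     ) -> list[ResidenceEvent]:
    """Maximal runs of consecutive in-contact frames, as timed events.

    Duration is run length × frame interval; events are ordered and
    non-overlapping; gaps are never bridged.
    """
    series = np.asarray(contact_series_1d, dtype=bool)
    if series.size == 0:
        raise ValueError("contact series is empty")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    padded = np.concatenate([[False], series, [False]]).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [
        ResidenceEvent(
            start=float(s * frame_interval),
            end=float(s * frame_interval + (e - s) * frame_interval),
            duration=float((e - s) * frame_interval),
        )
        for s, e in zip(starts, ends)
    ]


def build_contact_profile(traj: Trajectory,
                          config: ContactConfig) -> ContactProfile:
    """Contact fractions, residence events and H-bond fractions for one run."""
    keys, in_contact = contact_series(traj, config)
    n_frames = in_contact.shape[0]
    fractions = dict(zip(keys, in_contact.mean(axis=0)))
    events = {
        k: residence_events(in_contact[:, j], traj.frame_interval)
        for j, k in enumerate(keys)
    }
    _, dmin = _series_min_distances(traj.coordinates, traj.topology)
    hbond = dict(zip(keys, (dmin <= config.hbond_cutoff).mean(axis=0)))
    return ContactProfile(
        residues=keys,
        contact_fraction={k: float(v) for k, v in fractions.items()},
        events=events,
        n_frames=n_frames,
        frame_interval=traj.frame_interval,
        hbond_fraction={k: float(v) for k, v in hbond.items()},
    )


def summarize_contacts(
    profiles: dict[str, ContactProfile],
    outcomes: dict[str, str],
    config: ContactConfig,
    geometry: PoreGeometry | None = None,
) -> pd.DataFrame:
    """Group per-run contact profiles by capture label and summarise.

    ``outcomes`` maps run id → label ("captured" | "possible" | "failed").
    Returns one row per (label, residue) with the mean contact fraction
    across the group's runs (or the pooled-frame fraction, per config), the
    extended flag, transient/stable event counts and the residue's zone.
    """
    missing = sorted(set(profiles) ^ set(outcomes))
    if missing:
        raise KeyError(f"profiles and outcomes disagree on runs: {missing}")

    groups: dict[str, list[str]] = {}
    for run_id in sorted(profiles):
        groups.setdefault(outcomes[run_id], []).append(run_id)

    rows = []
    for label in sorted(groups):
        run_ids = groups[label]
        residues = sorted(
            {k for r in run_ids for k in profiles[r].residues},
            key=lambda k: (k[1], k[0]),
        )
        for key in residues:
            fracs = [profiles[r].contact_fraction.get(key, 0.0)
                     for r in run_ids]
            if config.averaging == "per_run":
                mean_fraction = float(np.mean(fracs))
            else:
                frames = sum(profiles[r].n_frames for r in run_ids)
                hits = sum(
                    profiles[r].contact_fraction.get(key, 0.0)
                    * profiles[r].n_frames
                    for r in run_ids
                )
                mean_fraction = hits / frames if frames else 0.0
            all_events = [
                e for r in run_ids for e in profiles[r].events.get(key, [])
            ]
            rows.append(
                {
                    "label": label,
                    "residue_name": key[0],
                    "residue_number": key[1],
                    "residue": f"{key[0]}{key[1]}",
                    "zone": (
                        geometry.zone_of(key[1]).value
                        if geometry is not None and geometry.zone_of(key[1])
                        else ""
                    ),
                    "mean_fraction": mean_fraction,
                    "extended": mean_fraction
                    > config.extended_fraction_threshold,
                    "n_events": len(all_events),
                    "n_transient_events": sum(
                        e.duration < config.transient_max_duration
                        for e in all_events
                    ),
                    "n_stable_events": sum(
                        e.duration > config.stable_min_duration
                        for e in all_events
                    ),
                    "n_runs": len(run_ids),
                }
            )
    return pd.DataFrame(rows)


def zone_rollup(summary: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each label's extended residues per zone."""
    ext = summary[summary["extended"]]
    if ext.empty:
        return pd.DataFrame(columns=["label", "zone", "fraction", "n_residues"])
    rows = []
    for label, grp in ext.groupby("label"):
        counts = grp.groupby("zone").size()
        total = counts.sum()
        for zone, cnt in counts.items():
            rows.append(
                {"label": label, "zone": zone,
                 "fraction": cnt / total, "n_residues": int(cnt)}
            )
    return pd.DataFrame(rows)
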