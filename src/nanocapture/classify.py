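"""Trichotomous capture classification of trajectories.

A trajectory is classified against the N17 capture plane:

* **captured** — every solute atom below the plane *and* inside the pore
  mouth radius.  Capture latches at the first such frame: no exit from the
  vestibule is ever observed once the nucleotide interacts with the protein
  below this region, so later frames cannot revoke the label.
* **possible** — the final frame straddles the plane (some atoms above,
  some below): the nucleotide sits at the edge of the vestibule entrance
  and could either enter or diffuse away.
* **failed** — the final frame lies entirely above the plane.

Frames entirely below the plane but *outside* the mouth radius are counted
as above the plane for labelling (the solute has slipped past the rim on
the outside of the cap); the ``excluded_outside_pore`` flag records that
this automated check fired, replacing the visual inspection it stands for.

Boundary convention: an atom exactly on the plane counts as above (strict
inequality for "below"), making "all atoms below" conservative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .geometry import PoreGeometry, axial_radial_coords
from .io import Trajectory

__all__ = [
    "FrameClass",
    "ClassificationConfig",
    "CaptureOutcome",
    "classify_frame",
    "classify_trajectory",
]


class FrameClass(str, enum.Enum):
    BELOW_ALL = "below_all"
    ABOVE_ALL = "above_all"
    STRADDLING = "straddling"


@dataclass(frozen=True)
class ClassificationConfig:
    """Planes and radii used for classification (nm).

    ``evaluation`` selects between latched classification (default; capture
    is absorbing) and final-frame-only classification, kept for sensitivity
    checks.
    """

    capture_plane_z: float = -0.5
    pore_mouth_radius: float = 1.3
    translocation_plane_z: float = -10.0
    evaluation: str = "latched"

    def __post_init__(self) -> None:
        if not self.translocation_plane_z < self.capture_plane_z:
            raise ValueError(
                "translocation_plane_z must lie below capture_plane_z"
            )
        if self.evaluation not in ("latched", "final_frame"):
            raise ValueError("evaluation must be 'latched' or 'final_frame'")

    @classmethod
    def from_geometry(cls, geometry: PoreGeometry,
                      evaluation: str = "latched") -> "ClassificationConfig":
        return cls(
            capture_plane_z=geometry.capture_plane_z,
            pore_mouth_radius=geometry.pore_mouth_radius,
            translocation_plane_z=geometry.barrel_exit_z,
            evaluation=evaluation,
        )


@dataclass(frozen=True)
class CaptureOutcome:
    """Per-trajectory label with latch time and translocation flag."""

    label: str                      # "captured" | "possible" | "failed"
    latch_time: float | None        # ps; set iff label == "captured"
    translocated: bool
    excluded_outside_pore: bool

    def __post_init__(self) -> None:
        if self.label not in ("captured", "possible", "failed"):
            raise ValueError(f"unknown label {self.label!r}")
        if (self.latch_time is not None) != (self.label == "captured"):
            raise ValueError("latch_time must be set iff label == 'captured'")
        if self.translocated and self.label != "captured":
            raise ValueError("translocated implies captured")


def classify_frame(
    solute_coords,
    config: ClassificationConfig,
    geometry: PoreGeometry,
) -> tuple[FrameClass, bool]:
    """Classify one frame's solute coordinates against the capture plane.

    Returns the frame class and ``inside_pore``: whether every atom that is
    below the plane lies within the pore mouth radius (vacuously true when
    none are below).
    """
    coords = np.asarray(solute_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0 or coords.shape[1] != 3:
        raise ValueError("solute coordinates must be a non-empty (n, 3) array")
    axial, radial = axial_radial_coords(coords, geometry)
    below = axial < config.capture_plane_z  # strict: on-plane counts as above
    inside = bool(np.all(radial[below] <= config.pore_mouth_radius))
    if below.all():
        cls = FrameClass.BELOW_ALL
    elif not below.any():
        cls = FrameClass.ABOVE_ALL
    else:
        cls = FrameClass.STRADDLING
    return cls, inside


def classify_trajectory(
    traj: Trajectory,
    config: ClassificationConfig,
    geometry: PoreGeometry,
) -> CaptureOutcome:
    """Scan a trajectory and assign its capture outcome.

    In latched mode the first frame that is fully below the plane and inside
    the mouth radius fixes the label as captured with that frame's time as
    the latch time.  Otherwise the final frame decides: straddling →
    possible, above (or below-but-outside) → failed.  Translocation is any
    frame with all atoms below the barrel exit plane.
    """
    if traj.n_frames == 0:
        raise ValueError("cannot classify an empty trajectory")
    sol = traj.topology.solute_indices
    # vectorised over frames: axial/radial of every solute atom in every frame
    coords = traj.coordinates[:, sol, :]
    n_frames, n_sol = coords.shape[:2]
    axial, radial = axial_radial_coords(coords.reshape(-1, 3), geometry)
    axial = axial.reshape(n_frames, n_sol)
    radial = radial.reshape(n_frames, n_sol)

    below = axial < config.capture_plane_z
    below_all = below.all(axis=1)
    above_all = ~below.any(axis=1)
    outside = radial > config.pore_mouth_radius
    inside_pore = ~(below & outside).any(axis=1)

    captured_frames = below_all & inside_pore
    excluded = bool((below_all & ~inside_pore).any())
    translocated_frames = (axial < config.translocation_plane_z).all(axis=1)

    def final_label() -> str:
        f = traj.n_frames - 1
        if captured_frames[f]:
            return "captured"
        if below_all[f]:      # below but outside the pore: counts as failed
            return "failed"
        if above_all[f]:
            return "failed"
        return "possible"

    if config.evaluation == "latched":
        hits = np.flatnonzero(captured_frames)
        if hits.size:
            first = int(hits[0])
            return CaptureOutcome(
                label="captured",
                latch_time=float(traj.times[first]),
                translocated=bool(translocated_frames[first:].any()),
                excluded_outside_pore=excluded,
            )
        label = final_label()
    else:
        label = final_label()

    if label == "captured":   # final_frame mode reaching here
        f = traj.n_frames - 1
        return CaptureOutcome(
            label="captured",
            latch_time=float(traj.times[f]),
            translocated=bool(translocated_frames.any()),
            excluded_outside_pore=excluded,
        )
    return CaptureOutcome(
        label=label, latch_time=None, translocated=False,
        excluded_outside_pore=excluded,
    )
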