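"""Simplified alpha-hemolysin pore geometry.

Alpha-hemolysin (αHL) is a heptameric pore with a wide cap/vestibule domain
sitting on top of a transmembrane beta barrel.  For capture-region analysis
only a handful of geometric references matter:

* the ring of K8 Cα atoms, whose centroid defines the release-point origin
  above the vestibule mouth,
* the ring of N17 Cα atoms ("capture plane"), against which trajectories are
  classified as captured / possible / failed,
* the vestibule mouth radius and the outer radius of the cap surface, and
* the barrel exit plane used to flag full translocation.

Everything here is a simplified, rotationally symmetric surrogate of the real
protein: the pore axis is the fixed z axis, the K8 ring centroid is the
coordinate origin, and residues are represented by labelled zones rather than
atomic detail.  All lengths are nm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ZoneLabel",
    "ResidueRing",
    "GeometryConfig",
    "PoreGeometry",
    "GeometryError",
    "build_default_pore",
    "ring_centroid",
    "axial_radial_coords",
    "DEFAULT_ZONE_MAP",
]


class GeometryError(ValueError):
    """A geometry configuration violates an ordering or shape constraint."""


class ZoneLabel(str, enum.Enum):
    """Coarse location of a residue in the simplified pore model."""

    VESTIBULE_INTERIOR = "vestibule_interior"
    VESTIBULE_RIM = "vestibule_rim"
    CAP_SURFACE = "cap_surface"
    BARREL = "barrel"


#: Residue-number → zone assignments for every residue the contact analysis
#: can report on.  Vestibule-interior residues line the cavity below the
#: mouth; rim residues sit at the edge of the entrance; D45/K46/N47 lie on
#: the outer cap surface where they can trap the nucleotide outside the pore.
DEFAULT_ZONE_MAP: dict[int, ZoneLabel] = {
    2: ZoneLabel.VESTIBULE_INTERIOR,   # D2
    3: ZoneLabel.VESTIBULE_INTERIOR,   # S3
    9: ZoneLabel.VESTIBULE_INTERIOR,   # T9
    13: ZoneLabel.VESTIBULE_INTERIOR,  # D13
    293: ZoneLabel.VESTIBULE_INTERIOR, # N293
    1: ZoneLabel.VESTIBULE_RIM,        # A1
    6: ZoneLabel.VESTIBULE_RIM,        # N6
    8: ZoneLabel.VESTIBULE_RIM,        # K8 (mouth ring)
    10: ZoneLabel.VESTIBULE_RIM,       # G10
    11: ZoneLabel.VESTIBULE_RIM,       # T11
    15: ZoneLabel.VESTIBULE_RIM,       # G15
    16: ZoneLabel.VESTIBULE_RIM,       # S16 / I16
    17: ZoneLabel.VESTIBULE_RIM,       # N17 (capture-plane ring)
    18: ZoneLabel.VESTIBULE_RIM,       # T18
    19: ZoneLabel.VESTIBULE_RIM,       # T19
    20: ZoneLabel.VESTIBULE_RIM,       # V20
    45: ZoneLabel.CAP_SURFACE,         # D45
    46: ZoneLabel.CAP_SURFACE,         # K46
    47: ZoneLabel.CAP_SURFACE,         # N47
}


@dataclass(frozen=True)
class ResidueRing:
    """A symmetric ring of equivalent residues (one Cα position each).

    Parameters
    ----------
    residue_name : str
        Three-or-fewer letter residue code shared by all members (e.g. "LYS").
    residue_number : int
        Sequence number shared by all members (e.g. 8 for the K8 ring).
    positions : (n, 3) array
        Cα positions in nm, one row per protomer.
    """

    residue_name: str
    residue_number: int
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise GeometryError("ring positions must be an (n, 3) array")
        if pos.shape[0] < 3:
            raise GeometryError(
                f"ring of {self.residue_name}{self.residue_number} has "
                f"{pos.shape[0]} members; at least 3 required"
            )
        # non-degenerate: members must not be collinear
        rel = pos - pos.mean(axis=0)
        if np.linalg.matrix_rank(rel, tol=1e-9) < 2:
            raise GeometryError("ring positions are collinear (degenerate ring)")
        object.__setattr__(self, "positions", pos)

    @property
    def member_count(self) -> int:
        return int(self.positions.shape[0])

    @property
    def centroid(self) -> np.ndarray:
        return ring_centroid(self)


def ring_centroid(ring: ResidueRing) -> np.ndarray:
    """Arithmetic mean of the ring member positions (nm)."""
    pos = np.asarray(ring.positions, dtype=float)
    if pos.size == 0:
        raise GeometryError("cannot take the centroid of an empty ring")
    return pos.mean(axis=0)


@dataclass(frozen=True)
class GeometryConfig:
    """Tunable dimensions of the surrogate pore (all nm).

    Defaults are αHL-like in proportion, not fitted to the crystal structure:
    a 1.3 nm mouth, a 5 nm cap, the N17 capture plane 0.5 nm below the K8
    ring and the barrel exit 10 nm below it.
    """

    pore_mouth_radius: float = 1.3
    cap_outer_radius: float = 5.0
    funnel_entry_radius: float = 2.2
    capture_plane_z: float = -0.5
    barrel_exit_z: float = -10.0
    n17_ring_radius: float = 1.15
    heptamer_size: int = 7

    def validate(self) -> None:
        if self.pore_mouth_radius <= 0:
            raise GeometryError("pore_mouth_radius must be positive")
        if not self.pore_mouth_radius < self.cap_outer_radius:
            raise GeometryError(
                "pore_mouth_radius must be smaller than cap_outer_radius "
                f"({self.pore_mouth_radius} >= {self.cap_outer_radius})"
            )
        if not (self.pore_mouth_radius <= self.funnel_entry_radius
                < self.cap_outer_radius):
            raise GeometryError(
                "funnel_entry_radius must lie between pore_mouth_radius "
                "and cap_outer_radius"
            )
        if not self.capture_plane_z < 0:
            raise GeometryError(
                "capture_plane_z must lie below the K8 ring centroid (z < 0)"
            )
        if not self.barrel_exit_z < self.capture_plane_z:
            raise GeometryError(
                "barrel_exit_z must lie below capture_plane_z "
                f"({self.barrel_exit_z} >= {self.capture_plane_z})"
            )
        if self.heptamer_size < 3:
            raise GeometryError("heptamer_size must be at least 3")


@dataclass(frozen=True)
class PoreGeometry:
    """Reference frame and classification surfaces of the surrogate pore.

    The coordinate origin is the K8 ring centroid and ``axis`` is the unit
    vector pointing *up*, away from the pore, so the axial coordinate of a
    release point is positive and descent into the vestibule is towards
    negative axial values.
    """

    k8_ring: ResidueRing
    n17_ring: ResidueRing
    axis: np.ndarray
    capture_plane_z: float
    pore_mouth_radius: float
    cap_outer_radius: float
    barrel_exit_z: float
    funnel_entry_radius: float = 2.2
    zone_map: dict[int, ZoneLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise GeometryError("pore axis must be a nonzero vector")
        object.__setattr__(self, "axis", axis / norm)
        if not self.capture_plane_z < 0:
            raise GeometryError("capture plane must lie below the K8 centroid")
        if not self.barrel_exit_z < self.capture_plane_z:
            raise GeometryError("barrel exit must lie below the capture plane")
        if not 0 < self.pore_mouth_radius < self.cap_outer_radius:
            raise GeometryError(
                "require 0 < pore_mouth_radius < cap_outer_radius"
            )

    @property
    def origin(self) -> np.ndarray:
        return ring_centroid(self.k8_ring)

    def zone_of(self, residue_number: int) -> ZoneLabel | None:
        """Zone label for a residue number, or None if unzoned."""
        return self.zone_map.get(int(residue_number))

    def funnel_radius_at(self, z: float | np.ndarray):
        """Radius of the vestibule entrance funnel at axial coordinate z.

        The funnel opens from the mouth radius at the capture plane to the
        entry radius at the cap surface (z = 0), clamped to that range
        outside the neck.
        """
        frac = (np.asarray(z) - self.capture_plane_z) / (0.0 - self.capture_plane_z)
        frac = np.clip(frac, 0.0, 1.0)
        return self.pore_mouth_radius + frac * (
            self.funnel_entry_radius - self.pore_mouth_radius
        )

    def to_dict(self) -> dict:
        return {
            "pore_mouth_radius": float(self.pore_mouth_radius),
            "cap_outer_radius": float(self.cap_outer_radius),
            "funnel_entry_radius": float(self.funnel_entry_radius),
            "capture_plane_z": float(self.capture_plane_z),
            "barrel_exit_z": float(self.barrel_exit_z),
            "axis": [float(x) for x in self.axis],
            "k8_ring": {
                "residue_name": self.k8_ring.residue_name,
                "residue_number": self.k8_ring.residue_number,
                "positions": self.k8_ring.positions.tolist(),
            },
            "n17_ring": {
                "residue_name": self.n17_ring.residue_name,
                "residue_number": self.n17_ring.residue_number,
                "positions": self.n17_ring.positions.tolist(),
            },
            "zone_map": {int(k): v.value for k, v in self.zone_map.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PoreGeometry":
        def _ring(rd):
            return ResidueRing(
                residue_name=rd["residue_name"],
                residue_number=int(rd["residue_number"]),
                positions=np.asarray(rd["positions"], dtype=float),
            )

        return cls(
            k8_ring=_ring(d["k8_ring"]),
            n17_ring=_ring(d["n17_ring"]),
            axis=np.asarray(d.get("axis", [0.0, 0.0, 1.0]), dtype=float),
            capture_plane_z=float(d["capture_plane_z"]),
            pore_mouth_radius=float(d["pore_mouth_radius"]),
            cap_outer_radius=float(d["cap_outer_radius"]),
            barrel_exit_z=float(d["barrel_exit_z"]),
            funnel_entry_radius=float(d.get("funnel_entry_radius", 2.2)),
            zone_map={
                int(k): ZoneLabel(v) for k, v in d.get("zone_map", {}).items()
            },
        )

    @classmethod
    def load(cls, path) -> "PoreGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _symmetric_ring(radius: float, z: float, n: int) -> np.ndarray:
    angles = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.full(n, z)]
    )


def build_default_pore(config: GeometryConfig | None = None) -> PoreGeometry:
    """Construct the surrogate pore geometry.

    The K8 ring is placed on the mouth circle at z = 0 (so its centroid is
    the origin), the N17 ring on the capture plane, and the default zone map
    labels every residue the contact analysis reports on.

    Raises
    ------
    GeometryError
        If the configuration violates the radius/plane ordering constraints.
    """
    config = config or GeometryConfig()
    config.validate()
    n = config.heptamer_size
    k8 = ResidueRing(
        residue_name="LYS",
        residue_number=8,
        positions=_symmetric_ring(config.pore_mouth_radius, 0.0, n),
    )
    n17 = ResidueRing(
        residue_name="ASN",
        residue_number=17,
        positions=_symmetric_ring(config.n17_ring_radius, config.capture_plane_z, n),
    )
    return PoreGeometry(
        k8_ring=k8,
        n17_ring=n17,
        axis=np.array([0.0, 0.0, 1.0]),
        capture_plane_z=config.capture_plane_z,
        pore_mouth_radius=config.pore_mouth_radius,
        cap_outer_radius=config.cap_outer_radius,
        barrel_exit_z=config.barrel_exit_z,
        funnel_entry_radius=config.funnel_entry_radius,
        zone_map=dict(DEFAULT_ZONE_MAP),
    )


def axial_radial_coords(point, geometry: PoreGeometry):
    """Cylindrical (axial, radial) coordinates of points in the pore frame.

    axial is the signed projection onto the pore axis relative to the K8 ring
    centroid (positive above the ring); radial is the distance from the axis.
    Accepts a single 3-vector or an (n, 3) array; returns matching scalars or
    arrays (nm).
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    rel = p - geometry.origin
    axial = rel @ geometry.axis
    radial = np.linalg.norm(rel - np.outer(axial, geometry.axis), axis=1)
    if single:
        return float(axial[0]), float(radial[0])
    return axial, radial
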