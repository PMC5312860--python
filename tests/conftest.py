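import numpy as np
import pytest

from nanocapture import (
    ClassificationConfig,
    Trajectory,
    build_default_pore,
    build_synthetic_topology,
)


@pytest.fixture(scope="session")
def geometry():
    return build_default_pore()


@pytest.fixture(scope="session")
def topology(geometry):
    return build_synthetic_topology(geometry)


@pytest.fixture(scope="session")
def classification_config(geometry):
    return ClassificationConfig.from_geometry(geometry)


@pytest.fixture
def make_trajectory(topology):
    """Build a trajectory from a solute-centre path over static protein."""

    def _make(centre_path, frame_interval=10.0, orientation="down"):
        from nanocapture.synthetic import solute_offsets

        centre_path = np.asarray(centre_path, dtype=float)
        n_frames = centre_path.shape[0]
        coords = np.broadcast_to(
            topology.reference_positions, (n_frames, topology.n_atoms, 3)
        ).copy()
        offsets = solute_offsets(orientation)
        sol = topology.solute_indices
        coords[:, sol, :] = centre_path[:, None, :] + offsets[None, :, :]
        times = np.arange(n_frames) * frame_interval
        return Trajectory(
            topology=topology, times=times, coordinates=coords,
            frame_interval=frame_interval,
        )

    return _make


MINIMAL_PDB = """\
ATOM      1  CA  LYS A   8      13.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  LYS B   8       8.109  10.163   0.000  1.00  0.00           C
ATOM      3  CA  LYS C   8      -2.893  12.674   0.000  1.00  0.00           C
ATOM      4  CA  LYS D   8     -11.713   5.644   0.000  1.00  0.00           C
ATOM      5  CA  LYS E   8     -11.713  -5.644   0.000  1.00  0.00           C
ATOM      6  CA  LYS F   8      -2.893 -12.674   0.000  1.00  0.00           C
ATOM      7  CA  LYS G   8       8.109 -10.163   0.000  1.00  0.00           C
ATOM      8  CA  ASP A  45      24.000   0.000   1.500  1.00  0.00           C
ATOM      9  CA  LYS A  46      27.000   0.000   1.500  1.00  0.00           C
ATOM     10  CA  ASN A  47      30.000   0.000   1.500  1.00  0.00           C
HETATM   11  P   CMP X 500       0.000   0.000  30.000  1.00  0.00           P
HETATM   12  C1' CMP X 500       0.000   0.000  32.500  1.00  0.00           C
HETATM   13  N1  CMP X 500       0.000   0.000  35.000  1.00  0.00           N
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path
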