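import numpy as np
import pytest

from allonet import synthetic as syn
from allonet.corrnet import DynamicNetwork
from allonet.trajio import ResidueTrajectory


@pytest.fixture(scope="session")
def two_block_spec():
    return syn.SyntheticSystemSpec.with_blocks((10, 10), n_frames=500, seed=7)


@pytest.fixture(scope="session")
def two_block_traj(two_block_spec):
    return syn.generate_trajectory(two_block_spec)


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory, two_block_spec, two_block_traj):
    """On-disk PDB topology + DCD trajectory of the two-block system."""
    outdir = tmp_path_factory.mktemp("fixture")
    topo = syn.generate_topology(two_block_spec)
    return syn.write_fixture(topo, two_block_traj, outdir)


def make_traj(coords, residue_ids=None, atoms_per_residue=1, names=None,
              superposed=True):
    """Hand-built ResidueTrajectory from a (frames, atoms, 3) array."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    n_res = n_atoms // atoms_per_residue
    if residue_ids is None:
        residue_ids = np.arange(1, n_res + 1)
    resindex = np.repeat(np.arange(n_res), atoms_per_residue)
    if names is None:
        names = (["CA"] + [f"CB{i}" for i in range(1, atoms_per_residue)]) * n_res
    return ResidueTrajectory(residue_ids=np.asarray(residue_ids),
                             atom_resindex=resindex, atom_names=names,
                             coords=coords, superposed=superposed)


def net_from_graph(G) -> DynamicNetwork:
    """Wrap a bare networkx graph (with 'weight' attrs) as a DynamicNetwork."""
    return DynamicNetwork(graph=G, residue_ids=np.array(sorted(G.nodes)),
                          contact_fraction=0.75, rt=5.0)
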