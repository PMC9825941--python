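"""Shared fixtures: small programmatically generated systems."""

import numpy as np
import pytest

from ensemblecd.trajectory_io import AtomRecord, Frame, Trajectory


def make_topology(names, resnames=None, resids=None, mol_ids=None):
    n = len(names)
    resnames = resnames or ["GLY"] * n
    resids = resids or [1] * n
    mol_ids = mol_ids or [0] * n
    return [
        AtomRecord(index=i, name=names[i], residue_name=resnames[i],
                   residue_index=resids[i], molecule_id=mol_ids[i],
                   element=names[i][0])
        for i in range(n)
    ]


def make_trajectory(coords, box=None, topology=None, superposed=False):
    """Trajectory from an (n_frames, n_atoms, 3) array."""
    coords = np.asarray(coords, dtype=float)
    if topology is None:
        topology = make_topology([f"C{i}" if i else "CA" for i in range(coords.shape[1])])
    frames = [Frame(coordinates=c, box=box, time=float(t))
              for t, c in enumerate(coords)]
    return Trajectory(topology=topology, frames=frames, superposed=superposed)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def gag_topology():
    """Backbone-only 3-residue peptide: N, CA, C, O per residue."""
    names, resnames, resids = [], [], []
    for r, resname in enumerate(("GLY", "ALA", "GLY"), start=1):
        for name in ("N", "CA", "C", "O"):
            names.append(name)
            resnames.append(resname)
            resids.append(r)
    return make_topology(names, resnames, resids, mol_ids=[0] * len(names))


@pytest.fixture
def gag_trajectory(gag_topology, rng):
    """Three random frames over the 12-atom peptide topology."""
    coords = rng.normal(scale=0.3, size=(3, 12, 3))
    frames = [Frame(coordinates=c, box=None, time=float(t))
              for t, c in enumerate(coords)]
    return Trajectory(topology=gag_topology, frames=frames)
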