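"""Shared fixtures: synthetic bundles, hand-written PDB text, toy topologies."""

from __future__ import annotations

import numpy as np
import pytest

import gopull as gp
from gopull.go_model import GoTopology, SIGMA_FACTOR
from gopull.structure_io import AtomRecord, CAlphaStructure, Residue


def format_pdb_atom(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_seq: int,
    xyz,
    occupancy: float = 1.0,
    element: str = "C",
    altloc: str = " ",
) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc:1s}{res_name:3s} {chain:1s}"
        f"{res_seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb_text(path, lines) -> str:
    text = "\n".join(lines + ["END"]) + "\n"
    path.write_text(text)
    return str(path)


@pytest.fixture(scope="session")
def bundle4():
    """Standard 4-helix test bundle (57 residues) with contact map/topology."""
    s = gp.make_helix_bundle(4, 12, 3, 10.0, seed=1)
    cmap = gp.build_contact_map(s)
    topo = gp.build_topology(s, cmap)
    return s, cmap, topo


@pytest.fixture(scope="session")
def bundle2():
    s = gp.make_helix_bundle(2, 10, 3, 10.0, seed=2)
    cmap = gp.build_contact_map(s)
    topo = gp.build_topology(s, cmap)
    return s, cmap, topo


@pytest.fixture()
def two_bead_topology():
    """Two beads joined only by one breakable native contact at 5 Å."""
    r0 = 5.0
    return GoTopology(
        n_residues=2,
        bond_i=[], bond_j=[], bond_r0=[], bond_k=100.0,
        chir_first=[], chir_c0=[], chir_inv_norm=[], chirality_k=1.0,
        nat_i=[0], nat_j=[1], nat_sigma=[r0 / SIGMA_FACTOR], epsilon=1.0,
        rep_i=[], rep_j=[], repulsive_cutoff=4.0,
        native_positions=np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]),
    )


def make_calpha_structure(ca_coords, atoms_per_residue=None) -> CAlphaStructure:
    """Structure from bare Cα coordinates, with optional extra heavy atoms.

    ``atoms_per_residue`` maps residue offset → list of (name, element, xyz).
    Every residue always carries its Cα as a heavy atom.
    """
    ca_coords = np.asarray(ca_coords, dtype=float)
    residues = []
    for i, ca in enumerate(ca_coords):
        heavy = [AtomRecord(i + 1, "ALA", "CA", "C", ca, 1.70)]
        if atoms_per_residue and i in atoms_per_residue:
            for name, elem, xyz in atoms_per_residue[i]:
                radius = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}[elem]
                heavy.append(AtomRecord(i + 1, "ALA", name, elem, np.asarray(xyz, float), radius))
        residues.append(Residue(i + 1, "ALA", ca, heavy))
    return CAlphaStructure(residues)
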