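"""Structure-based (Gō) coarse-grained force field.

Native contacts come from the overlap criterion: each heavy atom's van der
Waals radius is enlarged 1.24×, and two residues separated in sequence by at
least two others form a native contact if any of their heavy-atom pairs
overlap. Native pairs interact through a Lennard-Jones well of uniform depth
1 ε whose minimum sits at the native Cα–Cα distance; all remaining pairs are
purely repulsive below 4 Å. Consecutive residues are connected by stiff
harmonic bonds, and a chirality term restrains the signed triple product of
consecutive bond vectors to its native value.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .structure_io import CAlphaStructure

__all__ = [
    "ContactMap",
    "GoTopology",
    "EnergyBreakdown",
    "GoModelParams",
    "build_contact_map",
    "build_contact_map_calpha",
    "build_topology",
    "energy_forces",
]

SIGMA_FACTOR = 2.0 ** (1.0 / 6.0)  # LJ minimum at σ·2^(1/6)
REPULSIVE_CUTOFF = 4.0  # Å
DEFAULT_ENLARGEMENT = 1.24
DEFAULT_MIN_SEP = 3  # |i-j| ≥ 3: at least two residues in between


@dataclass
class ContactMap:
    """Native contact list with 0-based chain offsets ``i < j``."""

    pairs: list[tuple[int, int]]
    native_distance: np.ndarray  # Å, aligned with pairs
    n_residues: int
    min_sep: int = DEFAULT_MIN_SEP

    def __post_init__(self) -> None:
        self.native_distance = np.asarray(self.native_distance, dtype=float)
        for (i, j), d in zip(self.pairs, self.native_distance):
            if not i < j:
                raise ValueError(f"contact pair ({i}, {j}) not ordered")
            if j - i < self.min_sep:
                raise ValueError(f"contact pair ({i}, {j}) violates min_sep")
            if d <= 0:
                raise ValueError(f"contact pair ({i}, {j}) has non-positive distance")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(pair) in set(map(tuple, self.pairs))

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("i\tj\tnative_distance\n")
            for (i, j), d in zip(self.pairs, self.native_distance):
                fh.write(f"{i}\t{j}\t{d:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str, n_residues: int, min_sep: int = DEFAULT_MIN_SEP) -> "ContactMap":
        pairs, dist = [], []
        with open(path) as fh:
            next(fh)
            for line in fh:
                i, j, d = line.split()
                pairs.append((int(i), int(j)))
                dist.append(float(d))
        return cls(pairs, np.array(dist), n_residues, min_sep)


@dataclass
class GoModelParams:
    """Force-field parameters not fixed by the native structure."""

    epsilon: float = 1.0  # uniform LJ well depth, ε
    bond_k: float = 100.0  # ε/Å² (not stated in the source model; configurable)
    chirality_k: float = 1.0  # ε
    repulsive_cutoff: float = REPULSIVE_CUTOFF  # Å
    mass: float = 1.0


@dataclass
class GoTopology:
    """Complete force-field instantiation for one chain.

    All index arrays are 0-based chain offsets. ``sigma`` is fixed by
    ``native_distance / 2^(1/6)`` so each native LJ well has its minimum at
    the native separation. Non-native repulsive pairs carry a shifted LJ
    repulsion truncated at its minimum (``repulsive_cutoff``), keeping energy
    and force continuous at the cutoff.
    """

    n_residues: int
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_r0: np.ndarray
    bond_k: float
    chir_first: np.ndarray  # first residue of each 4-residue window
    chir_c0: np.ndarray  # native chirality values
    chir_inv_norm: np.ndarray  # 1/(product of native bond lengths)
    chirality_k: float
    nat_i: np.ndarray
    nat_j: np.ndarray
    nat_sigma: np.ndarray
    epsilon: float
    rep_i: np.ndarray
    rep_j: np.ndarray
    repulsive_cutoff: float
    mass: float = 1.0
    native_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("bond_i", "bond_j", "chir_first", "nat_i", "nat_j", "rep_i", "rep_j"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        for name in ("bond_r0", "chir_c0", "chir_inv_norm", "nat_sigma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.native_positions is not None:
            self.native_positions = np.asarray(self.native_positions, dtype=np.float64)

    @property
    def n_native_contacts(self) -> int:
        return len(self.nat_i)

    @property
    def contour_length(self) -> float:
        """Sum of native bond lengths, Å."""
        return float(self.bond_r0.sum())

    def native_contact_distances(self) -> np.ndarray:
        return self.nat_sigma * SIGMA_FACTOR

    def to_json(self, path: str) -> None:
        doc = {}
        for k, v in asdict(self).items():
            doc[k] = v.tolist() if isinstance(v, np.ndarray) else v
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str) -> "GoTopology":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("native_positions") is not None:
            doc["native_positions"] = np.array(doc["native_positions"])
        return cls(**doc)


@dataclass
class EnergyBreakdown:
    bonds: float = 0.0
    chirality: float = 0.0
    native_lj: float = 0.0
    repulsive: float = 0.0
    pulling_springs: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.bonds
            + self.chirality
            + self.native_lj
            + self.repulsive
            + self.pulling_springs
        )


# ---------------------------------------------------------------------------
# Contact map
# ---------------------------------------------------------------------------


def build_contact_map(
    structure: CAlphaStructure,
    enlargement: float = DEFAULT_ENLARGEMENT,
    min_sep: int = DEFAULT_MIN_SEP,
) -> ContactMap:
    """Native contact map by the heavy-atom overlap criterion.

    Residues ``(i, j)`` (0-based offsets, ``j - i ≥ min_sep``) form a contact
    iff some heavy-atom pair satisfies ``d < enlargement·(r_i + r_j)``
    (strict). The stored native distance is the Cα–Cα distance.
    """
    if not structure.has_heavy_atoms:
        raise ValueError(
            "structure has no heavy atoms; use build_contact_map_calpha() "
            "for the Cα-distance fallback criterion"
        )
    coords = []
    radii = []
    owner = []
    for k, res in enumerate(structure.residues):
        for a in res.heavy_atoms:
            coords.append(a.position)
            radii.append(a.vdw_radius)
            owner.append(k)
    coords = np.array(coords)
    radii = np.array(radii)
    owner = np.array(owner)

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    cutoff = enlargement * (radii[:, None] + radii[None, :])
    sep = owner[None, :] - owner[:, None]
    overlap = (dist < cutoff) & (sep >= min_sep)

    ca = structure.ca_coords
    pair_set = set()
    ai, aj = np.where(overlap)
    for a, b in zip(ai, aj):
        pair_set.add((int(owner[a]), int(owner[b])))
    pairs = sorted(pair_set)
    ndist = np.array([np.linalg.norm(ca[i] - ca[j]) for i, j in pairs])
    return ContactMap(pairs, ndist, structure.n_residues, min_sep)


def build_contact_map_calpha(
    structure: CAlphaStructure,
    cutoff: float = 7.5,
    min_sep: int = DEFAULT_MIN_SEP,
) -> ContactMap:
    """Cα-distance fallback contact criterion (NOT the overlap criterion).

    Provided for structures without heavy atoms; pairs with Cα–Cα distance
    below ``cutoff`` and sequence separation ≥ ``min_sep`` become contacts.
    """
    ca = structure.ca_coords
    n = len(ca)
    pairs, ndist = [], []
    for i in range(n):
        for j in range(i + min_sep, n):
            d = float(np.linalg.norm(ca[i] - ca[j]))
            if d < cutoff:
                pairs.append((i, j))
                ndist.append(d)
    return ContactMap(pairs, np.array(ndist), n, min_sep)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


def _chirality_values(coords: np.ndarray, inv_norm: np.ndarray | None = None):
    """Signed triple products of consecutive bond vectors, normalized.

    The normalization is the product of the three native bond lengths
    (``inv_norm`` precomputed as its inverse); when building a topology it is
    derived from the coordinates themselves.
    """
    b = np.diff(coords, axis=0)
    if len(b) < 3:
        return np.zeros(0), np.zeros(0)
    v1, v2, v3 = b[:-2], b[1:-1], b[2:]
    triple = np.einsum("ij,ij->i", np.cross(v1, v2), v3)
    if inv_norm is None:
        lens = np.linalg.norm(b, axis=1)
        inv_norm = 1.0 / (lens[:-2] * lens[1:-1] * lens[2:])
    return triple * inv_norm, inv_norm


def build_topology(
    structure: CAlphaStructure,
    contact_map: ContactMap,
    params: GoModelParams | None = None,
) -> GoTopology:
    """Instantiate the full force field from native coordinates and contacts."""
    params = params or GoModelParams()
    coords = structure.ca_coords
    n = len(coords)
    if contact_map.n_residues != n:
        raise ValueError("contact map inconsistent with structure size")
    if contact_map.pairs and max(j for _, j in contact_map.pairs) >= n:
        raise ValueError("contact references residue absent from structure")

    bond_i = np.arange(n - 1)
    bond_j = bond_i + 1
    bond_r0 = np.linalg.norm(coords[1:] - coords[:-1], axis=1)

    chir_c0, chir_inv_norm = _chirality_values(coords)
    chir_first = np.arange(len(chir_c0))

    nat_i = np.array([p[0] for p in contact_map.pairs], dtype=np.int64)
    nat_j = np.array([p[1] for p in contact_map.pairs], dtype=np.int64)
    nat_sigma = contact_map.native_distance / SIGMA_FACTOR

    native = set(map(tuple, contact_map.pairs))
    rep_pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + contact_map.min_sep, n)
        if (i, j) not in native
    ]
    rep_i = np.array([p[0] for p in rep_pairs], dtype=np.int64)
    rep_j = np.array([p[1] for p in rep_pairs], dtype=np.int64)

    return GoTopology(
        n_residues=n,
        bond_i=bond_i,
        bond_j=bond_j,
        bond_r0=bond_r0,
        bond_k=params.bond_k,
        chir_first=chir_first,
        chir_c0=chir_c0,
        chir_inv_norm=chir_inv_norm,
        chirality_k=params.chirality_k,
        nat_i=nat_i,
        nat_j=nat_j,
        nat_sigma=nat_sigma,
        epsilon=params.epsilon,
        rep_i=rep_i,
        rep_j=rep_j,
        repulsive_cutoff=params.repulsive_cutoff,
        mass=params.mass,
        native_positions=coords,
    )


# ---------------------------------------------------------------------------
# Energies and forces
# ---------------------------------------------------------------------------


def energy_forces(
    topology: GoTopology,
    positions: np.ndarray,
) -> tuple[EnergyBreakdown, np.ndarray]:
    """Potential energy by term and exact negative-gradient forces.

    Raises on coincident interacting beads rather than returning infinities.
    """
    from ._kernels import forces_full

    positions = np.ascontiguousarray(positions, dtype=np.float64)
    if positions.shape != (topology.n_residues, 3):
        raise ValueError(
            f"positions shape {positions.shape} does not match "
            f"topology ({topology.n_residues}, 3)"
        )
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite positions")
    forces = np.zeros_like(positions)
    e_bond, e_chir, e_lj, e_rep, status = forces_full(
        positions,
        topology.bond_i,
        topology.bond_j,
        topology.bond_r0,
        topology.bond_k,
        topology.chir_first,
        topology.chir_c0,
        topology.chir_inv_norm,
        topology.chirality_k,
        topology.nat_i,
        topology.nat_j,
        topology.nat_sigma,
        topology.epsilon,
        topology.rep_i,
        topology.rep_j,
        topology.repulsive_cutoff,
        forces,
    )
    if status != 0:
        raise ValueError("coincident beads: zero distance in interacting pair")
    breakdown = EnergyBreakdown(
        bonds=e_bond, chirality=e_chir, native_lj=e_lj, repulsive=e_rep
    )
    return breakdown, forces
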