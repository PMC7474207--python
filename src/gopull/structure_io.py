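"""Structure input/output and synthetic helix-bundle generation.

Reads Cα chains (with retained heavy atoms) from PDB files, annotates
helices from Cα geometry alone, and builds idealized Cα helix bundles so
every downstream module is testable without external structure files.

Residue numbering from the source file is preserved on each residue;
internal arrays are 0-based in chain order, with ``CAlphaStructure.index_of``
mapping original residue numbers to array offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.optimize import brentq

__all__ = [
    "AtomRecord",
    "Residue",
    "CAlphaStructure",
    "HelixAnnotation",
    "HelixDetectorParams",
    "VDW_RADII",
    "read_pdb_calpha",
    "write_pdb",
    "write_xyz",
    "assign_helices",
    "make_helix_bundle",
    "ideal_helix_coords",
]

#: built-in element → van der Waals radius map (Å) for the overlap criterion
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
_VDW_FALLBACK = 1.70

#: plausible range for consecutive Cα–Cα distances in native structures (Å)
_CA_CA_RANGE = (2.5, 4.5)


@dataclass
class AtomRecord:
    """One heavy atom retained for contact-map construction."""

    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    vdw_radius: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")
        if self.vdw_radius <= 0:
            raise ValueError(f"non-positive vdW radius for atom {self.atom_name}")


@dataclass
class Residue:
    """One residue: original index, name, Cα position and its heavy atoms."""

    index: int
    name: str
    ca: np.ndarray
    heavy_atoms: list[AtomRecord] = field(default_factory=list)


@dataclass
class HelixAnnotation:
    """Helix segments (labelled H1… from the N-terminus) plus a per-residue flag.

    ``segments`` holds ``(label, start_residue, end_residue)`` in the
    structure's residue numbering, inclusive; ``per_residue_helical`` is
    aligned with chain order.
    """

    segments: list[tuple[str, int, int]]
    per_residue_helical: np.ndarray

    @property
    def labels(self) -> list[str]:
        return [s[0] for s in self.segments]

    def segment_residue_offsets(self, structure: "CAlphaStructure") -> dict[str, np.ndarray]:
        """Map each helix label to 0-based chain offsets of its residues."""
        out = {}
        for label, start, end in self.segments:
            i0 = structure.index_of[start]
            i1 = structure.index_of[end]
            out[label] = np.arange(i0, i1 + 1)
        return out


@dataclass
class CAlphaStructure:
    residues: list[Residue]
    chain_id: str = "A"
    source: str = "synthetic"
    warnings: list[str] = field(default_factory=list)
    ground_truth_helices: HelixAnnotation | None = None

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([r.index for r in self.residues], dtype=int)

    @property
    def index_of(self) -> dict[int, int]:
        """Original residue number → 0-based chain offset."""
        return {r.index: i for i, r in enumerate(self.residues)}

    @property
    def has_heavy_atoms(self) -> bool:
        return all(len(r.heavy_atoms) > 0 for r in self.residues)

    def validate(self) -> None:
        idx = self.residue_indices
        if np.any(np.diff(idx) <= 0):
            raise ValueError("residue indices must be strictly increasing")


def _vdw_radius(element: str, warnings: list[str]) -> float:
    element = element.strip().upper()
    if element in VDW_RADII:
        return VDW_RADII[element]
    msg = f"unknown element {element!r}: using fallback vdW radius {_VDW_FALLBACK} Å"
    if msg not in warnings:
        warnings.append(msg)
    return _VDW_FALLBACK


def read_pdb_calpha(
    path: str,
    chain: str = "A",
    residue_range: tuple[int, int] | None = None,
    model: int = 1,
) -> CAlphaStructure:
    """Read one chain of a PDB file as a Cα structure with retained heavy atoms.

    Only ``ATOM`` records are considered; hydrogens are dropped; alternate
    locations are resolved to the highest-occupancy conformer.

    Parameters
    ----------
    path:
        PDB file path.
    chain:
        Chain identifier; a missing chain is an error.
    residue_range:
        Optional inclusive 1-based ``(first, last)`` range filter applied to
        the file's residue numbering.
    model:
        Model number for multi-model (e.g. NMR) files.

    Raises
    ------
    ValueError
        If the chain is absent or any selected residue lacks a Cα atom.
    """
    pdb = PDBFile.read(path)
    atoms = pdb.get_structure(model=model, altloc="occupancy")
    atoms = atoms[~atoms.hetero]
    available = sorted(set(atoms.chain_id))
    atoms = atoms[atoms.chain_id == chain]
    if atoms.array_length() == 0:
        raise ValueError(
            f"chain {chain!r} not found in {path} (available chains: {available})"
        )
    if residue_range is not None:
        lo, hi = residue_range
        atoms = atoms[(atoms.res_id >= lo) & (atoms.res_id <= hi)]
        if atoms.array_length() == 0:
            raise ValueError(f"no residues of chain {chain!r} in range {lo}-{hi}")

    warnings: list[str] = []
    residues: list[Residue] = []
    for res_id in np.unique(atoms.res_id):
        sel = atoms[atoms.res_id == res_id]
        heavy = sel[(sel.element != "H") & (sel.element != "D")]
        ca_mask = heavy.atom_name == "CA"
        if not np.any(ca_mask):
            raise ValueError(
                f"residue {int(res_id)} ({sel.res_name[0]}) has no CA atom"
            )
        ca = heavy.coord[ca_mask][0].astype(float)
        records = [
            AtomRecord(
                residue_index=int(res_id),
                residue_name=str(heavy.res_name[k]),
                atom_name=str(heavy.atom_name[k]),
                element=str(heavy.element[k]),
                position=heavy.coord[k].astype(float),
                vdw_radius=_vdw_radius(str(heavy.element[k]), warnings),
            )
            for k in range(heavy.array_length())
        ]
        residues.append(Residue(int(res_id), str(sel.res_name[0]), ca, records))

    idx = np.array([r.index for r in residues])
    gaps = np.where(np.diff(idx) > 1)[0]
    for g in gaps:
        warnings.append(f"gap in residue numbering between {idx[g]} and {idx[g + 1]}")
    coords = np.array([r.ca for r in residues])
    if len(coords) > 1:
        d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        bad = np.where((d < _CA_CA_RANGE[0]) | (d > _CA_CA_RANGE[1]))[0]
        for b in bad:
            warnings.append(
                f"Cα–Cα distance {d[b]:.2f} Å between residues "
                f"{idx[b]} and {idx[b + 1]} outside {_CA_CA_RANGE}"
            )

    out = CAlphaStructure(residues, chain_id=chain, source=str(path), warnings=warnings)
    out.validate()
    return out


def write_pdb(structure: CAlphaStructure, path: str) -> None:
    """Write all retained heavy atoms of a structure to a PDB file."""
    records = [a for r in structure.residues for a in r.heavy_atoms]
    if not records:  # Cα-only structure: emit CA atoms
        records = [
            AtomRecord(r.index, r.name, "CA", "C", r.ca, _VDW_FALLBACK)
            for r in structure.residues
        ]
    n = len(records)
    arr = struc.AtomArray(n)
    arr.coord = np.array([a.position for a in records], dtype=np.float32)
    arr.chain_id = np.array([structure.chain_id] * n)
    arr.res_id = np.array([a.residue_index for a in records])
    arr.res_name = np.array([a.residue_name for a in records])
    arr.atom_name = np.array([a.atom_name for a in records])
    arr.element = np.array([a.element for a in records])
    arr.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(path)


def write_xyz(path: str, frames: np.ndarray, comment: str = "") -> None:
    """Write Cα frames as a plain multi-frame XYZ trajectory."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for f, frame in enumerate(frames):
            fh.write(f"{len(frame)}\n")
            fh.write(f"frame {f} {comment}\n")
            for x, y, z in frame:
                fh.write(f"CA {x:.4f} {y:.4f} {z:.4f}\n")


def read_xyz(path: str) -> np.ndarray:
    """Read a multi-frame XYZ trajectory written by :func:`write_xyz`."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i].split()[0])
        block = lines[i + 2 : i + 2 + n]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    return np.array(frames, dtype=float)


# ---------------------------------------------------------------------------
# Helix detection from Cα geometry
# ---------------------------------------------------------------------------


@dataclass
class HelixDetectorParams:
    """Thresholds of the Cα-geometry helix detector.

    Residue window ``i`` is helical when d(i, i+3) and d(i, i+4) both fall in
    compact-turn windows; all five residues of a passing window are marked.
    """

    d13_range: tuple[float, float] = (4.5, 6.0)
    d14_range: tuple[float, float] = (5.0, 6.8)
    #: sanity gate on the four Cα–Cα virtual bonds of a window; real chains
    #: always satisfy it (≈3.8 Å), it only rejects non-peptide-like geometry
    bond_range: tuple[float, float] = (3.0, 4.6)
    min_segment_len: int = 4


def assign_helices(
    structure: CAlphaStructure | np.ndarray,
    params: HelixDetectorParams | None = None,
) -> HelixAnnotation:
    """Annotate helices of a Cα chain from i→i+3 / i→i+4 distance windows.

    Accepts a structure or a bare ``(n, 3)`` coordinate array (used per-frame
    by the trajectory analyses). Chains shorter than 5 residues yield an
    empty annotation.
    """
    params = params or HelixDetectorParams()
    if isinstance(structure, CAlphaStructure):
        coords = structure.ca_coords
        res_index = structure.residue_indices
    else:
        coords = np.asarray(structure, dtype=float)
        res_index = np.arange(1, len(coords) + 1)
    n = len(coords)
    helical = np.zeros(n, dtype=bool)
    if n < 5:
        return HelixAnnotation([], helical)

    d13 = np.linalg.norm(coords[3:] - coords[:-3], axis=1)
    d14 = np.linalg.norm(coords[4:] - coords[:-4], axis=1)
    bonds = np.linalg.norm(coords[1:] - coords[:-1], axis=1)
    lo3, hi3 = params.d13_range
    lo4, hi4 = params.d14_range
    lob, hib = params.bond_range
    bond_ok = (bonds >= lob) & (bonds <= hib)
    window_bonds_ok = (
        bond_ok[: n - 4] & bond_ok[1 : n - 3] & bond_ok[2 : n - 2] & bond_ok[3 : n - 1]
    )
    ok = (
        (d13[: n - 4] >= lo3)
        & (d13[: n - 4] <= hi3)
        & (d14 >= lo4)
        & (d14 <= hi4)
        & window_bonds_ok
    )
    # an isolated passing window (no passing neighbour) is treated as noise
    neighbour = np.zeros_like(ok)
    neighbour[1:] |= ok[:-1]
    neighbour[:-1] |= ok[1:]
    keep = ok & (neighbour | (len(ok) == 1))
    for i in np.where(keep)[0]:
        helical[i : i + 5] = True

    segments: list[tuple[str, int, int]] = []
    i = 0
    while i < n:
        if helical[i]:
            j = i
            while j + 1 < n and helical[j + 1]:
                j += 1
            if j - i + 1 >= params.min_segment_len:
                segments.append((f"H{len(segments) + 1}", int(res_index[i]), int(res_index[j])))
            else:
                helical[i : j + 1] = False
            i = j + 1
        else:
            i += 1
    return HelixAnnotation(segments, helical)


# ---------------------------------------------------------------------------
# Synthetic helix bundles
# ---------------------------------------------------------------------------

#: ideal α-helix Cα geometry
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å

_LOOP_BOND = 3.8  # target Cα spacing along loop arcs, Å


def ideal_helix_coords(
    n: int,
    rise: float = HELIX_RISE,
    twist_deg: float = HELIX_TWIST,
    radius: float = HELIX_RADIUS,
    direction: int = +1,
    phase_deg: float = 0.0,
) -> np.ndarray:
    """Cα coordinates of an ideal α-helix along ±z, starting at z = 0."""
    i = np.arange(n)
    phi = np.deg2rad(phase_deg + direction * twist_deg * i)
    z = direction * rise * i
    return np.column_stack([radius * np.cos(phi), radius * np.sin(phi), z])


def _arc_points(a: np.ndarray, b: np.ndarray, n_points: int, arc_len: float,
                bulge_dir: np.ndarray) -> np.ndarray:
    """``n_points`` interior points on a circular arc from ``a`` to ``b``.

    The arc bulges toward ``bulge_dir`` and has total length ``arc_len``
    (falls back to a straight line when the chord is already that long).
    """
    chord_vec = b - a
    c = np.linalg.norm(chord_vec)
    t = np.linspace(0.0, 1.0, n_points + 2)[1:-1]
    if arc_len <= c * (1 + 1e-9) or c < 1e-9:
        return a + np.outer(t, chord_vec)
    # half-angle θ of the arc: arc_len = c·θ/sin(θ)
    theta = brentq(lambda th: math.sin(th) / th - c / arc_len, 1e-9, math.pi - 1e-9)
    radius = c / (2.0 * math.sin(theta))
    chord_hat = chord_vec / c
    n_hat = bulge_dir - np.dot(bulge_dir, chord_hat) * chord_hat
    nn = np.linalg.norm(n_hat)
    if nn < 1e-9:  # bulge parallel to chord: pick any perpendicular
        n_hat = np.cross(chord_hat, [0.0, 0.0, 1.0])
        if np.linalg.norm(n_hat) < 1e-9:
            n_hat = np.cross(chord_hat, [0.0, 1.0, 0.0])
        nn = np.linalg.norm(n_hat)
    n_hat /= nn
    center = (a + b) / 2.0 - n_hat * radius * math.cos(theta)
    u1 = (a - center) / radius
    u2 = (b - center) / radius
    omega = math.acos(np.clip(np.dot(u1, u2), -1.0, 1.0))
    # slerp from u1 to u2 through the bulge side
    w = np.cross(np.cross(u1, u2), u1)
    w /= np.linalg.norm(w)
    ang = t * omega
    pts = center + radius * (np.outer(np.cos(ang), u1) + np.outer(np.sin(ang), w))
    return pts


def _helix_axis_positions(n_helices: int, packing_distance: float) -> np.ndarray:
    """(x, y) axis positions with adjacent-in-chain helices packed at distance."""
    if n_helices == 1:
        return np.zeros((1, 2))
    if n_helices == 2:
        return np.array([[0.0, 0.0], [packing_distance, 0.0]])
    rc = packing_distance / (2.0 * math.sin(math.pi / n_helices))
    ang = 2.0 * math.pi * np.arange(n_helices) / n_helices
    return rc * np.column_stack([np.cos(ang), np.sin(ang)])


def make_helix_bundle(
    n_helices: int,
    helix_len: int,
    loop_len: int = 4,
    packing_distance: float = 10.0,
    seed: int = 0,
    jitter: float = 0.02,
) -> CAlphaStructure:
    """Generate an idealized antiparallel Cα helix bundle.

    Ideal α-helix geometry (rise 1.5 Å/residue, 100°/residue, radius 2.3 Å),
    helix axes packed at ``packing_distance`` (adjacent in chain = adjacent in
    the packing polygon), near-extended arc loops, and fixture-only pseudo
    heavy atoms placed so the 1.24× overlap criterion produces inter-helix
    contacts between packed neighbours as well as i,i+3 / i,i+4 intra-helix
    contacts. Deterministic for a given seed (a small Gaussian jitter breaks
    exact symmetry). Ground-truth helix boundaries are recorded on the
    returned structure.
    """
    if n_helices < 1:
        raise ValueError("n_helices must be ≥ 1")
    if helix_len < 8:
        raise ValueError("helix_len must be ≥ 8")
    if n_helices > 1 and packing_distance < 2.0 * HELIX_RADIUS:
        raise ValueError(
            f"packing_distance {packing_distance} Å < helix diameter "
            f"{2 * HELIX_RADIUS} Å: helices would interpenetrate"
        )

    axes = _helix_axis_positions(n_helices, packing_distance)
    coords_parts: list[np.ndarray] = []
    helix_ranges: list[tuple[int, int]] = []  # 0-based [start, end] inclusive
    helix_dirs: list[int] = []
    z_top = HELIX_RISE * (helix_len - 1)
    offset = 0
    for h in range(n_helices):
        direction = +1 if h % 2 == 0 else -1
        shift = np.array([axes[h, 0], axes[h, 1], 0.0 if direction > 0 else z_top])
        if h == 0:
            helix = ideal_helix_coords(helix_len, direction=direction) + shift
        else:
            # pick the phase that maximizes the loop chord, so connectors stay
            # extended enough not to masquerade as helical turns
            prev_end = coords_parts[-1][-1]
            best, best_chord = None, -1.0
            for phase in range(0, 360, 10):
                cand = ideal_helix_coords(
                    helix_len, direction=direction, phase_deg=float(phase)
                ) + shift
                chord = np.linalg.norm(cand[0] - prev_end)
                if chord > best_chord:
                    best, best_chord = cand, chord
            helix = best
        if h > 0:
            a = coords_parts[-1][-1]
            b = helix[0]
            # loop bulges beyond the helix ends it connects; kept near-extended
            # (arc only 15% longer than the chord) so connectors never look
            # helix-like to the distance-window detector
            bulge = np.array([0.0, 0.0, 1.0 if a[2] > z_top / 2 else -1.0])
            chord = float(np.linalg.norm(b - a))
            arc_len = min((loop_len + 1) * _LOOP_BOND, 1.15 * chord)
            loop = _arc_points(a, b, loop_len, arc_len, bulge)
            coords_parts.append(loop)
            offset += loop_len
        helix_ranges.append((offset, offset + helix_len - 1))
        helix_dirs.append(direction)
        coords_parts.append(helix)
        offset += helix_len

    coords = np.vstack(coords_parts)
    rng = np.random.default_rng(seed)
    coords = coords + rng.normal(0.0, jitter, coords.shape)
    n = len(coords)

    # fixture-only pseudo heavy atoms (see module docs): 2 radial toward the
    # bundle core, 2 axial along the local helix axis / chain tangent
    core_xy = axes.mean(axis=0)
    helix_of = np.full(n, -1, dtype=int)
    for h, (i0, i1) in enumerate(helix_ranges):
        helix_of[i0 : i1 + 1] = h

    residues: list[Residue] = []
    for i in range(n):
        ca = coords[i]
        radial = np.array([core_xy[0] - ca[0], core_xy[1] - ca[1], 0.0])
        rn = np.linalg.norm(radial)
        radial = radial / rn if rn > 1e-9 else np.array([1.0, 0.0, 0.0])
        if helix_of[i] >= 0:
            axial = np.array([0.0, 0.0, float(helix_dirs[helix_of[i]])])
        else:  # loop: local chain tangent
            lo = max(i - 1, 0)
            hi = min(i + 1, n - 1)
            axial = coords[hi] - coords[lo]
            axial = axial / max(np.linalg.norm(axial), 1e-9)
        positions = [
            ca,
            ca + 1.6 * radial,
            ca + 3.2 * radial,
            ca + 2.4 * axial,
            ca - 2.4 * axial,
        ]
        names = ["CA", "CR1", "CR2", "CT1", "CT2"]
        heavy = [
            AtomRecord(i + 1, "ALA", name, "C", pos, VDW_RADII["C"])
            for name, pos in zip(names, positions)
        ]
        residues.append(Residue(i + 1, "ALA", ca, heavy))

    segments = [
        (f"H{h + 1}", i0 + 1, i1 + 1) for h, (i0, i1) in enumerate(helix_ranges)
    ]
    helical = np.zeros(n, dtype=bool)
    for _, s, e in segments:
        helical[s - 1 : e] = True
    out = CAlphaStructure(residues, chain_id="A", source="synthetic")
    out.ground_truth_helices = HelixAnnotation(segments, helical)
    return out
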