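"""Reduced-unit system and conversions to physical units.

Lengths are in Å, energies in ε, times in τ. The energy unit is calibrated
against unfolding experiments to ε = 110 pN·Å, giving ε ≈ 6.62 kJ/mol.
Temperature enters only as kT in units of ε (default 0.3 ε).
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23

#: energy unit in pN·Å (= 1e-22 J)
EPS_PN_ANGSTROM = 110.0

#: 1 ε in kJ/mol
EPS_KJ_PER_MOL = EPS_PN_ANGSTROM * 1e-22 * AVOGADRO / 1000.0  # ≈ 6.624

#: default reduced temperature, kT / ε
DEFAULT_KT = 0.3

#: default integration time step, τ
DEFAULT_DT = 0.005

ANGSTROM_PER_NM = 10.0


def eps_to_kj_per_mol(e: float) -> float:
    """Convert an energy from ε to kJ/mol."""
    return e * EPS_KJ_PER_MOL


def kj_per_mol_to_eps(e: float) -> float:
    """Convert an energy from kJ/mol to ε."""
    return e / EPS_KJ_PER_MOL


def spring_kj_mol_nm2_to_eps_A2(k: float) -> float:
    """Convert a spring constant from kJ/(mol·nm²) to ε/Å².

    Used for physical-unit umbrella constants, e.g. the 2000 kJ/mol·nm⁻²
    umbrella maps to ≈ 3.02 ε/Å².
    """
    return k / EPS_KJ_PER_MOL / ANGSTROM_PER_NM**2


def force_eps_A_to_pN(f: float) -> float:
    """Convert a force from ε/Å to pN."""
    return f * EPS_PN_ANGSTROM
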