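"""Overdamped Langevin (Brownian) dynamics in reduced units.

Thermostat constants follow the coarse-grained protocol: kT = 0.3 ε,
damping γ = 2m/τ, noise dispersion 2γkT, time step 0.005 τ. The integrator
is Euler–Maruyama; its contract is correct Boltzmann statistics, which the
test suite verifies against quadrature oracles.

Two execution paths exist: a compiled kernel for plain dynamics (no external
force) and a python loop accepting an arbitrary ``external_force(positions,
time) -> forces`` callable. Both are deterministic per seed, but use distinct
random streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .go_model import GoTopology

__all__ = [
    "LangevinParams",
    "SimState",
    "PolynomialPotential",
    "step",
    "end_to_end",
    "sample_polynomial_1d",
]


@dataclass
class LangevinParams:
    kT: float = 0.3  # ε
    gamma: float | None = None  # defaults to 2·m/τ
    dt: float = 0.005  # τ
    mass: float = 1.0
    seed: int = 0
    overdamped: bool = True

    def __post_init__(self) -> None:
        if self.gamma is None:
            self.gamma = 2.0 * self.mass
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kT < 0:
            raise ValueError("kT must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not self.overdamped:
            raise NotImplementedError(
                "only the overdamped integrator is provided; BXD velocity "
                "inversion is realized as displacement reflection"
            )

    @property
    def noise_dispersion(self) -> float:
        """Dispersion of the thermal noise, 2·γ·kT."""
        return 2.0 * self.gamma * self.kT


@dataclass
class SimState:
    positions: np.ndarray
    time: float = 0.0
    rng_counter: int = 0  # advances every propagation call

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")

    def copy(self) -> "SimState":
        return SimState(self.positions.copy(), self.time, self.rng_counter)


def derive_seed(base_seed: int, *keys: int) -> int:
    """Stable per-replica / per-box seed derivation (uint32 for the kernels)."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def check_stability(topology: GoTopology, params: LangevinParams) -> None:
    """Warn when the stiffest bond exceeds the Euler–Maruyama stability limit.

    The relative coordinate of a bonded pair carries mobility 2/γ, so
    stability requires bond_k·dt·2/γ < 2.
    """
    import warnings

    if len(topology.bond_i) and topology.bond_k * params.dt * 2.0 / params.gamma >= 2.0:
        warnings.warn(
            f"bond_k = {topology.bond_k} ε/Å² is unstable at dt = {params.dt} τ "
            f"(limit {params.gamma / params.dt:.0f}); reduce dt or bond_k",
            stacklevel=3,
        )


def step(
    state: SimState,
    topology: GoTopology,
    params: LangevinParams,
    n_steps: int,
    external_force=None,
) -> SimState:
    """Advance ``n_steps`` of overdamped dynamics; returns a new state.

    With no ``external_force`` the compiled kernel is used; otherwise a
    python loop adds ``external_force(positions, time)`` each step.
    Raises on numerical blow-up, naming the step index.
    """
    check_stability(topology, params)
    new = state.copy()
    seed = derive_seed(params.seed, state.rng_counter)
    if external_force is None:
        status, at_step = _kernels.run_plain(
            new.positions,
            topology.bond_i, topology.bond_j, topology.bond_r0, topology.bond_k,
            topology.chir_first, topology.chir_c0, topology.chir_inv_norm,
            topology.chirality_k,
            topology.nat_i, topology.nat_j, topology.nat_sigma, topology.epsilon,
            topology.rep_i, topology.rep_j, topology.repulsive_cutoff,
            params.kT, params.gamma, params.dt, seed, n_steps,
        )
        _raise_on_status(status, at_step)
    else:
        from .go_model import energy_forces

        rng = np.random.default_rng(seed)
        mob = params.dt / params.gamma
        amp = np.sqrt(2.0 * params.kT * params.dt / params.gamma)
        pos = new.positions
        for s in range(n_steps):
            _, forces = energy_forces(topology, pos)
            forces = forces + external_force(pos, new.time + s * params.dt)
            pos += forces * mob + amp * rng.standard_normal(pos.shape)
            if s % 200 == 199 and not (
                np.all(np.isfinite(pos)) and np.abs(pos).max() < 1e6
            ):
                raise FloatingPointError(f"numerical blow-up at step {s}")
    new.time = state.time + n_steps * params.dt
    new.rng_counter = state.rng_counter + 1
    return new


def _raise_on_status(status: int, at_step: int) -> None:
    if status == _kernels.OK:
        return
    if status == _kernels.BLOWUP:
        raise FloatingPointError(f"numerical blow-up at step {at_step}")
    if status == _kernels.COINCIDENT:
        raise ValueError(f"coincident beads at step {at_step}")
    raise RuntimeError(f"kernel failure (status {status}) at step {at_step}")


def end_to_end(state_or_positions) -> float:
    """End-to-end distance: first-to-last Cα (the reaction coordinate)."""
    pos = (
        state_or_positions.positions
        if isinstance(state_or_positions, SimState)
        else np.asarray(state_or_positions, dtype=float)
    )
    if len(pos) < 2:
        raise ValueError("need at least two residues")
    return float(np.linalg.norm(pos[-1] - pos[0]))


# ---------------------------------------------------------------------------
# 1D analytic systems (estimator validation)
# ---------------------------------------------------------------------------


@dataclass
class PolynomialPotential:
    """V(x) = Σ c_k x^k given highest-order-first coefficients."""

    coeffs: tuple[float, ...]  # np.polyval convention

    def __call__(self, x):
        return np.polyval(self.coeffs, x)

    @property
    def force_coeffs(self) -> np.ndarray:
        """Highest-first coefficients of −dV/dx (for the kernels)."""
        return -np.polyder(np.asarray(self.coeffs, dtype=float))

    @classmethod
    def harmonic(cls, k: float = 1.0) -> "PolynomialPotential":
        return cls((0.5 * k, 0.0, 0.0))

    @classmethod
    def quartic(cls, a: float = 1.0) -> "PolynomialPotential":
        return cls((a, 0.0, 0.0, 0.0, 0.0))

    @classmethod
    def linear(cls, slope: float) -> "PolynomialPotential":
        return cls((slope, 0.0))


def sample_polynomial_1d(
    potential: PolynomialPotential,
    params: LangevinParams,
    n_steps: int,
    x0: float = 0.0,
    n_equil: int = 0,
    stride: int = 1,
    bias_k: float = 0.0,
    bias_center: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Sample x along overdamped dynamics in a 1D polynomial potential.

    Optionally adds a harmonic bias ½·bias_k·(x − bias_center)² (used by the
    umbrella-sampling validation systems).
    """
    n_samples = (n_steps - n_equil + stride - 1) // stride
    samples = np.empty(max(n_samples, 0))
    kernel_seed = derive_seed(params.seed if seed is None else seed)
    fc = np.ascontiguousarray(potential.force_coeffs, dtype=np.float64)
    _, n_s = _kernels.sample_poly1d(
        float(x0), fc, params.kT, params.gamma, params.dt, kernel_seed,
        n_steps, n_equil, stride, bias_k, bias_center, samples,
    )
    return samples[:n_s]
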