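"""Umbrella sampling along the end-to-end coordinate and a WHAM solver.

Windows carry harmonic biases ½k(rc − c)²; starting states are taken from a
pulling trajectory (frame nearest each center). The weighted-histogram
solver iterates the standard self-consistent equations until the window
offsets converge, and bootstrap resampling provides PMF error bars.
Physical-unit umbrella constants (kJ/mol·nm⁻²) are converted through
ε = 6.62 kJ/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .go_model import GoTopology
from .langevin_engine import LangevinParams, derive_seed
from .pulling_smd import PullingTrajectory
from .units import spring_kj_mol_nm2_to_eps_A2

__all__ = [
    "UmbrellaWindow",
    "WhamResult",
    "seed_windows_from_pulling",
    "run_window",
    "wham",
    "bootstrap_pmf_error",
]


@dataclass
class UmbrellaWindow:
    center: float  # Å
    k_umb: float  # ε/Å²
    samples: np.ndarray = field(default_factory=lambda: np.zeros(0))
    start_positions: np.ndarray | None = None
    final_positions: np.ndarray | None = None  # set by run_window

    def __post_init__(self) -> None:
        if self.k_umb < 0:
            raise ValueError("k_umb must be non-negative")
        self.samples = np.asarray(self.samples, dtype=float)

    @classmethod
    def with_physical_k(cls, center: float, k_kj_mol_nm2: float) -> "UmbrellaWindow":
        """Window from an umbrella constant given in kJ/mol·nm⁻²."""
        return cls(center, spring_kj_mol_nm2_to_eps_A2(k_kj_mol_nm2))

    def bias_energy(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.k_umb * (np.asarray(x) - self.center) ** 2


@dataclass
class WhamResult:
    rc: np.ndarray  # bin centers
    free_energy: np.ndarray  # ε, min-shifted to 0
    window_offsets: np.ndarray  # f_i, ε
    iterations: int
    convergence: float  # max |Δf| at termination
    counts: np.ndarray  # pooled histogram counts per bin

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"rc": self.rc, "free_energy_eps": self.free_energy, "counts": self.counts}
        ).to_csv(path, index=False)


def seed_windows_from_pulling(
    trajectory: PullingTrajectory,
    centers: np.ndarray,
    k_umb: float,
) -> list[UmbrellaWindow]:
    """One window per center, started from the pulling frame whose
    end-to-end distance is closest to it.

    Centers outside the trajectory's achievable range are an error; two
    centers mapping to the same frame produce a warning but both windows.
    """
    if trajectory.frames is None:
        raise ValueError("trajectory stores no frames; rerun with frame_stride > 0")
    ext = trajectory.frame_extensions
    lo, hi = float(ext.min()), float(ext.max())
    windows = []
    used: dict[int, float] = {}
    for c in np.atleast_1d(centers):
        if not (lo <= c <= hi):
            raise ValueError(
                f"window center {c:.2f} Å outside trajectory range "
                f"[{lo:.2f}, {hi:.2f}] Å"
            )
        k = int(np.argmin(np.abs(ext - c)))
        if k in used:
            warnings.warn(
                f"centers {used[k]:.2f} and {c:.2f} Å map to the same frame {k}"
            )
        used[k] = float(c)
        windows.append(
            UmbrellaWindow(float(c), k_umb, start_positions=trajectory.frames[k].copy())
        )
    return windows


def run_window(
    topology: GoTopology,
    window: UmbrellaWindow,
    params: LangevinParams,
    n_steps: int,
    n_equil: int | None = None,
    seed: int = 0,
    sample_stride: int = 10,
) -> UmbrellaWindow:
    """Propagate one biased window and collect rc samples.

    By default the first third of the run is discarded as equilibration
    (mirroring 30 ns windows analysed over their last 20 ns).
    """
    if window.start_positions is None:
        if topology.native_positions is None:
            raise ValueError("window has no start positions")
        window.start_positions = topology.native_positions.copy()
    if n_equil is None:
        n_equil = n_steps // 3
    if window.k_umb * params.dt * 2.0 / params.gamma >= 2.0:
        warnings.warn(
            f"k_umb = {window.k_umb} ε/Å² is unstable at dt = {params.dt} τ "
            f"(limit {params.gamma / params.dt:.0f}); reduce dt",
            stacklevel=2,
        )
    pos = np.ascontiguousarray(window.start_positions, dtype=np.float64).copy()
    cap = (n_steps - n_equil + sample_stride - 1) // sample_stride
    samples = np.zeros(max(cap, 0))
    status, at_step, n_s = _kernels.run_umbrella(
        pos,
        topology.bond_i, topology.bond_j, topology.bond_r0, topology.bond_k,
        topology.chir_first, topology.chir_c0, topology.chir_inv_norm,
        topology.chirality_k,
        topology.nat_i, topology.nat_j, topology.nat_sigma, topology.epsilon,
        topology.rep_i, topology.rep_j, topology.repulsive_cutoff,
        params.kT, params.gamma, params.dt, derive_seed(seed),
        window.k_umb, window.center,
        n_steps, n_equil, sample_stride,
        samples,
    )
    if status != _kernels.OK:
        raise RuntimeError(
            f"window at {window.center:.2f} Å failed (status {status}, "
            f"step {at_step})"
        )
    return UmbrellaWindow(
        window.center, window.k_umb, samples[:n_s], window.start_positions, pos
    )


def _histograms(windows, bin_width):
    all_samples = np.concatenate([w.samples for w in windows])
    lo, hi = all_samples.min(), all_samples.max()
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi + 1e-12)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array(
        [np.histogram(w.samples, bins=edges)[0] for w in windows], dtype=float
    )
    return centers, counts


def wham(
    windows: list[UmbrellaWindow],
    kT: float,
    bin_width: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> WhamResult:
    """Self-consistent WHAM over the windows' rc histograms.

    Adjacent windows (ordered by center) must share at least one occupied
    bin. The returned PMF is −kT·ln p, shifted so its minimum is zero.
    """
    windows = [w for w in windows]
    if not windows or any(len(w.samples) == 0 for w in windows):
        raise ValueError("every window needs samples")
    if bin_width is None:
        centers_sorted = np.sort([w.center for w in windows])
        spacing = np.min(np.diff(centers_sorted)) if len(windows) > 1 else 1.0
        bin_width = max(spacing / 2.0, 1e-6)

    centers, counts = _histograms(windows, bin_width)
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        shared = (counts[a] > 0) & (counts[b] > 0)
        if not np.any(shared):
            raise ValueError(
                f"no histogram overlap between windows at "
                f"{windows[a].center:.2f} and {windows[b].center:.2f} Å"
            )

    n_win = len(windows)
    n_tot = counts.sum(axis=1)  # samples per window
    pooled = counts.sum(axis=0)
    bias = np.array([w.bias_energy(centers) for w in windows])  # (win, bin)
    log_c = -bias / kT

    f = np.zeros(n_win)  # window free-energy offsets, ε
    delta = np.inf
    for it in range(1, max_iter + 1):
        # log denominator per bin: ln Σ_i N_i exp((f_i − U_i(b))/kT)
        log_w = log_c + (f / kT)[:, None] + np.log(n_tot)[:, None]
        m = log_w.max(axis=0)
        log_den = m + np.log(np.exp(log_w - m).sum(axis=0))
        with np.errstate(divide="ignore"):
            log_p = np.where(pooled > 0, np.log(pooled), -np.inf) - log_den
        # f_i = −kT ln Σ_b c_i(b) p(b)
        lw = log_c + log_p
        mm = lw.max(axis=1)
        f_new = -kT * (mm + np.log(np.exp(lw - mm[:, None]).sum(axis=1)))
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations (max|Δf| = {delta:.3g})"
        )

    log_w = log_c + (f / kT)[:, None] + np.log(n_tot)[:, None]
    m = log_w.max(axis=0)
    log_den = m + np.log(np.exp(log_w - m).sum(axis=0))
    with np.errstate(divide="ignore"):
        log_p = np.where(pooled > 0, np.log(pooled), -np.inf) - log_den
    pmf = -kT * log_p
    finite = np.isfinite(pmf)
    pmf = pmf - pmf[finite].min()
    return WhamResult(centers, pmf, f, it, delta, pooled)


def bootstrap_pmf_error(
    windows: list[UmbrellaWindow],
    kT: float,
    n_boot: int = 200,
    bin_width: float | None = None,
    seed: int = 0,
    block: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap standard error of the WHAM PMF per bin.

    Windows are resampled in contiguous blocks of ``block`` samples to
    respect autocorrelation. Profiles are re-anchored to zero mean over
    their common finite support before taking the spread. Returns
    ``(rc_grid, stderr)`` on the same grid as :func:`wham` with the same
    ``bin_width``.
    """
    rng = np.random.default_rng(seed)
    base = wham(windows, kT, bin_width=bin_width)
    profiles = []
    for _ in range(n_boot):
        resampled = []
        for w in windows:
            s = w.samples
            n_blocks = max(len(s) // block, 1)
            starts = rng.integers(0, max(len(s) - block + 1, 1), n_blocks)
            take = np.concatenate([s[st : st + block] for st in starts])
            resampled.append(UmbrellaWindow(w.center, w.k_umb, take))
        try:
            res = wham(resampled, kT, bin_width=bin_width)
        except (ValueError, RuntimeError):
            continue
        # align onto the base grid
        prof = np.interp(base.rc, res.rc, res.free_energy, left=np.nan, right=np.nan)
        finite = np.isfinite(prof) & np.isfinite(base.free_energy)
        if finite.sum() < 2:
            continue
        prof = prof - np.nanmean(prof[finite] - base.free_energy[finite])
        profiles.append(prof)
    if len(profiles) < 10:
        raise RuntimeError("too few successful bootstrap resamples")
    arr = np.array(profiles)
    return base.rc, np.nanstd(arr, axis=0)
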