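"""Constant-velocity pulling with elastic springs on both termini.

One spring anchors the static terminus at its initial position; the other
spring's anchor moves along the initial end-to-end axis at constant
velocity. The recorded force is the instantaneous moving-spring tension
along that axis, and the accumulated pulling work is W(t) = Σ F·v_p·dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import _kernels
from .go_model import GoTopology
from .langevin_engine import LangevinParams, check_stability, derive_seed

__all__ = [
    "PullingProtocol",
    "PullingTrajectory",
    "run_pulling",
    "work_from_force_trace",
    "detect_rupture_peaks",
]

DEFAULT_SPRING_K = 0.12  # ε/Å²
DEFAULT_VELOCITY = 0.005  # Å/τ


@dataclass
class PullingProtocol:
    spring_k: float = DEFAULT_SPRING_K
    velocity: float = DEFAULT_VELOCITY
    pulled_terminus: str = "C"  # the moving spring; the other is anchored
    total_extension: float | None = None  # Å; default 1.05 × contour length

    def __post_init__(self) -> None:
        if self.spring_k <= 0:
            raise ValueError("spring_k must be positive")
        if self.velocity < 0:
            raise ValueError("velocity must be non-negative")
        if self.pulled_terminus not in ("N", "C"):
            raise ValueError("pulled_terminus must be 'N' or 'C'")


@dataclass
class PullingTrajectory:
    """Time series of one pulling replica (+ optional position frames)."""

    time: np.ndarray  # τ
    end_to_end: np.ndarray  # Å
    spring_extension: np.ndarray  # Å, along the pulling axis
    force: np.ndarray  # ε/Å, moving-spring tension
    work: np.ndarray  # ε, accumulated
    seed: int
    frames: np.ndarray | None = None  # (n_frames, n, 3)
    frame_time: np.ndarray | None = None
    axis: np.ndarray | None = None
    final_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("end_to_end", "spring_extension", "force", "work"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {
                "time": self.time,
                "end_to_end": self.end_to_end,
                "spring_extension": self.spring_extension,
                "force": self.force,
                "work": self.work,
            }
        ).to_csv(path, index=False)

    @property
    def frame_extensions(self) -> np.ndarray:
        """End-to-end distance of each stored frame."""
        if self.frames is None:
            raise ValueError("trajectory stores no frames")
        d = self.frames[:, -1, :] - self.frames[:, 0, :]
        return np.linalg.norm(d, axis=1)


def run_pulling(
    topology: GoTopology,
    protocol: PullingProtocol,
    params: LangevinParams,
    seed: int = 0,
    start_positions: np.ndarray | None = None,
    n_steps: int | None = None,
    record_stride: int = 100,
    frame_stride: int = 0,
) -> PullingTrajectory:
    """Run one constant-velocity pulling replica.

    The pulling axis is the initial N→C unit vector (held fixed). The run
    ends when the moving anchor's displacement reaches
    ``protocol.total_extension`` (default 1.05 × contour length), or after
    ``n_steps`` when the velocity is zero.
    """
    if start_positions is None:
        if topology.native_positions is None:
            raise ValueError("no start positions and topology has no native_positions")
        start_positions = topology.native_positions
    check_stability(topology, params)
    pos = np.ascontiguousarray(start_positions, dtype=np.float64).copy()
    n = topology.n_residues
    if pos.shape != (n, 3):
        raise ValueError("start positions inconsistent with topology")

    if protocol.velocity == 0:
        if n_steps is None:
            raise ValueError("n_steps required when velocity is zero")
    elif n_steps is None:
        total_ext = protocol.total_extension
        if total_ext is None:
            total_ext = 1.05 * topology.contour_length
        n_steps = int(np.ceil(total_ext / (protocol.velocity * params.dt)))

    if protocol.pulled_terminus == "C":
        static_idx, moving_idx = 0, n - 1
    else:
        static_idx, moving_idx = n - 1, 0
    axis = pos[n - 1] - pos[0]
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9:
        raise ValueError("termini coincide: pulling axis undefined")
    axis = axis / nrm
    if protocol.pulled_terminus == "N":
        axis = -axis

    n_rec = n_steps // record_stride + 1
    rec = {k: np.zeros(n_rec) for k in ("time", "e2e", "ext", "force", "work")}
    n_frames_cap = (n_steps // frame_stride + 1) if frame_stride > 0 else 0
    frames = np.zeros((n_frames_cap, n, 3))

    kernel_seed = derive_seed(seed)
    status, at_step, n_rec_out, n_frames = _kernels.run_pulling(
        pos,
        topology.bond_i, topology.bond_j, topology.bond_r0, topology.bond_k,
        topology.chir_first, topology.chir_c0, topology.chir_inv_norm,
        topology.chirality_k,
        topology.nat_i, topology.nat_j, topology.nat_sigma, topology.epsilon,
        topology.rep_i, topology.rep_j, topology.repulsive_cutoff,
        params.kT, params.gamma, params.dt, kernel_seed,
        protocol.spring_k, protocol.velocity,
        np.ascontiguousarray(axis),
        static_idx, moving_idx,
        np.ascontiguousarray(pos[static_idx].copy()),
        np.ascontiguousarray(pos[moving_idx].copy()),
        n_steps, record_stride, frame_stride,
        rec["time"], rec["e2e"], rec["ext"], rec["force"], rec["work"],
        frames,
    )
    if status != _kernels.OK:
        raise RuntimeError(
            f"pulling replica (seed {seed}) failed with status {status} "
            f"at step {at_step}"
        )
    sl = slice(0, n_rec_out)
    return PullingTrajectory(
        time=rec["time"][sl],
        end_to_end=rec["e2e"][sl],
        spring_extension=rec["ext"][sl],
        force=rec["force"][sl],
        work=rec["work"][sl],
        seed=seed,
        frames=frames[:n_frames] if frame_stride > 0 else None,
        frame_time=(np.arange(n_frames) * frame_stride * params.dt)
        if frame_stride > 0
        else None,
        axis=axis,
        final_positions=pos,
    )


def work_from_force_trace(
    force: np.ndarray, velocity: float, dt: float
) -> np.ndarray:
    """Accumulated pulling work W(t) = Σ F·v_p·dt.

    ``force`` is the spring tension sampled at uniform ``dt``; entry ``k`` of
    the returned series is the work done over the first ``k + 1`` steps.
    """
    force = np.asarray(force, dtype=float)
    if force.ndim != 1:
        raise ValueError("force trace must be 1D")
    return np.cumsum(force) * velocity * dt


def detect_rupture_peaks(
    extension: np.ndarray,
    force: np.ndarray,
    smoothing_window: int = 1,
    min_prominence: float = 0.5,
) -> list[tuple[float, float]]:
    """Rupture events: prominent maxima of the smoothed force–extension curve.

    Returns ``(extension, peak_force)`` pairs ordered by extension; an empty
    list when nothing exceeds the prominence threshold.
    """
    extension = np.asarray(extension, dtype=float)
    force = np.asarray(force, dtype=float)
    if len(extension) != len(force):
        raise ValueError("extension and force length mismatch")
    if len(force) == 0:
        return []
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        force = np.convolve(force, kernel, mode="same")
    idx, _ = find_peaks(force, prominence=min_prominence)
    order = np.argsort(extension[idx])
    return [(float(extension[i]), float(force[i])) for i in idx[order]]
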