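"""Numba kernels: force evaluation and long Brownian-dynamics loops.

Everything here works in reduced units (Å, ε, τ). The overdamped update is
Euler–Maruyama: dx = F·dt/γ + N(0, 2·kT·dt/γ). Kernels draw their Gaussian
noise from an explicitly seeded xorshift128+ generator (Marsaglia polar
transform) — substantially faster than numba's builtin RNG and bit-stable
across library versions; identical seeds give bit-identical trajectories.
Distribution quality is covered by the Boltzmann-fidelity tests.

A Verlet-style active list over the (static) non-native pair set keeps the
repulsive term O(active pairs): the full pair list is rescanned whenever the
accumulated maximum per-bead displacement could have let a pair enter the
cutoff+skin shell.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SKIN = 2.0  # Å, neighbour-list shell beyond the repulsive cutoff

# status codes returned by kernels
OK = 0
BLOWUP = 1
COINCIDENT = 2
QUOTA_NOT_REACHED = 3
RELEASE_FAILED = 4


# ---------------------------------------------------------------------------
# seeded RNG (xorshift128+ / splitmix64 init / polar Gaussian)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _next_u64(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    state[1] = s1
    return s0 + s1


@njit(cache=True, inline="always")
def _uniform(state):
    # 53-bit mantissa uniform in [0, 1)
    return float(_next_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _init_rng(seed):
    state = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed)
    for k in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        z2 = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z2 = (z2 ^ (z2 >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[k] = z2 ^ (z2 >> np.uint64(31))
    return state


@njit(cache=True)
def _fill_gauss(state, out):
    """Fill a flat array with standard normals (Marsaglia polar method)."""
    i = 0
    nn = out.size
    while i < nn:
        u = 2.0 * _uniform(state) - 1.0
        v = 2.0 * _uniform(state) - 1.0
        r = u * u + v * v
        if r >= 1.0 or r == 0.0:
            continue
        fac = np.sqrt(-2.0 * np.log(r) / r)
        out[i] = u * fac
        i += 1
        if i < nn:
            out[i] = v * fac
            i += 1


@njit(cache=True, inline="always")
def _gauss1(state):
    while True:
        u = 2.0 * _uniform(state) - 1.0
        v = 2.0 * _uniform(state) - 1.0
        r = u * u + v * v
        if 0.0 < r < 1.0:
            return u * np.sqrt(-2.0 * np.log(r) / r)


@njit(cache=True)
def gaussian_sample(seed, n):
    """Standard-normal draws from the kernel RNG (exposed for testing)."""
    state = _init_rng(seed)
    out = np.empty(n)
    _fill_gauss(state, out)
    return out


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------


@njit(cache=True)
def _build_replist(pos, rep_i, rep_j, cutoff_nl2, act_i, act_j):
    n_act = 0
    for k in range(len(rep_i)):
        i = rep_i[k]
        j = rep_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx * dx + dy * dy + dz * dz < cutoff_nl2:
            act_i[n_act] = i
            act_j[n_act] = j
            n_act += 1
    return n_act


@njit(cache=True, fastmath=True)
def _forces_nl(
    pos,
    bond_i, bond_j, bond_r0, bond_k,
    chir_first, chir_c0, chir_inv, chir_k,
    nat_i, nat_j, nat_sig, eps,
    act_i, act_j, n_act, rep_cut,
    f,
):
    """Accumulate Gō-model forces into ``f`` (zeroed here).

    Returns (e_bond, e_chir, e_lj, e_rep, status).
    """
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e_bond = 0.0
    e_chir = 0.0
    e_lj = 0.0
    e_rep = 0.0
    status = OK

    # harmonic bonds
    for k in range(len(bond_i)):
        i = bond_i[k]
        j = bond_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-12:
            status = COINCIDENT
            continue
        r = np.sqrt(r2)
        dr = r - bond_r0[k]
        e_bond += 0.5 * bond_k * dr * dr
        g = -bond_k * dr / r
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz

    # chirality windows: V = ½κ(C − C0)², C = (b1×b2)·b3 / N0
    for k in range(len(chir_first)):
        a = chir_first[k]
        b1x = pos[a + 1, 0] - pos[a, 0]
        b1y = pos[a + 1, 1] - pos[a, 1]
        b1z = pos[a + 1, 2] - pos[a, 2]
        b2x = pos[a + 2, 0] - pos[a + 1, 0]
        b2y = pos[a + 2, 1] - pos[a + 1, 1]
        b2z = pos[a + 2, 2] - pos[a + 1, 2]
        b3x = pos[a + 3, 0] - pos[a + 2, 0]
        b3y = pos[a + 3, 1] - pos[a + 2, 1]
        b3z = pos[a + 3, 2] - pos[a + 2, 2]
        inv = chir_inv[k]
        c23x = b2y * b3z - b2z * b3y
        c23y = b2z * b3x - b2x * b3z
        c23z = b2x * b3y - b2y * b3x
        c31x = b3y * b1z - b3z * b1y
        c31y = b3z * b1x - b3x * b1z
        c31z = b3x * b1y - b3y * b1x
        c12x = b1y * b2z - b1z * b2y
        c12y = b1z * b2x - b1x * b2z
        c12z = b1x * b2y - b1y * b2x
        c_val = (c12x * b3x + c12y * b3y + c12z * b3z) * inv
        dc = c_val - chir_c0[k]
        e_chir += 0.5 * chir_k * dc * dc
        g = chir_k * dc * inv
        f[a, 0] += g * c23x
        f[a, 1] += g * c23y
        f[a, 2] += g * c23z
        f[a + 1, 0] -= g * (c23x - c31x)
        f[a + 1, 1] -= g * (c23y - c31y)
        f[a + 1, 2] -= g * (c23z - c31z)
        f[a + 2, 0] -= g * (c31x - c12x)
        f[a + 2, 1] -= g * (c31y - c12y)
        f[a + 2, 2] -= g * (c31z - c12z)
        f[a + 3, 0] -= g * c12x
        f[a + 3, 1] -= g * c12y
        f[a + 3, 2] -= g * c12z

    # native contacts: full LJ with minimum at native distance
    for k in range(len(nat_i)):
        i = nat_i[k]
        j = nat_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-12:
            status = COINCIDENT
            continue
        s2 = nat_sig[k] * nat_sig[k] / r2
        s6 = s2 * s2 * s2
        s12 = s6 * s6
        e_lj += 4.0 * eps * (s12 - s6)
        g = 24.0 * eps * (2.0 * s12 - s6) / r2
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz

    # non-native pairs: repulsive LJ branch truncated and shifted at rep_cut
    sig6 = rep_cut**6 / 2.0  # σ_rep = rep_cut / 2^(1/6)
    cut2 = rep_cut * rep_cut
    for k in range(n_act):
        i = act_i[k]
        j = act_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut2:
            continue
        if r2 < 1e-12:
            status = COINCIDENT
            continue
        r6 = r2 * r2 * r2
        s6 = sig6 / r6
        s12 = s6 * s6
        e_rep += 4.0 * eps * (s12 - s6) + eps
        g = 24.0 * eps * (2.0 * s12 - s6) / r2
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz

    return e_bond, e_chir, e_lj, e_rep, status


@njit(cache=True)
def forces_full(
    pos,
    bond_i, bond_j, bond_r0, bond_k,
    chir_first, chir_c0, chir_inv, chir_k,
    nat_i, nat_j, nat_sig, eps,
    rep_i, rep_j, rep_cut,
    f,
):
    """Force/energy evaluation over the complete non-native pair list."""
    return _forces_nl(
        pos,
        bond_i, bond_j, bond_r0, bond_k,
        chir_first, chir_c0, chir_inv, chir_k,
        nat_i, nat_j, nat_sig, eps,
        rep_i, rep_j, len(rep_i), rep_cut,
        f,
    )


@njit(cache=True)
def _check_finite(pos):
    n = pos.shape[0]
    for i in range(n):
        for d in range(3):
            v = pos[i, d]
            if not np.isfinite(v) or abs(v) > 1.0e6:
                return False
    return True


# ---------------------------------------------------------------------------
# propagators
# ---------------------------------------------------------------------------


@njit(cache=True)
def run_plain(
    pos,
    bond_i, bond_j, bond_r0, bond_k,
    chir_first, chir_c0, chir_inv, chir_k,
    nat_i, nat_j, nat_sig, eps,
    rep_i, rep_j, rep_cut,
    kT, gamma, dt, seed, n_steps,
):
    """Unrestrained overdamped dynamics for ``n_steps``; modifies ``pos``."""
    state = _init_rng(seed)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    noise = np.empty(3 * n)
    act_i = np.empty(len(rep_i), dtype=np.int64)
    act_j = np.empty(len(rep_i), dtype=np.int64)
    cutoff_nl2 = (rep_cut + _SKIN) ** 2
    n_act = _build_replist(pos, rep_i, rep_j, cutoff_nl2, act_i, act_j)
    disp = 0.0
    mob = dt / gamma
    amp = np.sqrt(2.0 * kT * dt / gamma)
    for step in range(n_steps):
        if disp > 0.5 * _SKIN:
            n_act = _build_replist(pos, rep_i, rep_j, cutoff_nl2, act_i, act_j)
            disp = 0.0
        eb, ec, el, er, status = _forces_nl(
            pos,
            bond_i, bond_j, bond_r0, bond_k,
            chir_first, chir_c0, chir_inv, chir_k,
            nat_i, nat_j, nat_sig, eps,
            act_i, act_j, n_act, rep_cut,
            f,
        )
        if status != OK:
            return status, step
        _fill_gauss(state, noise)
        max_d2 = 0.0
        for i in range(n):
            ddx = f[i, 0] * mob + amp * noise[3 * i]
            ddy = f[i, 1] * mob + amp * noise[3 * i + 1]
            ddz = f[i, 2] * mob + amp * noise[3 * i + 2]
            pos[i, 0] += ddx
            pos[i, 1] += ddy
            pos[i, 2] += ddz
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 > max_d2:
                max_d2 = d2
        disp += np.sqrt(max_d2)
        if step % 200 == 199 and not _check_finite(pos):
            return BLOWUP, step
    return OK, n_steps


@njit(cache=True)
def run_pulling(
    pos,
    bond_i, bond_j, bond_r0, bond_k,
    chir_first, chir_c0, chir_inv, chir_k,
    nat_i, nat_j, nat_sig, eps,
    rep_i, rep_j, rep_cut,
    kT, gamma, dt, seed,
    spring_k, vel, axis, static_idx, moving_idx,
    anchor_static, anchor_move0,
    n_steps, record_stride, frame_stride,
    rec_time, rec_e2e, rec_ext, rec_force, rec_work,
    frames,
):
    """Constant-velocity pulling with springs on both termini.

    The static terminus is tethered to its initial position; the moving
    anchor travels along ``axis`` at ``vel``. Records (time, end-to-end,
    spring extension along the axis, spring tension, accumulated work) every
    ``record_stride`` steps and position frames every ``frame_stride`` steps.
    Returns (status, step, n_records, n_frames).
    """
    state = _init_rng(seed)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    noise = np.empty(3 * n)
    act_i = np.empty(len(rep_i), dtype=np.int64)
    act_j = np.empty(len(rep_i), dtype=np.int64)
    cutoff_nl2 = (rep_cut + _SKIN) ** 2
    n_act = _build_replist(pos, rep_i, rep_j, cutoff_nl2, act_i, act_j)
    disp = 0.0
    mob = dt / gamma
    amp = np.sqrt(2.0 * kT * dt / gamma)
    work = 0.0
    n_rec = 0
    n_frames = 0
    for step in range(n_steps):
        if disp > 0.5 * _SKIN:
            n_act = _build_replist(pos, rep_i, rep_j, cutoff_nl2, act_i, act_j)
            disp = 0.0
        eb, ec, el, er, status = _forces_nl(
            pos,
            bond_i, bond_j, bond_r0, bond_k,
            chir_first, chir_c0, chir_inv, chir_k,
            nat_i, nat_j, nat_sig, eps,
            act_i, act_j, n_act, rep_cut,
            f,
        )
        if status != OK:
            return status, step, n_rec, n_frames
        t = step * dt
        amx = anchor_move0[0] + axis[0] * vel * t
        amy = anchor_move0[1] + axis[1] * vel * t
        amz = anchor_move0[2] + axis[2] * vel * t
        dx = amx - pos[moving_idx, 0]
        dy = amy - pos[moving_idx, 1]
        dz = amz - pos[moving_idx, 2]
        f[moving_idx, 0] += spring_k * dx
        f[moving_idx, 1] += spring_k * dy
        f[moving_idx, 2] += spring_k * dz
        ext = dx * axis[0] + dy * axis[1] + dz * axis[2]
        tension = spring_k * ext
        sx = anchor_static[0] - pos[static_idx, 0]
        sy = anchor_static[1] - pos[static_idx, 1]
        sz = anchor_static[2] - pos[static_idx, 2]
        f[static_idx, 0] += spring_k * sx
        f[static_idx, 1] += spring_k * sy
        f[static_idx, 2] += spring_k * sz

        if step % record_stride == 0 and n_rec < len(rec_time):
            ex = pos[n - 1, 0] - pos[0, 0]
            ey = pos[n - 1, 1] - pos[0, 1]
            ez = pos[n - 1, 2] - pos[0, 2]
            rec_time[n_rec] = t
            rec_e2e[n_rec] = np.sqrt(ex * ex + ey * ey + ez * ez)
            rec_ext[n_rec] = ext
            rec_force[n_rec] = tension
            rec_work[n_rec] = work
            n_rec += 1
        if frame_stride > 0 and step % frame_stride == 0 and n_frames < frames.shape[0]:
            for i in range(n):
                frames[n_frames, i, 0] = pos[i, 0]
                frames[n_frames, i, 1] = pos[i, 1]
                frames[n_frames, i, 2] = pos[i, 2]
            n_frames += 1

        work += tension * vel * dt
        _fill_gauss(state, noise)
        max_d2 = 0.0
        for i in range(n):
            ddx = f[i, 0] * mob + amp * noise[3 * i]
            ddy = f[i, 1] * mob + amp * noise[3 * i + 1]
            ddz = f[i, 2] * mob + amp * noise[3 * i + 2]
            pos[i, 0] += ddx
            pos[i, 1] += ddy
            pos[i, 2] += ddz
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 > max_d2:
                max_d2 = d2
        disp += np.sqrt(max_d2)
        if step % 200 == 199 and not _check_finite(pos):
            return BLOWUP, step, n_rec, n_frames
    return OK, n_steps, n_rec, n_frames


@njit(cache=True)
def run_umbrella(
    pos,
    bond_i, bond_j, bond_r0, bond_k,
    chir_first, chir_c0, chir_inv, chir_k,
    nat_i, nat_j, nat_sig, eps,
    rep_i, rep_j, rep_cut,
    kT, gamma, dt, seed,
    k_umb, center,
    n_steps, n_equil, sample_stride,
    samples,
):
    """Umbrella-biased dynamics on the end-to-end coordinate.

    Applies ½·k_umb·(rc − center)² through forces on the terminal beads and
    collects rc samples every ``sample_stride`` steps after ``n_equil``.
    Returns (status, step, n_samples).
    """
    state = _init_rng(seed)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    noise = np.empty(3 * n)
    act_i = np.empty(len(rep_i), dtype=np.int64)
    act_j = np.empty(len(rep_i), dtype=np.int64)
    cutoff_nl2 = (rep_cut + _SKIN) ** 2
    n_act = _build_replist(pos, rep_i, rep_j, cutoff_nl2, act_i, act_j)
    disp = 0.0
    mob = dt / gamma
    amp = np.sqrt(2.0 * kT * dt / gamma)
    n_s = 0
    for step in range(n_steps):
        if disp > 0.5 * _SKIN:
            n_act = _build_replist(pos, rep_i, rep_j, cutoff_nl2, act_i, act_j)
            disp = 0.0
        eb, ec, el, er, status = _forces_nl(
            pos,
            bond_i, bond_j, bond_r0, bond_k,
            chir_first, chir_c0, chir_inv, chir_k,
            nat_i, nat_j, nat_sig, eps,
            act_i, act_j, n_act, rep_cut,
            f,
        )
        if status != OK:
            return status, step, n_s
        ex = pos[n - 1, 0] - pos[0, 0]
        ey = pos[n - 1, 1] - pos[0, 1]
        ez = pos[n - 1, 2] - pos[0, 2]
        rc = np.sqrt(ex * ex + ey * ey + ez * ez)
        if rc > 1e-9:
            g = -k_umb * (rc - center) / rc
            f[n - 1, 0] += g * ex
            f[n - 1, 1] += g * ey
            f[n - 1, 2] += g * ez
            f[0, 0] -= g * ex
            f[0, 1] -= g * ey
            f[0, 2] -= g * ez
        if step >= n_equil and (step - n_equil) % sample_stride == 0 and n_s < len(samples):
            samples[n_s] = rc
            n_s += 1
        _fill_gauss(state, noise)
        max_d2 = 0.0
        for i in range(n):
            ddx = f[i, 0] * mob + amp * noise[3 * i]
            ddy = f[i, 1] * mob + amp * noise[3 * i + 1]
            ddz = f[i, 2] * mob + amp * noise[3 * i + 2]
            pos[i, 0] += ddx
            pos[i, 1] += ddy
            pos[i, 2] += ddz
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 > max_d2:
                max_d2 = d2
        disp += np.sqrt(max_d2)
        if step % 200 == 199 and not _check_finite(pos):
            return BLOWUP, step, n_s
    return OK, n_steps, n_s


@njit(cache=True)
def run_bxd_box(
    pos,
    bond_i, bond_j, bond_r0, bond_k,
    chir_first, chir_c0, chir_inv, chir_k,
    nat_i, nat_j, nat_sig, eps,
    rep_i, rep_j, rep_cut,
    kT, gamma, dt, seed,
    lo, hi, n_events, min_steps, max_steps, do_release,
    hit_wall, hit_time,
):
    """One BXD box on the coarse-grained system, rc = end-to-end distance.

    A proposed move whose rc crosses a wall counts as a hit and is mirrored
    about the wall along the reaction coordinate (overdamped velocity
    inversion). Statistics collection ends once ``n_events`` hits AND
    ``min_steps`` steps have accumulated; the trajectory is then released
    through the upper wall (still reflecting at the lower one) when
    ``do_release``. The first ``len(hit_wall)`` hits are logged; the
    returned counts cover all hits. Returns (status, n_up, n_down,
    residence_time, n_steps_used).
    """
    state = _init_rng(seed)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    noise = np.empty(3 * n)
    act_i = np.empty(len(rep_i), dtype=np.int64)
    act_j = np.empty(len(rep_i), dtype=np.int64)
    cutoff_nl2 = (rep_cut + _SKIN) ** 2
    n_act = _build_replist(pos, rep_i, rep_j, cutoff_nl2, act_i, act_j)
    disp = 0.0
    mob = dt / gamma
    amp = np.sqrt(2.0 * kT * dt / gamma)
    n_up = 0
    n_down = 0
    releasing = False
    residence = 0.0
    step = 0
    while step < max_steps:
        if disp > 0.5 * _SKIN:
            n_act = _build_replist(pos, rep_i, rep_j, cutoff_nl2, act_i, act_j)
            disp = 0.0
        eb, ec, el, er, status = _forces_nl(
            pos,
            bond_i, bond_j, bond_r0, bond_k,
            chir_first, chir_c0, chir_inv, chir_k,
            nat_i, nat_j, nat_sig, eps,
            act_i, act_j, n_act, rep_cut,
            f,
        )
        if status != OK:
            return status, n_up, n_down, step * dt, step
        ex = pos[n - 1, 0] - pos[0, 0]
        ey = pos[n - 1, 1] - pos[0, 1]
        ez = pos[n - 1, 2] - pos[0, 2]
        rc = np.sqrt(ex * ex + ey * ey + ez * ez)
        ux = ex / rc
        uy = ey / rc
        uz = ez / rc
        _fill_gauss(state, noise)
        d0x = f[0, 0] * mob + amp * noise[0]
        d0y = f[0, 1] * mob + amp * noise[1]
        d0z = f[0, 2] * mob + amp * noise[2]
        dNx = f[n - 1, 0] * mob + amp * noise[3 * (n - 1)]
        dNy = f[n - 1, 1] * mob + amp * noise[3 * (n - 1) + 1]
        dNz = f[n - 1, 2] * mob + amp * noise[3 * (n - 1) + 2]
        nex = ex + dNx - d0x
        ney = ey + dNy - d0y
        nez = ez + dNz - d0z
        rc_new = np.sqrt(nex * nex + ney * ney + nez * nez)
        crossed_up = rc_new >= hi
        crossed_lo = rc_new < lo
        if (crossed_up or crossed_lo) and not (releasing and crossed_up):
            if not releasing:
                n_rec = n_up + n_down
                if n_rec < len(hit_wall):
                    hit_wall[n_rec] = 1 if crossed_up else -1
                    hit_time[n_rec] = step * dt
                if crossed_up:
                    n_up += 1
                else:
                    n_down += 1
            # mirror the rc-component of the move about the wall: rescale the
            # proposed end-to-end vector to length 2·wall − rc_new, sharing
            # the correction equally between the two terminal beads
            wall = hi if crossed_up else lo
            rc_ref = 2.0 * wall - rc_new
            if rc_ref > 0.1 and rc_new > 1e-9 and lo <= rc_ref and (rc_ref < hi or releasing):
                scale = rc_ref / rc_new
                cx = 0.5 * (scale - 1.0) * nex
                cy = 0.5 * (scale - 1.0) * ney
                cz = 0.5 * (scale - 1.0) * nez
                d0x -= cx
                d0y -= cy
                d0z -= cz
                dNx += cx
                dNy += cy
                dNz += cz
            else:
                # mirrored move still outside: reject terminal moves
                d0x = d0y = d0z = 0.0
                dNx = dNy = dNz = 0.0
        max_d2 = 0.0
        for i in range(n):
            if i == 0:
                ddx, ddy, ddz = d0x, d0y, d0z
            elif i == n - 1:
                ddx, ddy, ddz = dNx, dNy, dNz
            else:
                ddx = f[i, 0] * mob + amp * noise[3 * i]
                ddy = f[i, 1] * mob + amp * noise[3 * i + 1]
                ddz = f[i, 2] * mob + amp * noise[3 * i + 2]
            pos[i, 0] += ddx
            pos[i, 1] += ddy
            pos[i, 2] += ddz
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 > max_d2:
                max_d2 = d2
        disp += np.sqrt(max_d2)
        step += 1
        if step % 200 == 0 and not _check_finite(pos):
            return BLOWUP, n_up, n_down, step * dt, step
        if not releasing and (n_up + n_down) >= n_events and step >= min_steps:
            residence = step * dt
            if not do_release:
                return OK, n_up, n_down, residence, step
            releasing = True
        if releasing:
            ex = pos[n - 1, 0] - pos[0, 0]
            ey = pos[n - 1, 1] - pos[0, 1]
            ez = pos[n - 1, 2] - pos[0, 2]
            if np.sqrt(ex * ex + ey * ey + ez * ez) >= hi:
                return OK, n_up, n_down, residence, step
    if releasing:
        return RELEASE_FAILED, n_up, n_down, residence, step
    return QUOTA_NOT_REACHED, n_up, n_down, step * dt, step


# ---------------------------------------------------------------------------
# 1D polynomial systems
# ---------------------------------------------------------------------------


@njit(cache=True)
def _polyval(coeffs, x):
    v = 0.0
    for c in coeffs:
        v = v * x + c
    return v


@njit(cache=True)
def sample_poly1d(
    x0, force_coeffs, kT, gamma, dt, seed,
    n_steps, n_equil, stride, bias_k, bias_c,
    samples,
):
    """Overdamped 1D dynamics in a polynomial potential (+ optional bias).

    ``force_coeffs`` are highest-first coefficients of −dV/dx. Returns
    (final_x, n_samples).
    """
    state = _init_rng(seed)
    x = x0
    mob = dt / gamma
    amp = np.sqrt(2.0 * kT * dt / gamma)
    n_s = 0
    for step in range(n_steps):
        fval = _polyval(force_coeffs, x) - bias_k * (x - bias_c)
        if step >= n_equil and (step - n_equil) % stride == 0 and n_s < len(samples):
            samples[n_s] = x
            n_s += 1
        x += fval * mob + amp * _gauss1(state)
    return x, n_s


@njit(cache=True)
def run_bxd_box_1d(
    x0, force_coeffs, kT, gamma, dt, seed,
    lo, hi, n_events, min_steps, max_steps, do_release,
    hit_wall, hit_time,
):
    """One BXD box for a 1D polynomial system; see :func:`run_bxd_box`.

    Returns (status, final_x, n_up, n_down, residence_time, n_steps_used).
    """
    state = _init_rng(seed)
    x = x0
    mob = dt / gamma
    amp = np.sqrt(2.0 * kT * dt / gamma)
    n_up = 0
    n_down = 0
    releasing = False
    residence = 0.0
    step = 0
    while step < max_steps:
        fval = _polyval(force_coeffs, x)
        dxp = fval * mob + amp * _gauss1(state)
        xn = x + dxp
        crossed_up = xn >= hi
        crossed_lo = xn < lo
        if (crossed_up or crossed_lo) and not (releasing and crossed_up):
            if not releasing:
                n_rec = n_up + n_down
                if n_rec < len(hit_wall):
                    hit_wall[n_rec] = 1 if crossed_up else -1
                    hit_time[n_rec] = step * dt
                if crossed_up:
                    n_up += 1
                else:
                    n_down += 1
            # mirror the crossing point back about the wall
            xr = 2.0 * hi - xn if crossed_up else 2.0 * lo - xn
            if lo <= xr and (xr < hi or releasing):
                x = xr
            # else reject: x unchanged
        else:
            x = xn
        step += 1
        if not releasing and (n_up + n_down) >= n_events and step >= min_steps:
            residence = step * dt
            if not do_release:
                return OK, x, n_up, n_down, residence, step
            releasing = True
        if releasing and x >= hi:
            return OK, x, n_up, n_down, residence, step
    if releasing:
        return RELEASE_FAILED, x, n_up, n_down, residence, step
    return QUOTA_NOT_REACHED, x, n_up, n_down, step * dt, step
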