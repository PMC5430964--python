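"""Numba kernels for the Langevin bead-spring integrator.

All kernels work on plain float64 arrays; the user-facing API lives in
:mod:`traphop.simulation`.  Status codes returned by the force/integration
kernels: 0 = ok, 1 = bond length >= r_o (FENE blow-up), 2 = bead inside a
post, 3 = non-finite coordinate.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_BOND = 1
STATUS_OVERLAP = 2
STATUS_NONFINITE = 3

_WCA_CUT = 2.0 ** (1.0 / 6.0)


@njit(cache=True)
def bonded_forces_energy(pos, f, k_s, r_o, sigma, k_B_T, printed_fene):
    """FENE + WCA forces between bonded neighbours.  Adds into ``f``.

    Returns (energy, status, bad_bond_index).
    """
    n = pos.shape[0]
    energy = 0.0
    wca_cut = _WCA_CUT * sigma
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= r_o:
            return energy, STATUS_BOND, i
        if printed_fene:
            # literal printed form: -(k_s r_o^2 / 2) ln(1 - r/r_o)
            dudr = 0.5 * k_s * r_o / (1.0 - r / r_o)
            energy += -0.5 * k_s * r_o * r_o * np.log(1.0 - r / r_o)
        else:
            # Kremer-Grest form: -(k_s r_o^2 / 2) ln(1 - (r/r_o)^2)
            x2 = (r / r_o) * (r / r_o)
            dudr = k_s * r / (1.0 - x2)
            energy += -0.5 * k_s * r_o * r_o * np.log(1.0 - x2)
        if r < wca_cut:
            sr2 = (sigma / r) * (sigma / r)
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            dudr += -(48.0 / r) * (sr12 - 0.5 * sr6)
            energy += 4.0 * (sr12 - sr6) + 1.0
        # energies/forces are in units of k_B_T per the model definition
        scale = k_B_T * dudr / r
        fx = scale * dx
        fy = scale * dy
        fz = scale * dz
        f[i, 0] += fx
        f[i, 1] += fy
        f[i, 2] += fz
        f[i + 1, 0] -= fx
        f[i + 1, 1] -= fy
        f[i + 1, 2] -= fz
    return energy * k_B_T, STATUS_OK, -1


@njit(cache=True)
def post_forces_energy(pos, f, post_xy, box, R, eps, r_cutoff, sigma, k_B_T):
    """Shifted Lennard-Jones bead-post forces (in-plane, minimum image).

    The potential acts on the surface separation s = r - R where r is the
    in-plane distance to the post axis; it is shifted by its cutoff value so
    energy (and the bead-post interaction) is continuous at s = r_cutoff.
    Adds into ``f``; returns (energy, status, bad_bead_index).
    """
    n = pos.shape[0]
    m = post_xy.shape[0]
    energy = 0.0
    src = sigma / r_cutoff
    src6 = src**6
    shift = 4.0 * eps * (src6 * src6 - src6)
    for i in range(n):
        for j in range(m):
            dx = pos[i, 0] - post_xy[j, 0]
            dy = pos[i, 1] - post_xy[j, 1]
            dx -= box[0] * np.round(dx / box[0])
            dy -= box[1] * np.round(dy / box[1])
            r = np.sqrt(dx * dx + dy * dy)
            if r <= R:
                return energy, STATUS_OVERLAP, i
            s = r - R
            if s < r_cutoff:
                ss = sigma / s
                ss6 = ss**6
                ss12 = ss6 * ss6
                energy += 4.0 * eps * (ss12 - ss6) - shift
                dudr = -(4.0 * eps / s) * (12.0 * ss12 - 6.0 * ss6)
                scale = -k_B_T * dudr / r
                f[i, 0] += scale * dx
                f[i, 1] += scale * dy
    return energy * k_B_T, STATUS_OK, -1


@njit(cache=True)
def total_forces(pos, f, k_s, r_o, sigma, k_B_T, printed_fene,
                 has_posts, post_xy, box, R, eps, r_cutoff):
    f[:] = 0.0
    e_b, status, idx = bonded_forces_energy(pos, f, k_s, r_o, sigma, k_B_T, printed_fene)
    if status != STATUS_OK:
        return e_b, status, idx
    e_p = 0.0
    if has_posts:
        e_p, status, idx = post_forces_energy(
            pos, f, post_xy, box, R, eps, r_cutoff, sigma, k_B_T
        )
        if status != STATUS_OK:
            return e_b + e_p, status, idx
    return e_b + e_p, STATUS_OK, -1


@njit(cache=True)
def reflect_walls(pos, vel, H):
    """Specular reflection at z = 0 and z = H (position mirror, v_z negated)."""
    n = pos.shape[0]
    for i in range(n):
        z = pos[i, 2]
        # repeated fold handles (rare) multi-crossing in one step
        for _ in range(8):
            if z < 0.0:
                z = -z
                vel[i, 2] = -vel[i, 2]
            elif z > H:
                z = 2.0 * H - z
                vel[i, 2] = -vel[i, 2]
            else:
                break
        pos[i, 2] = z


@njit(cache=True)
def com_and_rg(pos):
    """In-plane COM and projected radius of gyration of (unwrapped) positions."""
    n = pos.shape[0]
    cx = 0.0
    cy = 0.0
    for i in range(n):
        cx += pos[i, 0]
        cy += pos[i, 1]
    cx /= n
    cy /= n
    s = 0.0
    for i in range(n):
        dx = pos[i, 0] - cx
        dy = pos[i, 1] - cy
        s += dx * dx + dy * dy
    return cx, cy, np.sqrt(s / n)


@njit(cache=True)
def integrate(pos, vel, n_steps, sample_every, dt, mass, gamma, k_B_T,
              k_s, r_o, sigma, printed_fene,
              has_posts, post_xy, box, R, eps, r_cutoff,
              has_walls, H, seed, random_forces, uniform_kick,
              snap_every, snapshots):
    """Velocity-Verlet Langevin integration with sampling.

    The total force is f_int + f_fric + f_R with friction -m*gamma*v and a
    random force of zero mean and per-component std (2 m gamma k_B_T /
    dt)^(1/2) redrawn every step — Gaussian by default, or uniform with the
    same variance when ``uniform_kick`` (the velocity distribution stays
    Maxwellian because each velocity integrates ~1/(gamma*dt) kicks).
    Samples (in-plane COM, projected Rg, total energy, min/max z, max bond
    length) are recorded every ``sample_every`` steps.

    Returns (com, rg, energy, times, zmin, zmax, maxbond, status, bad_index,
    bad_step, n_sampled, n_snapped).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_samp = n_steps // sample_every
    com = np.zeros((n_samp, 2))
    rg = np.zeros(n_samp)
    energy = np.zeros(n_samp)
    times = np.zeros(n_samp)
    zmin = np.zeros(n_samp)
    zmax = np.zeros(n_samp)
    maxbond = np.zeros(n_samp)

    f = np.zeros((n, 3))
    fr = np.zeros((n, 3))
    std = np.sqrt(2.0 * mass * gamma * k_B_T / dt)
    ustd = std * np.sqrt(12.0)  # uniform on [-1/2, 1/2) has variance 1/12
    if random_forces:
        if uniform_kick:
            for i in range(n):
                for k in range(3):
                    fr[i, k] = ustd * (np.random.random() - 0.5)
        else:
            for i in range(n):
                for k in range(3):
                    fr[i, k] = std * np.random.standard_normal()

    e_pot, status, idx = total_forces(
        pos, f, k_s, r_o, sigma, k_B_T, printed_fene,
        has_posts, post_xy, box, R, eps, r_cutoff
    )
    if status != STATUS_OK:
        return com, rg, energy, times, zmin, zmax, maxbond, status, idx, 0, 0, 0

    half = 0.5 * dt
    isamp = 0
    isnap = 0
    for step in range(n_steps):
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * ((f[i, k] + fr[i, k]) / mass - gamma * vel[i, k])
        for i in range(n):
            for k in range(3):
                pos[i, k] += dt * vel[i, k]
        if has_walls:
            reflect_walls(pos, vel, H)
        e_pot, status, idx = total_forces(
            pos, f, k_s, r_o, sigma, k_B_T, printed_fene,
            has_posts, post_xy, box, R, eps, r_cutoff
        )
        if status != STATUS_OK:
            return (com, rg, energy, times, zmin, zmax, maxbond,
                    status, idx, step, isamp, isnap)
        if random_forces:
            if uniform_kick:
                for i in range(n):
                    for k in range(3):
                        fr[i, k] = ustd * (np.random.random() - 0.5)
            else:
                for i in range(n):
                    for k in range(3):
                        fr[i, k] = std * np.random.standard_normal()
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * ((f[i, k] + fr[i, k]) / mass - gamma * vel[i, k])
        if not np.isfinite(pos[0, 0]):
            return (com, rg, energy, times, zmin, zmax, maxbond,
                    STATUS_NONFINITE, 0, step, isamp, isnap)

        if (step + 1) % sample_every == 0 and isamp < n_samp:
            cx, cy, r_gyr = com_and_rg(pos)
            com[isamp, 0] = cx
            com[isamp, 1] = cy
            rg[isamp] = r_gyr
            e_kin = 0.0
            for i in range(n):
                for k in range(3):
                    e_kin += 0.5 * mass * vel[i, k] * vel[i, k]
            energy[isamp] = e_pot + e_kin
            times[isamp] = (step + 1) * dt
            zlo = pos[0, 2]
            zhi = pos[0, 2]
            mb = 0.0
            for i in range(n):
                if pos[i, 2] < zlo:
                    zlo = pos[i, 2]
                if pos[i, 2] > zhi:
                    zhi = pos[i, 2]
                if i < n - 1:
                    dx = pos[i + 1, 0] - pos[i, 0]
                    dy = pos[i + 1, 1] - pos[i, 1]
                    dz = pos[i + 1, 2] - pos[i, 2]
                    b = np.sqrt(dx * dx + dy * dy + dz * dz)
                    if b > mb:
                        mb = b
            zmin[isamp] = zlo
            zmax[isamp] = zhi
            maxbond[isamp] = mb
            isamp += 1
        if snap_every > 0 and (step + 1) % snap_every == 0 and isnap < snapshots.shape[0]:
            snapshots[isnap] = pos
            isnap += 1
    return com, rg, energy, times, zmin, zmax, maxbond, STATUS_OK, -1, n_steps, isamp, isnap
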