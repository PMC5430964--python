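"""Langevin dynamics of a Gaussian FENE bead-spring chain in a post array.

The chain is ideal (non-bonded beads do not interact); bonded neighbours
interact through a FENE spring plus a WCA repulsion.  Posts are z-invariant
cylinders that attract (or repel) beads through a shifted Lennard-Jones
potential acting on the in-plane surface separation; the slit confines the
chain between reflective walls at z = 0 and z = H.  Beads follow the Langevin
equation m dv/dt = f_int - m*gamma*v + f_R integrated with velocity Verlet.

Units: sigma (bead diameter) = length, k_B*T = energy, bead mass m = mass.
The single-bead diffusivity is D_0 = k_B*T/(m*gamma) and the diffusion time
t_D = sigma^2/D_0 is the natural time unit for observables (D_0 = 10 and
t_D = 0.1 at the default parameters).  Trajectory samples are reported with
times in t_D so diffusivities come out in sigma^2/t_D.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernels as K
from .analysis import ComTrajectory
from .geometry import PostArrayGeometry, nearest_post_distance


class IntegrationError(RuntimeError):
    """Raised when the integrator detects a blow-up (overstretched bond,
    bead-post overlap, or non-finite coordinates)."""


@dataclass(frozen=True)
class SimConfig:
    """All parameters of the Langevin chain model.

    Defaults are the model parameters of the study system: a 160-bead Gaussian
    chain with FENE springs (k_s = 30 kT/sigma^2, r_o = 1.5 sigma), friction
    gamma = 0.1, timestep dt = 0.1 t_D = 0.01 time units, and bead-post
    attraction of strength epsilon (kT) cut off 2.5 sigma beyond the post
    surface (1.12 sigma for purely repulsive posts).
    """

    n_beads: int = 160
    k_s: float = 30.0
    r_o: float = 1.5
    sigma: float = 1.0
    k_B_T: float = 1.0
    mass: float = 1.0
    gamma: float = 0.1
    dt: float = 0.01
    epsilon: float = 1.0
    r_cutoff: float = 2.5
    geometry: Optional[PostArrayGeometry] = None
    seed: int = 0
    n_steps_total: int = 100_000
    n_steps_equil: int = 0
    sample_every: int = 100
    snapshot_every: int = 0
    printed_fene: bool = False
    random_forces: bool = True
    kick: str = "gaussian"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.r_cutoff <= 0:
            raise ValueError("r_cutoff must be positive")
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if self.kick not in ("gaussian", "uniform"):
            raise ValueError("kick must be 'gaussian' or 'uniform'")

    @property
    def D_0(self) -> float:
        """Single-bead diffusivity k_B T / (m gamma)."""
        return self.k_B_T / (self.mass * self.gamma)

    @property
    def t_D(self) -> float:
        """Bead diffusion time sigma^2 / D_0."""
        return self.sigma**2 / self.D_0

    @property
    def repulsive(self) -> bool:
        """True when the cutoff truncates the well (r_cutoff <= 2^(1/6) sigma)."""
        return self.r_cutoff <= 2.0 ** (1.0 / 6.0) * self.sigma


@dataclass
class ChainState:
    """Bead positions/velocities (n_beads x 3, sigma and sigma/time units)."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0

    def copy(self) -> "ChainState":
        return ChainState(self.positions.copy(), self.velocities.copy(), self.time)


@dataclass
class SimTrace:
    """Sampled observables of one simulation trial.

    ``times`` are in t_D; ``com_samples`` is the unwrapped in-plane COM track
    (sigma); ``rg_samples`` the projected radius of gyration (sigma).
    """

    times: np.ndarray
    com_samples: np.ndarray
    rg_samples: np.ndarray
    energy_samples: np.ndarray
    zmin_samples: np.ndarray
    zmax_samples: np.ndarray
    maxbond_samples: np.ndarray
    config: SimConfig
    snapshots: Optional[np.ndarray] = None
    trial_index: int = 0

    @property
    def com_track(self) -> ComTrajectory:
        """COM track as a ComTrajectory (times in t_D, lengths in sigma)."""
        return ComTrajectory(times=self.times, xy=self.com_samples, units="simulation")


def _geometry_arrays(config: SimConfig):
    geo = config.geometry
    if geo is None:
        return (False, np.zeros((1, 2)), np.array([1.0, 1.0]), 0.0, False, 0.0)
    return (
        True,
        np.ascontiguousarray(geo.post_centers, dtype=float),
        np.asarray(geo.box, dtype=float),
        float(geo.post_radius_R),
        True,
        float(geo.slit_height_H),
    )


def bonded_forces(state: ChainState, config: SimConfig) -> np.ndarray:
    """Per-bead forces from FENE + WCA between bonded neighbours only."""
    f = np.zeros_like(state.positions)
    _, status, idx = K.bonded_forces_energy(
        state.positions, f, config.k_s, config.r_o, config.sigma,
        config.k_B_T, config.printed_fene,
    )
    if status == K.STATUS_BOND:
        raise IntegrationError(
            f"bond {idx}-{idx + 1} reached length >= r_o = {config.r_o}"
        )
    return f


def post_forces(state: ChainState, config: SimConfig) -> np.ndarray:
    """Per-bead forces from the shifted LJ bead-post interaction."""
    f = np.zeros_like(state.positions)
    has_posts, post_xy, box, R, _, _ = _geometry_arrays(config)
    if not has_posts:
        return f
    _, status, idx = K.post_forces_energy(
        state.positions, f, post_xy, box, R,
        config.epsilon, config.r_cutoff, config.sigma, config.k_B_T,
    )
    if status == K.STATUS_OVERLAP:
        raise IntegrationError(f"bead {idx} is inside a post (r <= R)")
    return f


def post_potential(surface_separation: np.ndarray, config: SimConfig) -> np.ndarray:
    """Bead-post potential U(s)/kT vs surface separation s = r - R.

    Shifted by its cutoff value so U is continuous; zero beyond the cutoff.
    """
    s = np.asarray(surface_separation, dtype=float)
    src6 = (config.sigma / config.r_cutoff) ** 6
    shift = 4.0 * config.epsilon * (src6**2 - src6)
    ss6 = (config.sigma / s) ** 6
    u = 4.0 * config.epsilon * (ss6**2 - ss6) - shift
    return np.where(s < config.r_cutoff, u, 0.0)


def total_energy(state: ChainState, config: SimConfig) -> float:
    """Kinetic + potential energy (kT units), for integrator checks."""
    f = np.zeros_like(state.positions)
    has_posts, post_xy, box, R, _, _ = _geometry_arrays(config)
    e_pot, status, idx = K.total_forces(
        state.positions, f, config.k_s, config.r_o, config.sigma,
        config.k_B_T, config.printed_fene,
        has_posts, post_xy, box, R, config.epsilon, config.r_cutoff,
    )
    if status != K.STATUS_OK:
        raise IntegrationError(f"invalid state (status {status}, index {idx})")
    e_kin = 0.5 * config.mass * float((state.velocities**2).sum())
    return float(e_pot) + e_kin


def step(state: ChainState, config: SimConfig, rng: np.random.Generator) -> ChainState:
    """One velocity-Verlet Langevin step with wall reflection.

    The random force has zero mean and per-component standard deviation
    (2 m gamma k_B T / dt)^(1/2); walls reflect specularly (position mirrored,
    z-velocity negated).  Returns a new ChainState.
    """
    pos = state.positions.copy()
    vel = state.velocities.copy()
    cfg = config
    n = cfg.n_beads
    std = np.sqrt(2.0 * cfg.mass * cfg.gamma * cfg.k_B_T / cfg.dt)
    has_posts, post_xy, box, R, has_walls, H = _geometry_arrays(cfg)

    def forces(p):
        f = np.zeros_like(p)
        e, status, idx = K.total_forces(
            p, f, cfg.k_s, cfg.r_o, cfg.sigma, cfg.k_B_T, cfg.printed_fene,
            has_posts, post_xy, box, R, cfg.epsilon, cfg.r_cutoff,
        )
        if status == K.STATUS_BOND:
            raise IntegrationError(f"bond {idx}-{idx + 1} reached r_o during step")
        if status == K.STATUS_OVERLAP:
            raise IntegrationError(f"bead {idx} overlapped a post during step")
        return f

    fr = std * rng.standard_normal((n, 3)) if cfg.random_forces else np.zeros((n, 3))
    f = forces(pos)
    half = 0.5 * cfg.dt
    vel += half * ((f + fr) / cfg.mass - cfg.gamma * vel)
    pos += cfg.dt * vel
    if has_walls:
        K.reflect_walls(pos, vel, H)
    f = forces(pos)
    fr = std * rng.standard_normal((n, 3)) if cfg.random_forces else np.zeros((n, 3))
    vel += half * ((f + fr) / cfg.mass - cfg.gamma * vel)
    if not np.all(np.isfinite(pos)):
        raise IntegrationError(f"non-finite coordinate after step at t={state.time}")
    return ChainState(pos, vel, state.time + cfg.dt)


def grow_chain(config: SimConfig, rng: np.random.Generator,
               bond_length: float = 0.97) -> ChainState:
    """Initial condition: a random walk threading the free space of the array.

    Each bond direction is drawn uniformly in-plane with a small z component;
    candidate directions are resampled until the new bead clears every post by
    at least one bead diameter and stays inside the slit.  Velocities are
    Maxwell-Boltzmann.
    """
    geo = config.geometry
    n = config.n_beads
    pos = np.zeros((n, 3))
    if geo is not None:
        a = geo.lattice_constant
        # start at the midpoint of a nearest-neighbour gap
        start = np.array([0.25 * a, 0.25 * a * np.sqrt(3.0)])
        z0 = 0.5 * geo.slit_height_H
        clearance = geo.post_radius_R + 1.0
    else:
        start = np.zeros(2)
        z0 = 0.0
        clearance = None
    pos[0, :2] = start
    pos[0, 2] = z0
    for i in range(1, n):
        for _attempt in range(200):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            dz = rng.uniform(-0.2, 0.2)
            d = np.array([np.cos(theta), np.sin(theta), dz])
            d *= bond_length / np.linalg.norm(d)
            cand = pos[i - 1] + d
            if geo is not None:
                if not (0.5 < cand[2] < geo.slit_height_H - 0.5):
                    if not (0.0 < cand[2] < geo.slit_height_H):
                        continue
                if float(nearest_post_distance(cand[:2], geo)) < clearance:
                    continue
            pos[i] = cand
            break
        else:
            raise IntegrationError("failed to grow initial chain in the array")
    vel = rng.standard_normal((n, 3)) * np.sqrt(config.k_B_T / config.mass)
    return ChainState(pos, vel, 0.0)


def run(config: SimConfig, initial_state: Optional[ChainState] = None,
        trial_index: int = 0) -> SimTrace:
    """Run one simulation trial; deterministic given ``config.seed``.

    Equilibrates for ``n_steps_equil`` steps, then records the in-plane COM,
    projected Rg, total energy and sanity observables every ``sample_every``
    steps for ``n_steps_total`` steps.
    """
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(trial_index,))
    grow_seed, equil_seed, prod_seed = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)
    ]
    if initial_state is None:
        state = grow_chain(config, np.random.default_rng(grow_seed))
    else:
        state = initial_state.copy()
    has_posts, post_xy, box, R, has_walls, H = _geometry_arrays(config)
    common = dict(
        dt=config.dt, mass=config.mass, gamma=config.gamma, k_B_T=config.k_B_T,
        k_s=config.k_s, r_o=config.r_o, sigma=config.sigma,
        printed_fene=config.printed_fene,
        has_posts=has_posts, post_xy=post_xy, box=box, R=R,
        eps=config.epsilon, r_cutoff=config.r_cutoff,
        has_walls=has_walls, H=H, random_forces=config.random_forces,
        uniform_kick=(config.kick == "uniform"),
    )
    pos = np.ascontiguousarray(state.positions, dtype=float)
    vel = np.ascontiguousarray(state.velocities, dtype=float)

    def _raise(status, idx, bad_step):
        if status == K.STATUS_BOND:
            raise IntegrationError(
                f"bond {idx}-{idx + 1} reached r_o at step {bad_step}"
            )
        if status == K.STATUS_OVERLAP:
            raise IntegrationError(f"bead {idx} entered a post at step {bad_step}")
        raise IntegrationError(f"non-finite coordinates at step {bad_step}")

    if config.n_steps_equil > 0:
        out = K.integrate(
            pos, vel, config.n_steps_equil, config.n_steps_equil,
            seed=equil_seed, snap_every=0, snapshots=np.zeros((0, config.n_beads, 3)),
            **common,
        )
        status, idx, bad_step = out[7], out[8], out[9]
        if status != K.STATUS_OK:
            _raise(status, idx, bad_step)

    n_snap = (config.n_steps_total // config.snapshot_every
              if config.snapshot_every > 0 else 0)
    snapshots = np.zeros((n_snap, config.n_beads, 3))
    out = K.integrate(
        pos, vel, config.n_steps_total, config.sample_every,
        seed=prod_seed, snap_every=config.snapshot_every, snapshots=snapshots,
        **common,
    )
    (com, rg, energy, times, zmin, zmax, maxbond,
     status, idx, bad_step, n_samp, n_snapped) = out
    if status != K.STATUS_OK:
        _raise(status, idx, bad_step)
    return SimTrace(
        times=times / config.t_D,
        com_samples=com,
        rg_samples=rg,
        energy_samples=energy,
        zmin_samples=zmin,
        zmax_samples=zmax,
        maxbond_samples=maxbond,
        config=config,
        snapshots=snapshots if n_snap else None,
        trial_index=trial_index,
    )


def run_trials(config: SimConfig, n_trials: int) -> list[SimTrace]:
    """Independent trials with one counter-derived RNG stream per trial."""
    return [run(replace(config, seed=config.seed), trial_index=t)
            for t in range(n_trials)]


def projected_rg(state_or_positions, box: Optional[np.ndarray] = None) -> float:
    """Projected (in-plane) radius of gyration of a chain configuration.

    If ``box`` is given the chain is first unwrapped bond-by-bond with the
    minimum-image convention, so wrapped configurations measure correctly.
    """
    pos = getattr(state_or_positions, "positions", state_or_positions)
    xy = np.atleast_2d(np.asarray(pos, dtype=float))[:, :2].copy()
    if xy.shape[0] == 0:
        raise ValueError("need at least one bead")
    if box is not None and xy.shape[0] > 1:
        bonds = np.diff(xy, axis=0)
        bonds -= box * np.round(bonds / box)
        xy = np.vstack([xy[0], xy[0] + np.cumsum(bonds, axis=0)])
    com = xy.mean(axis=0)
    return float(np.sqrt(((xy - com) ** 2).sum(axis=1).mean()))
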