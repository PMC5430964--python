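"""Synthetic single-molecule trajectories.

These generators produce displacement/position tracks with the statistical
structure the analysis modules assume — they stand in for unpublished
experimental single-molecule data.  Defaults mirror the imaging conditions of
the study system: long-term observation at 1 frame / 3 s for 3000 s (or
short-term at 2 frames/s for 100 s), trapped levels spaced by g ~ 0.84 um,
within-trap fluctuations of width w_trap ~ 0.31 um, and a per-frame trapping
probability P_trap.

All generators are pure functions of (config, seed).  The trap-hop generator
inverts the HMM observation model exactly: its Gaussian observation noise has
standard deviation w_trap/sqrt(2) so that a shifted-Gaussian fit of the form
exp[-(r-c)^2/w^2] returns w = w_trap, keeping generator and decoder
conventions bit-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .analysis import ComTrajectory


@dataclass(frozen=True)
class SynthConfig:
    """Trap-hop trajectory generator settings (units: um, s)."""

    p_trap: float = 0.7
    step_size_g: float = 0.84
    w_trap: float = 0.31
    frame_interval: float = 3.0
    duration: float = 3000.0
    seed: int = 0
    n_levels_max: Optional[int] = None
    hop_bias: float = 0.5  # probability that a hop goes up (+1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_trap <= 1.0:
            raise ValueError("p_trap must lie in [0, 1]")
        if self.step_size_g <= 0 or self.w_trap <= 0:
            raise ValueError("step_size_g and w_trap must be positive")
        if not 0.0 <= self.hop_bias <= 1.0:
            raise ValueError("hop_bias must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1


def _latent_levels(cfg: SynthConfig, rng: np.random.Generator,
                   n_frames: int) -> np.ndarray:
    """Trap-level random walk: stay with p_trap, else hop +-1, reflecting at
    level 0 (and at n_levels_max if set) exactly like the boundary rows of
    the HMM transition matrix."""
    levels = np.zeros(n_frames, dtype=np.int64)
    top = cfg.n_levels_max
    for t in range(1, n_frames):
        j = levels[t - 1]
        if rng.random() < cfg.p_trap:
            levels[t] = j
            continue
        if j == 0:
            levels[t] = 1
        elif top is not None and j >= top:
            levels[t] = j - 1
        else:
            levels[t] = j + 1 if rng.random() < cfg.hop_bias else j - 1
    return levels


def synth_traphop(config: SynthConfig, return_levels: bool = False):
    """Displacement trajectory from the trap-hop observation model.

    Observed r(t) = level(t)*g + Gaussian(0, w_trap/sqrt(2)), folded to
    non-negative values (displacements are radial magnitudes).  With
    ``return_levels`` the latent trap-level path is returned alongside the
    trajectory (useful for estimator-validation round trips).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    levels = _latent_levels(config, rng, n)
    noise = rng.normal(0.0, config.w_trap / np.sqrt(2.0), size=n)
    r = np.abs(levels * config.step_size_g + noise)
    times = np.arange(n) * config.frame_interval
    traj = ComTrajectory(times=times, r=r, units="experimental")
    return (traj, levels) if return_levels else traj


def synth_traphop_two_scale(config: SynthConfig, g2_factor: float = 1.4,
                            frac_large: float = 0.5) -> ComTrajectory:
    """Trap-hop trajectory mixing two hop magnitudes g and g2_factor*g.

    Each hop draws its magnitude from {g, g2_factor*g} (large with probability
    ``frac_large``); the latent displacement reflects at zero.  Exercises the
    multiple-optimum detection of the step-size scan.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    g = config.step_size_g
    latent = np.zeros(n)
    for t in range(1, n):
        x = latent[t - 1]
        if rng.random() < config.p_trap:
            latent[t] = x
            continue
        mag = g * g2_factor if rng.random() < frac_large else g
        sign = 1.0 if (x <= 0 or rng.random() < config.hop_bias) else -1.0
        latent[t] = abs(x + sign * mag)
    noise = rng.normal(0.0, config.w_trap / np.sqrt(2.0), size=n)
    r = np.abs(latent + noise)
    times = np.arange(n) * config.frame_interval
    return ComTrajectory(times=times, r=r, units="experimental")


def synth_brownian(D: float, frame_interval: float, duration: float,
                   seed: int = 0) -> ComTrajectory:
    """2-D Brownian track with Gaussian increments of variance 2*D*dt per axis."""
    if D < 0:
        raise ValueError("D must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration / frame_interval)) + 1
    steps = rng.normal(0.0, np.sqrt(2.0 * D * frame_interval), size=(n - 1, 2))
    xy = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    times = np.arange(n) * frame_interval
    return ComTrajectory(times=times, xy=xy, units="experimental")


def synth_trapped(w_trap: float, center: float, frame_interval: float,
                  duration: float, seed: int = 0) -> ComTrajectory:
    """Fully trapped molecule: i.i.d. shifted-Gaussian displacement samples
    about a fixed center (width convention exp[-(r-c)^2/w_trap^2], i.e.
    Gaussian std w_trap/sqrt(2))."""
    if w_trap <= 0:
        raise ValueError("w_trap must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / frame_interval)) + 1
    r = rng.normal(center, w_trap / np.sqrt(2.0), size=n)
    times = np.arange(n) * frame_interval
    return ComTrajectory(times=times, r=r, units="experimental")
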