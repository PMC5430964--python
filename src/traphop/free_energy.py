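"""Free-energy barriers: analytic conformational-fluctuation model and
simulation potential of mean force (PMF).

The analytic model treats post-to-post hopping as a one-dimensional reaction
path x between two traps a gap d apart.  An ideal coil's end-to-end vector is
Gaussian, so the free energy of "reaching" along x from either trap is
harmonic with variance <x^2>_0 = <R_EE^2>_0/3 = 2 Rg^2, giving

    beta*F(x) = x^2/(2<x^2>_0) + (x - d)^2/(2<x^2>_0),

whose stationary point at x = d/2 sets the barrier beta*F* = d^2/(8 Rg^2).
(As printed, the summed profile is convex with its *minimum* at d/2 while the
accompanying text places minima at x = 0 and d; the profile and the printed
closed-form barrier d^2/8Rg^2 — the sum evaluated at d/2 — are both
reproduced as stated, and the inconsistency is documented rather than
resolved.)

The simulation PMF is Boltzmann inversion of the COM density folded into one
periodic cell of the post lattice, U_eff/kT = -ln P(r_COM), min-shifted to
zero, with a half-ensemble difference surface as the uncertainty estimate and
a 1-D transect along the shortest inter-post path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import PostArrayGeometry


class PmfError(ValueError):
    pass


@dataclass(frozen=True)
class BarrierModel:
    """Conformational-fluctuation barrier between traps a gap ``d`` apart."""

    gap_d: float
    r_g: float

    def __post_init__(self) -> None:
        if self.gap_d < 0:
            raise ValueError("gap_d must be non-negative")
        if self.r_g <= 0:
            raise ValueError("r_g must be positive")

    @property
    def x2_0(self) -> float:
        """Reaction-coordinate variance <x^2>_0 = <R_EE^2>_0/3 = 2 Rg^2."""
        return 2.0 * self.r_g**2


def barrier_profile(model: BarrierModel, x: np.ndarray) -> np.ndarray:
    """beta*F(x) = x^2/(2<x^2>_0) + (x-d)^2/(2<x^2>_0); symmetric about d/2."""
    x = np.asarray(x, dtype=float)
    v = model.x2_0
    return x**2 / (2.0 * v) + (x - model.gap_d) ** 2 / (2.0 * v)


def barrier_height(model: BarrierModel) -> float:
    """beta*F* = d^2/(8 Rg^2), the profile evaluated at x = d/2."""
    return model.gap_d**2 / (8.0 * model.r_g**2)


@dataclass
class PmfGrid:
    """2-D effective potential -ln P(r_COM) over one periodic lattice cell.

    ``u_eff`` is min-shifted to zero; bins with zero counts are NaN
    (undefined), never clipped to a large value.  ``transect`` holds the
    profile along the nearest-gap line as (dr from post surface, U_eff).
    """

    x_centers: np.ndarray
    y_centers: np.ndarray
    u_eff: np.ndarray
    half_ensemble_delta: np.ndarray
    transect_dr: np.ndarray
    transect_u: np.ndarray
    transect_delta: np.ndarray
    geometry: Optional[PostArrayGeometry] = None
    n_samples: int = 0

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.pcolormesh(self.x_centers, self.y_centers, self.u_eff.T,
                           shading="nearest")
        ax.set_xlabel("x (sigma)")
        ax.set_ylabel("y (sigma)")
        ax.set_aspect("equal")
        plt.colorbar(im, ax=ax, label=r"$U_{\rm eff}/k_BT$")
        return ax


def _hist_to_ueff(counts: np.ndarray) -> np.ndarray:
    """-ln of the normalised histogram, min-shifted over populated bins."""
    total = counts.sum()
    if total == 0:
        raise PmfError("empty histogram")
    with np.errstate(divide="ignore"):
        u = -np.log(counts / total)
    u[counts == 0] = np.nan
    u -= np.nanmin(u)
    return u


def fold_into_cell(samples: np.ndarray, geometry: PostArrayGeometry) -> np.ndarray:
    """Fold in-plane positions into one rectangular lattice cell using the
    lattice translation symmetry only (no point-group averaging)."""
    cell = geometry.cell_dimensions
    return np.mod(np.asarray(samples, dtype=float), cell)


def pmf_from_samples(com_samples: np.ndarray,
                     geometry: Optional[PostArrayGeometry] = None,
                     bins: int = 32,
                     cell: Optional[np.ndarray] = None) -> PmfGrid:
    """Boltzmann-inverted COM free-energy surface over one lattice cell.

    Parameters
    ----------
    com_samples : (n, 2) array
        In-plane COM positions (any images; they are folded into the cell).
    geometry : PostArrayGeometry, optional
        Supplies the cell and the transect direction.  If omitted, ``cell``
        must give the periodic cell dimensions (transect then spans the cell
        diagonal from the origin).
    bins : int
        Bins along x; y gets a proportional count so bins stay near-square.
    """
    samples = np.asarray(com_samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise PmfError("com_samples must be an (n, 2) array")
    if samples.shape[0] < 2:
        raise PmfError("need at least 2 samples")
    if geometry is not None:
        cell = geometry.cell_dimensions
        folded = fold_into_cell(samples, geometry)
    else:
        if cell is None:
            raise PmfError("either geometry or cell must be given")
        cell = np.asarray(cell, dtype=float)
        folded = np.mod(samples, cell)

    nx = int(bins)
    ny = max(1, int(round(bins * cell[1] / cell[0])))
    edges_x = np.linspace(0.0, cell[0], nx + 1)
    edges_y = np.linspace(0.0, cell[1], ny + 1)
    counts, _, _ = np.histogram2d(folded[:, 0], folded[:, 1],
                                  bins=[edges_x, edges_y])
    if (counts > 0).sum() <= 1:
        raise PmfError("degenerate histogram: all samples in one bin")
    u = _hist_to_ueff(counts)

    half = folded.shape[0] // 2
    c1, _, _ = np.histogram2d(folded[:half, 0], folded[:half, 1],
                              bins=[edges_x, edges_y])
    c2, _, _ = np.histogram2d(folded[half:, 0], folded[half:, 1],
                              bins=[edges_x, edges_y])
    with np.errstate(divide="ignore", invalid="ignore"):
        u1 = _hist_to_ueff(c1) if c1.sum() else np.full_like(u, np.nan)
        u2 = _hist_to_ueff(c2) if c2.sum() else np.full_like(u, np.nan)
    delta = np.abs(u1 - u2)

    x_centers = 0.5 * (edges_x[:-1] + edges_x[1:])
    y_centers = 0.5 * (edges_y[:-1] + edges_y[1:])

    # transect along the line joining nearest-neighbour post centers
    if geometry is not None:
        a = geometry.lattice_constant
        p0 = np.array([0.0, 0.0])
        p1 = np.array([0.5 * cell[0], 0.5 * cell[1]])  # body-centre post
        R = geometry.post_radius_R
        span = geometry.gap_d
    else:
        p0 = np.array([0.0, 0.0])
        p1 = cell.copy()
        a = float(np.linalg.norm(p1 - p0))
        R = 0.0
        span = a
    direction = (p1 - p0) / np.linalg.norm(p1 - p0)
    n_t = max(nx, ny)
    dr = np.linspace(0.0, span, n_t)
    pts = p0 + (R + dr)[:, None] * direction[None, :]
    pts = np.mod(pts, cell)
    ix = np.clip(np.searchsorted(edges_x, pts[:, 0], side="right") - 1, 0, nx - 1)
    iy = np.clip(np.searchsorted(edges_y, pts[:, 1], side="right") - 1, 0, ny - 1)
    t_u = u[ix, iy]
    t_delta = delta[ix, iy]

    return PmfGrid(
        x_centers=x_centers, y_centers=y_centers, u_eff=u,
        half_ensemble_delta=delta, transect_dr=dr, transect_u=t_u,
        transect_delta=t_delta, geometry=geometry, n_samples=samples.shape[0],
    )


def transect_barrier(grid: PmfGrid) -> dict:
    """Mid-gap barrier of the transect relative to its minimum.

    Returns a dict with ``barrier`` (NaN if the mid-gap region is entirely
    unpopulated — an unbounded lower estimate, flagged ``undefined=True``),
    the transect minimum, and the half-ensemble uncertainty at the barrier
    point.
    """
    u = grid.transect_u
    dr = grid.transect_dr
    if np.all(np.isnan(u)):
        # the molecule never visited the inter-post line at all: the barrier
        # exceeds the sampling resolution entirely
        return dict(barrier=np.nan, undefined=True, u_min=np.nan,
                    uncertainty=np.nan)
    u_min = np.nanmin(u)
    span = dr[-1]
    mid = (dr > 0.35 * span) & (dr < 0.65 * span)
    mid_u = u[mid]
    if np.all(np.isnan(mid_u)):
        return dict(barrier=np.nan, undefined=True, u_min=float(u_min),
                    uncertainty=np.nan)
    i_rel = np.nanargmax(mid_u)
    idx = np.flatnonzero(mid)[i_rel]
    return dict(
        barrier=float(u[idx] - u_min),
        undefined=False,
        u_min=float(u_min),
        uncertainty=float(grid.transect_delta[idx])
        if np.isfinite(grid.transect_delta[idx]) else np.nan,
    )
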