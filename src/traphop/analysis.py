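"""Statistics of center-of-mass trajectories.

Mean squared displacement with sliding (overlapping) time windows, short- and
long-term diffusivities from linear MSD fits, power-law exponents,
displacement(^2) distributions with single/double/stretched exponential fits,
and the shifted-Gaussian width of within-trap fluctuations.

Conventions: a 2-D track gives D = slope/4, a 1-D displacement series
D = slope/2; the single-exponential displacement law P(r^2) ~ exp(-r^2/lambda)
has lambda = 4 D dt for a 2-D random walk, so the characteristic diffusivity
derived from a fitted scale is lambda/(4 dt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize


class AnalysisError(ValueError):
    pass


class FitFailureError(AnalysisError):
    """Nonlinear fit did not converge; carries the residual report."""


@dataclass
class ComTrajectory:
    """Timestamped track: either a 2-D position track ``xy`` or a scalar
    displacement series ``r`` (|r(t) - r(0)| as measured experimentally).

    ``units`` tags the unit system: "experimental" (um, s) or "simulation"
    (sigma, t_D).  Frames must be uniformly spaced (required by the lag-based
    estimators).
    """

    times: np.ndarray
    xy: Optional[np.ndarray] = None
    r: Optional[np.ndarray] = None
    units: str = "experimental"
    frame_interval: float = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size < 2:
            raise AnalysisError("trajectory needs at least 2 frames")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise AnalysisError(f"time stamps must strictly increase (frame {bad})")
        self.frame_interval = float(dt.mean())
        if np.any(np.abs(dt - self.frame_interval) > 1e-6 * self.frame_interval):
            bad = int(np.argmax(np.abs(dt - self.frame_interval)
                                > 1e-6 * self.frame_interval)) + 1
            raise AnalysisError(f"non-uniform frame spacing at frame {bad}")
        if self.xy is None and self.r is None:
            raise AnalysisError("trajectory needs positions xy or displacements r")
        if self.xy is not None:
            self.xy = np.asarray(self.xy, dtype=float)
            if self.xy.shape != (self.times.size, 2):
                raise AnalysisError(
                    f"xy must have shape (n_frames, 2), got {self.xy.shape}"
                )
        if self.r is not None:
            self.r = np.asarray(self.r, dtype=float)
            if self.r.shape != self.times.shape:
                raise AnalysisError("r must have one value per frame")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def displacement(self) -> np.ndarray:
        """Scalar displacement from the initial position, r(t) = |r(t)-r(0)|."""
        if self.r is not None:
            return self.r
        return np.sqrt(((self.xy - self.xy[0]) ** 2).sum(axis=1))

    @property
    def dim(self) -> int:
        return 2 if self.xy is not None else 1

    def _coords(self) -> np.ndarray:
        return self.xy if self.xy is not None else self.r[:, None]


@dataclass
class MsdCurve:
    """MSD(lag) with pair counts and half-ensemble uncertainty per lag."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    half_ensemble_spread: np.ndarray
    dim: int = 2

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.lags[1:], self.msd[1:],
                    yerr=self.half_ensemble_spread[1:], **kwargs)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(r"$\Delta t$")
        ax.set_ylabel(r"MSD$(\Delta t)$")
        return ax


@dataclass
class DiffusivityFit:
    D: float
    window: tuple
    dim: int
    intercept: float = 0.0
    exponent_alpha: Optional[float] = None


@dataclass
class DisplacementFit:
    """Parameters of a fit to the displacement-squared distribution."""

    lag: float
    model: str
    lambda1: float
    c1: float
    lambda2: Optional[float] = None
    c2: Optional[float] = None
    stretch_beta: Optional[float] = None
    degenerate: bool = False

    @property
    def derived_D(self) -> float:
        """Characteristic diffusivity lambda1/(4 lag) of a 2-D walk."""
        return self.lambda1 / (4.0 * self.lag)

    @property
    def derived_D2(self) -> Optional[float]:
        if self.lambda2 is None:
            return None
        return self.lambda2 / (4.0 * self.lag)


@dataclass
class TrapWidthFit:
    center: float
    width: float
    amplitude: float


@dataclass
class DisplacementHistogram:
    """Normalized histograms of r^2 (primary) and r at one lag."""

    lag: float
    r2_centers: np.ndarray
    density: np.ndarray
    counts: np.ndarray
    n_pairs: int
    low_statistics: bool = False
    r_centers: Optional[np.ndarray] = None
    r_density: Optional[np.ndarray] = None

    @property
    def bin_width(self) -> float:
        return float(self.r2_centers[1] - self.r2_centers[0])


def msd(traj: ComTrajectory, max_lag: Optional[float] = None) -> MsdCurve:
    """Time-window (all overlapping pairs) MSD at integer-multiple lags.

    The per-lag uncertainty is the absolute difference between the MSD of the
    first and second halves of the pair ensemble.
    """
    dt = traj.frame_interval
    n = traj.n_frames
    if max_lag is None:
        max_lag = traj.times[-1] - traj.times[0]
    k_max = int(round(max_lag / dt))
    if k_max < 1:
        raise AnalysisError(
            f"max_lag {max_lag} is below one frame interval {dt}"
        )
    k_max = min(k_max, n - 1)
    coords = traj._coords()
    lags = np.arange(k_max + 1) * dt
    out = np.zeros(k_max + 1)
    n_pairs = np.zeros(k_max + 1, dtype=int)
    spread = np.zeros(k_max + 1)
    n_pairs[0] = n
    for k in range(1, k_max + 1):
        diff = coords[k:] - coords[:-k]
        sq = (diff**2).sum(axis=1)
        out[k] = sq.mean()
        n_pairs[k] = sq.size
        h = sq.size // 2
        if h >= 1 and sq.size - h >= 1:
            spread[k] = abs(sq[:h].mean() - sq[h:].mean())
    return MsdCurve(lags=lags, msd=out, n_pairs=n_pairs,
                    half_ensemble_spread=spread, dim=traj.dim)


def _window_mask(lags: np.ndarray, window: tuple) -> np.ndarray:
    lo, hi = window
    eps = 1e-9 * max(abs(hi), 1.0)
    return (lags >= lo - eps) & (lags <= hi + eps) & (lags > 0)


def fit_diffusivity(curve: MsdCurve, window: tuple,
                    dim: Optional[int] = None) -> DiffusivityFit:
    """Least-squares line through MSD vs lag over a window; D = slope/(2 dim)."""
    dim = curve.dim if dim is None else dim
    mask = _window_mask(curve.lags, window)
    if mask.sum() < 2:
        raise AnalysisError(
            f"window {window} contains {int(mask.sum())} lags; need >= 2"
        )
    slope, intercept = np.polyfit(curve.lags[mask], curve.msd[mask], 1)
    return DiffusivityFit(D=max(float(slope), 0.0) / (2 * dim), window=window,
                          dim=dim, intercept=float(intercept))


def powerlaw_exponent(curve: MsdCurve, window: tuple) -> float:
    """Slope of log MSD vs log lag over the window."""
    mask = _window_mask(curve.lags, window)
    if mask.sum() < 2:
        raise AnalysisError(f"window {window} contains fewer than 2 lags")
    if np.any(curve.msd[mask] <= 0):
        raise AnalysisError("MSD must be positive throughout the window")
    slope, _ = np.polyfit(np.log(curve.lags[mask]), np.log(curve.msd[mask]), 1)
    return float(slope)


def displacement_distribution(traj: ComTrajectory, lag: float,
                              bins: int = 50) -> DisplacementHistogram:
    """Normalized histogram of r(lag)^2 over all overlapping frame pairs."""
    dt = traj.frame_interval
    k = int(round(lag / dt))
    if abs(k * dt - lag) > 1e-6 * dt or k < 1:
        raise AnalysisError(f"lag {lag} is not a positive multiple of {dt}")
    coords = traj._coords()
    if k >= traj.n_frames:
        raise AnalysisError("lag exceeds trajectory duration")
    diff = coords[k:] - coords[:-k]
    sq = (diff**2).sum(axis=1)
    counts, edges = np.histogram(sq, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    density = counts / (counts.sum() * width)
    r = np.sqrt(sq)
    r_counts, r_edges = np.histogram(r, bins=bins)
    r_centers = 0.5 * (r_edges[:-1] + r_edges[1:])
    r_density = r_counts / (r_counts.sum() * (r_edges[1] - r_edges[0]))
    return DisplacementHistogram(
        lag=float(lag), r2_centers=centers, density=density, counts=counts,
        n_pairs=sq.size, low_statistics=sq.size < 50,
        r_centers=r_centers, r_density=r_density,
    )


def _weighted_line(x, y, w):
    W = np.asarray(w, dtype=float)
    A = np.vstack([x, np.ones_like(x)]).T * np.sqrt(W)[:, None]
    b = np.asarray(y) * np.sqrt(W)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    return coef  # slope, intercept


def fit_exponentials(hist: DisplacementHistogram,
                     model: str = "single") -> DisplacementFit:
    """Fit the displacement-squared distribution.

    single:    P = C1 exp(-r^2/lambda1)
    double:    P = C1 exp(-r^2/lambda1) + C2 exp(-r^2/lambda2), lambda2 > lambda1
    stretched: -ln P = a + (r^2/lambda1)^beta

    Fits are carried out on ln P vs r^2 weighted by counts (straight lines on
    a semilog plot); the double model refines with nonlinear least squares,
    seeding the tail scale from bins with r^2 > 3*lambda1.
    """
    mask = hist.counts > 0
    if mask.sum() < 5:
        raise AnalysisError("need at least 5 nonzero histogram bins")
    x = hist.r2_centers[mask]
    p = hist.density[mask]
    w = hist.counts[mask].astype(float)
    lnp = np.log(p)

    slope, icept = _weighted_line(x, lnp, w)
    lam1 = -1.0 / slope if slope < 0 else np.inf
    c1 = math.exp(icept)
    if not np.isfinite(lam1) or lam1 <= 0:
        raise FitFailureError("single-exponential fit gave non-decaying slope")

    if model == "single":
        return DisplacementFit(lag=hist.lag, model=model, lambda1=lam1, c1=c1)

    if model == "double":
        tail = x > 3.0 * lam1
        if tail.sum() >= 2:
            s2, i2 = _weighted_line(x[tail], lnp[tail], w[tail])
            lam2 = -1.0 / s2 if s2 < 0 else 10.0 * lam1
            c2 = math.exp(min(i2, 50.0))
        else:
            lam2, c2 = 5.0 * lam1, 0.1 * c1

        def f(xx, c1_, l1_, c2_, l2_):
            return c1_ * np.exp(-xx / l1_) + c2_ * np.exp(-xx / l2_)

        try:
            popt, _ = optimize.curve_fit(
                f, x, p, p0=[c1, lam1, c2, max(lam2, 1.5 * lam1)],
                sigma=1.0 / np.sqrt(w), maxfev=20000,
                bounds=([0, 1e-12, 0, 1e-12], [np.inf] * 4),
            )
        except RuntimeError as err:
            raise FitFailureError(f"double-exponential fit failed: {err}") from err
        c1_, l1_, c2_, l2_ = popt
        if l2_ < l1_:
            c1_, l1_, c2_, l2_ = c2_, l2_, c1_, l1_
        degenerate = (c2_ < 1e-3 * c1_) or (l2_ < 1.2 * l1_)
        return DisplacementFit(lag=hist.lag, model=model, lambda1=float(l1_),
                               c1=float(c1_), lambda2=float(l2_), c2=float(c2_),
                               degenerate=bool(degenerate))

    if model == "stretched":
        def g(xx, a, lam, beta):
            return a - (xx / lam) ** beta

        try:
            popt, _ = optimize.curve_fit(
                g, x, lnp, p0=[icept, lam1, 1.0],
                sigma=1.0 / np.sqrt(w), maxfev=20000,
                bounds=([-np.inf, 1e-12, 0.05], [np.inf, np.inf, 2.0]),
            )
        except RuntimeError as err:
            raise FitFailureError(f"stretched-exponential fit failed: {err}") from err
        a, lam, beta = popt
        return DisplacementFit(lag=hist.lag, model=model, lambda1=float(lam),
                               c1=math.exp(min(a, 50.0)), stretch_beta=float(beta))

    raise ValueError(f"unknown model {model!r}")


def fit_trap_width(r_samples: np.ndarray, bins: int = 40) -> TrapWidthFit:
    """Shifted-Gaussian fit A*exp[-(r-c)^2/w^2] to a displacement histogram.

    Note the convention has no factor 2 in the exponent: a Gaussian sample of
    standard deviation s fits with w = s*sqrt(2).  This keeps the width
    directly exchangeable with the trap-hop HMM emission width w_trap.
    """
    r = np.asarray(r_samples, dtype=float)
    if r.size < 10:
        raise AnalysisError("need at least 10 samples")
    if np.ptp(r) == 0:
        raise AnalysisError("degenerate input: all samples identical")
    counts, edges = np.histogram(r, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    density = counts / (counts.sum() * width)

    def f(x, A, c, w):
        return A * np.exp(-((x - c) ** 2) / w**2)

    p0 = [density.max(), float(r.mean()), float(r.std() * np.sqrt(2.0))]
    try:
        popt, _ = optimize.curve_fit(f, centers, density, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise FitFailureError(f"shifted-Gaussian fit failed: {err}") from err
    A, c, w = popt
    if w <= 0:
        w = -w
    return TrapWidthFit(center=float(c), width=float(w), amplitude=float(A))
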