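"""Hidden-Markov trap-hop decoder for single-molecule displacement tracks.

A molecule diffusing in a weakly attractive post array spends most frames
trapped near a post and occasionally hops to a neighbouring trap.  The
displacement trajectory r(t) = |r(t) - r(0)| is modelled as an HMM whose
hidden state is a trapped level j on a ladder r_0(j) = j*g (step size g,
roughly one lattice gap), with

* Gaussian emission weights G_j(r) = exp[-(r - j*g)^2 / w_trap^2] about each
  level (w_trap is the within-trap fluctuation width), and
* a tridiagonal row-stochastic transition matrix: stay with probability
  P_trap, hop to either neighbour with (1 - P_trap)/2 (boundary rows put the
  whole hop probability on their single neighbour).

The fitting procedure is a count-matching Viterbi iteration, not Baum-Welch:
decode the most likely state path, count its empirical transition matrix T*,
refit P_trap by minimising the Frobenius distance |T* - T(P_trap)| over the
visited rows, and repeat until P_trap converges.  Fit quality is the reduced
Pearson statistic chi^2/nu with nu = (#nonzero T* entries) - 3, and the
free-energy barrier to hopping follows from Boltzmann weighting of the hop
probability, dG = -ln(1 - P_trap*) in units of k_B T.

The model-level API is :class:`TrapHopHMM` / :class:`TrapHopResults`;
the individual operations are module functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .analysis import ComTrajectory


class DecodingError(RuntimeError):
    pass


class NonConvergenceError(RuntimeError):
    """Viterbi iteration exceeded max_iter; carries the iterate history."""

    def __init__(self, message: str, history: list):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class StepModel:
    """Ladder of trapped displacement levels r_0(j) = j*g, j in [0, n_steps]."""

    step_size_g: float
    w_trap: float = 0.31
    n_steps: int = 1

    def __post_init__(self) -> None:
        if self.step_size_g <= 0:
            raise ValueError("step_size_g must be positive")
        if self.w_trap <= 0:
            raise ValueError("w_trap must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def level_centers(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.step_size_g

    @classmethod
    def for_displacements(cls, r: np.ndarray, step_size_g: float,
                          w_trap: float = 0.31,
                          n_steps: Optional[int] = None) -> "StepModel":
        """Build a ladder covering the data: n_steps = ceil(max r / g)."""
        if n_steps is None:
            n_steps = max(1, int(math.ceil(float(np.max(r)) / step_size_g)))
        return cls(step_size_g=step_size_g, w_trap=w_trap, n_steps=n_steps)


@dataclass
class TransitionMatrix:
    """Tridiagonal row-stochastic transition structure of the trap-hop chain."""

    entries: np.ndarray
    p_trap: float

    @property
    def p_hop(self) -> float:
        return 1.0 - self.p_trap

    @property
    def n_states(self) -> int:
        return self.entries.shape[0]


@dataclass
class DecodedPath:
    """Most likely state path and the emission weights it was decoded from."""

    states: np.ndarray
    emissions_used: np.ndarray
    log_prob: float


@dataclass
class HmmResult:
    """Converged output of the Viterbi iteration."""

    p_trap_star: float
    chi2_over_nu: float
    iterations: int
    empirical_T: np.ndarray
    visited_rows: np.ndarray
    delta_G: float
    n_levels_visited: int
    history: list = field(default_factory=list)
    path: Optional[DecodedPath] = None
    below_detection_floor: Optional[bool] = None


def build_transition_matrix(p_trap: float, n_steps: int) -> TransitionMatrix:
    """T_ii = P_trap; interior off-diagonals P_hop/2; boundary rows put the
    full P_hop on their single neighbour.  Rows sum to one."""
    if not 0.0 <= p_trap <= 1.0:
        raise ValueError("p_trap must lie in [0, 1]")
    n = n_steps + 1
    p_hop = 1.0 - p_trap
    T = np.zeros((n, n))
    np.fill_diagonal(T, p_trap)
    if n == 1:
        T[0, 0] = 1.0
        return TransitionMatrix(entries=T, p_trap=p_trap)
    for i in range(1, n - 1):
        T[i, i - 1] = T[i, i + 1] = 0.5 * p_hop
    T[0, 1] = p_hop
    T[n - 1, n - 2] = p_hop
    return TransitionMatrix(entries=T, p_trap=p_trap)


def emissions(displacements: np.ndarray, model: StepModel) -> np.ndarray:
    """Per-frame likelihood weights v_j(t) = exp[-(r(t) - j*g)^2 / w_trap^2].

    Unnormalised by construction; only ratios matter to the decoder.
    """
    r = np.asarray(displacements, dtype=float)[:, None]
    centers = model.level_centers[None, :]
    return np.exp(-((r - centers) ** 2) / model.w_trap**2)


def log_emissions(displacements: np.ndarray, model: StepModel) -> np.ndarray:
    r = np.asarray(displacements, dtype=float)[:, None]
    centers = model.level_centers[None, :]
    return -((r - centers) ** 2) / model.w_trap**2


def viterbi_decode(emission_weights: np.ndarray, T: TransitionMatrix,
                   log_space_input: bool = False) -> DecodedPath:
    """Maximum-product state path (log-space dynamic programming).

    Initial state weights are the first frame's emissions (uniform prior);
    ties break toward the lower state index.
    """
    v = np.asarray(emission_weights, dtype=float)
    if v.ndim != 2 or v.shape[0] < 1:
        raise DecodingError("emissions must be a (n_frames, n_states) array")
    logv = v if log_space_input else _safe_log(v)
    with np.errstate(divide="ignore"):
        logT = np.where(T.entries > 0, np.log(np.maximum(T.entries, 1e-300)), -np.inf)
    n_frames, n_states = logv.shape
    if logT.shape != (n_states, n_states):
        raise DecodingError("transition matrix size does not match emissions")
    delta = logv[0].copy()
    if not np.any(np.isfinite(delta)):
        raise DecodingError("all-zero emission column at frame 0")
    psi = np.zeros((n_frames, n_states), dtype=np.int64)
    for t in range(1, n_frames):
        cand = delta[:, None] + logT  # cand[i, j]
        psi[t] = np.argmax(cand, axis=0)  # first (lowest) index wins ties
        delta = cand[psi[t], np.arange(n_states)] + logv[t]
        if not np.any(np.isfinite(delta)):
            raise DecodingError(f"all paths have zero probability at frame {t}")
    states = np.zeros(n_frames, dtype=np.int64)
    states[-1] = int(np.argmax(delta))
    log_prob = float(delta[states[-1]])
    for t in range(n_frames - 1, 0, -1):
        states[t - 1] = psi[t, states[t]]
    return DecodedPath(states=states, emissions_used=v, log_prob=log_prob)


def _safe_log(v: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(v > 0, np.log(np.maximum(v, 1e-300)), -np.inf)


def greedy_decode(displacements: np.ndarray, model: StepModel) -> np.ndarray:
    """Baseline without the Viterbi pass: assign each frame to the closest
    level.  Used for the fit-quality comparison against the full decoder."""
    r = np.asarray(displacements, dtype=float)
    states = np.rint(r / model.step_size_g).astype(np.int64)
    return np.clip(states, 0, model.n_steps)


def empirical_transitions(states: np.ndarray, n_steps: int):
    """Row-normalised transition frequencies of a decoded path.

    Returns (T_star, visited_rows, counts); rows never visited as a source
    state are flagged False in ``visited_rows`` and left as zero rows.
    """
    s = np.asarray(states, dtype=np.int64)
    if s.size < 2:
        raise DecodingError("path must have at least 2 frames")
    n = n_steps + 1
    counts = np.zeros((n, n))
    np.add.at(counts, (s[:-1], s[1:]), 1.0)
    row_sums = counts.sum(axis=1)
    visited = row_sums > 0
    T_star = np.zeros_like(counts)
    T_star[visited] = counts[visited] / row_sums[visited, None]
    return T_star, visited, counts


def fit_p_trap(empirical_T: np.ndarray, n_steps: int,
               visited_rows: Optional[np.ndarray] = None,
               row_weights: Optional[np.ndarray] = None) -> float:
    """P_trap minimising |T* - T(P_trap)| (Frobenius norm, visited rows only).

    With ``row_weights`` (occupation counts of each source state) the norm
    weights each visited row by how often the decoded path actually sampled
    it, so a level visited twice cannot outvote one occupied for hundreds of
    frames; without weights all visited rows count equally.

    The norm is unimodal in P_trap for this tridiagonal family; a bounded
    golden-section/Brent search on [0, 1] returns the unique minimiser.
    """
    T_star = np.asarray(empirical_T, dtype=float)
    if visited_rows is None:
        visited_rows = T_star.sum(axis=1) > 0
    if not np.any(visited_rows):
        raise DecodingError("no visited transitions: P_trap fit is undefined")
    rows = np.flatnonzero(visited_rows)
    if row_weights is None:
        w = np.ones(rows.size)
    else:
        w = np.asarray(row_weights, dtype=float)[rows]
        w = w / w.mean()

    def objective(p):
        T = build_transition_matrix(p, n_steps).entries
        d = T_star[rows] - T[rows]
        return float(np.sqrt((w[:, None] * d**2).sum()))

    res = optimize.minimize_scalar(objective, bounds=(0.0, 1.0),
                                   method="bounded",
                                   options={"xatol": 1e-7})
    return float(np.clip(res.x, 0.0, 1.0))


def reduced_chi2(T: TransitionMatrix | np.ndarray,
                 empirical_T: np.ndarray) -> float:
    """Pearson statistic chi^2 = sum (T_ij - T*_ij)^2 / T*_ij over nonzero
    empirical entries, divided by nu = (#nonzero entries) - 3.

    The formula is agnostic to the scale of its arguments; the fit-quality
    diagnostic of the Viterbi iteration feeds it *count* matrices (observed
    transition counts vs expected counts n_i * T_ij), the scale on which
    Pearson's test has its chi^2/nu ~ 1 calibration for a good fit.
    """
    Tm = T.entries if isinstance(T, TransitionMatrix) else np.asarray(T, float)
    T_star = np.asarray(empirical_T, dtype=float)
    mask = T_star > 0
    nu = int(mask.sum()) - 3
    if nu <= 0:
        raise DecodingError(f"degenerate degrees of freedom: nu = {nu}")
    chi2 = float((((Tm - T_star) ** 2)[mask] / T_star[mask]).sum())
    return chi2 / nu


def barrier_from_p(p_trap: float) -> float:
    """Free-energy barrier dG = -ln(1 - P_trap) in k_B T (Boltzmann hop law).

    P_trap = 1 (no hops observed) returns the infinite-barrier sentinel
    ``math.inf``.
    """
    if not 0.0 <= p_trap <= 1.0:
        raise ValueError("p_trap must lie in [0, 1]")
    if p_trap == 1.0:
        return math.inf
    return -math.log(1.0 - p_trap)


def detection_floor(frame_interval: float, frame_rate: float) -> float:
    """Smallest resolvable P_trap = exp(-dt * f_Nyq), f_Nyq = frame_rate/2.

    Fitted trapping probabilities below this floor are flagged unreliable:
    hops faster than the Nyquist frequency of the camera cannot be counted.
    """
    if frame_interval < 0 or frame_rate < 0:
        raise ValueError("frame_interval and frame_rate must be non-negative")
    return math.exp(-frame_interval * 0.5 * frame_rate)


def viterbi_iterate(displacements: np.ndarray, model: StepModel,
                    p0: float = 0.5, tol: float = 1e-3,
                    max_iter: int = 100,
                    frame_rate: Optional[float] = None,
                    frame_interval: Optional[float] = None,
                    use_viterbi: bool = True) -> HmmResult:
    """Count-matching Viterbi iteration for the trapping probability.

    Alternates decode -> count transitions -> refit P_trap until successive
    iterates differ by less than ``tol`` (also detected for a period-2 cycle,
    in which case the mean of the cycle is reported).  The converged result is
    independent of the starting guess p0 within tol.

    Set ``use_viterbi=False`` for the greedy nearest-level baseline (single
    pass decode, then fit), used to show the Viterbi pass is essential.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    r = np.asarray(displacements, dtype=float)
    logv = log_emissions(r, model)
    history = []
    p = float(p0)
    path = None
    for it in range(1, max_iter + 1):
        T = build_transition_matrix(p, model.n_steps)
        if use_viterbi:
            path = viterbi_decode(logv, T, log_space_input=True)
            states = path.states
        else:
            states = greedy_decode(r, model)
        T_star, visited, counts = empirical_transitions(states, model.n_steps)
        p_new = fit_p_trap(T_star, model.n_steps, visited,
                           row_weights=counts.sum(axis=1))
        history.append(p_new)
        converged = abs(p_new - p) < tol
        cycle = len(history) >= 3 and abs(history[-1] - history[-3]) < tol
        if not use_viterbi:
            converged = True  # greedy baseline is a single pass
        if converged or cycle:
            if cycle and not converged:
                p_new = 0.5 * (history[-1] + history[-2])
            T_fit = build_transition_matrix(p_new, model.n_steps)
            _, _, counts = empirical_transitions(states, model.n_steps)
            expected = counts.sum(axis=1)[:, None] * T_fit.entries
            try:
                chi2 = reduced_chi2(expected, counts)
            except DecodingError:
                # hop-free paths leave too few populated cells for nu > 0
                chi2 = float("nan")
            floor_flag = None
            if frame_rate is not None and frame_interval is not None:
                floor_flag = p_new < detection_floor(frame_interval, frame_rate)
            return HmmResult(
                p_trap_star=p_new,
                chi2_over_nu=chi2,
                iterations=it,
                empirical_T=T_star,
                visited_rows=visited,
                delta_G=barrier_from_p(p_new),
                n_levels_visited=int(len(np.unique(states))),
                history=history,
                path=DecodedPath(states=states, emissions_used=logv,
                                 log_prob=getattr(path, "log_prob", np.nan)),
                below_detection_floor=floor_flag,
            )
        p = p_new
    raise NonConvergenceError(
        f"Viterbi iteration did not converge in {max_iter} iterations", history
    )


def scan_step_size(displacements: np.ndarray, g_grid: Sequence[float],
                   w_trap: float = 0.31, p0: float = 0.5, tol: float = 1e-3,
                   max_iter: int = 100, p_floor: float = 0.135) -> pd.DataFrame:
    """Run the Viterbi iteration over a grid of step sizes g.

    Returns a table of (g, p_trap_star, chi2_over_nu, delta_G, n_steps,
    below_floor, local_min) where ``local_min`` flags local minima of
    chi^2/nu on the grid; multiple flagged rows signal several competing hop
    scales.  Rows whose fitted trapping probability falls below the Nyquist
    detection floor ``p_floor`` (default the exp(-2) = 0.135 floor of the
    study's imaging) describe hopping faster than the camera can resolve;
    they are flagged ``below_floor`` and excluded from minimum detection,
    since a fine enough ladder with near-free hopping can shadow any
    trajectory.
    """
    g_grid = np.asarray(list(g_grid), dtype=float)
    if g_grid.size == 0:
        raise ValueError("g_grid must be nonempty")
    rows = []
    for g in g_grid:
        model = StepModel.for_displacements(displacements, g, w_trap=w_trap)
        try:
            res = viterbi_iterate(displacements, model, p0=p0, tol=tol,
                                  max_iter=max_iter)
            rows.append(dict(g=g, p_trap_star=res.p_trap_star,
                             chi2_over_nu=res.chi2_over_nu,
                             delta_G=res.delta_G, n_steps=model.n_steps,
                             n_levels_visited=res.n_levels_visited))
        except (DecodingError, NonConvergenceError):
            rows.append(dict(g=g, p_trap_star=np.nan, chi2_over_nu=np.nan,
                             delta_G=np.nan, n_steps=model.n_steps,
                             n_levels_visited=0))
    table = pd.DataFrame(rows)
    below = table["p_trap_star"].to_numpy() < p_floor
    table["below_floor"] = below
    chi2 = table["chi2_over_nu"].to_numpy().copy()
    chi2[below] = np.nan
    table["local_min"] = find_local_minima(chi2)
    return table


def find_local_minima(values: np.ndarray) -> np.ndarray:
    """Flag strict-or-plateau local minima of a 1-D scan (NaN-aware)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        if not np.isfinite(v[i]):
            continue
        left = v[i - 1] if i > 0 and np.isfinite(v[i - 1]) else np.inf
        right = v[i + 1] if i < n - 1 and np.isfinite(v[i + 1]) else np.inf
        if v[i] <= left and v[i] <= right and (v[i] < left or v[i] < right
                                               or (i == 0 or i == n - 1)):
            flags[i] = True
    # collapse plateaus: keep only the first index of equal-valued runs
    for i in range(1, n):
        if flags[i] and flags[i - 1] and v[i] == v[i - 1]:
            flags[i] = False
    return flags


class TrapHopHMM:
    """Trap-hop HMM built from a displacement trajectory.

    Parameters
    ----------
    endog : ComTrajectory or array_like
        Displacement series r(t) (a ComTrajectory contributes its scalar
        displacement and its frame interval for detection-floor flags).
    step_size_g : float
        Spacing between trapped levels (same units as r).
    w_trap : float
        Within-trap fluctuation width (default 0.31, the experimental
        shifted-Gaussian width for a fully trapped molecule).
    n_steps : int, optional
        Ladder height; defaults to ceil(max r / g).

    Examples
    --------
    >>> res = TrapHopHMM(r, step_size_g=0.84, w_trap=0.31).fit()
    >>> res.p_trap_star, res.delta_G  # doctest: +SKIP
    """

    def __init__(self, endog, step_size_g: float, w_trap: float = 0.31,
                 n_steps: Optional[int] = None):
        if isinstance(endog, ComTrajectory):
            self.displacements = endog.displacement
            self.frame_interval = endog.frame_interval
        else:
            self.displacements = np.asarray(endog, dtype=float)
            self.frame_interval = None
        self.model = StepModel.for_displacements(
            self.displacements, step_size_g, w_trap=w_trap, n_steps=n_steps
        )

    def fit(self, p0: float = 0.5, tol: float = 1e-3,
            max_iter: int = 100) -> "TrapHopResults":
        kw = {}
        if self.frame_interval is not None:
            kw = dict(frame_interval=self.frame_interval,
                      frame_rate=1.0 / self.frame_interval)
        res = viterbi_iterate(self.displacements, self.model,
                              p0=p0, tol=tol, max_iter=max_iter, **kw)
        return TrapHopResults(self, res)

    def fit_greedy(self) -> "TrapHopResults":
        """Greedy nearest-level baseline (no Viterbi pass)."""
        res = viterbi_iterate(self.displacements, self.model, use_viterbi=False)
        return TrapHopResults(self, res)

    def scan(self, g_grid: Sequence[float], **kwargs) -> pd.DataFrame:
        return scan_step_size(self.displacements, g_grid,
                              w_trap=self.model.w_trap, **kwargs)


class TrapHopResults:
    """Results of a trap-hop HMM fit: estimates, diagnostics, summary."""

    def __init__(self, model: TrapHopHMM, result: HmmResult):
        self.model = model
        self._result = result

    @property
    def p_trap_star(self) -> float:
        return self._result.p_trap_star

    @property
    def p_hop_star(self) -> float:
        return 1.0 - self._result.p_trap_star

    @property
    def delta_G(self) -> float:
        return self._result.delta_G

    @property
    def chi2_over_nu(self) -> float:
        return self._result.chi2_over_nu

    @property
    def iterations(self) -> int:
        return self._result.iterations

    @property
    def empirical_T(self) -> np.ndarray:
        return self._result.empirical_T

    @property
    def n_levels_visited(self) -> int:
        return self._result.n_levels_visited

    @property
    def states(self) -> np.ndarray:
        return self._result.path.states

    @property
    def below_detection_floor(self) -> Optional[bool]:
        return self._result.below_detection_floor

    def to_dict(self) -> dict:
        return {
            "p_trap_star": self.p_trap_star,
            "p_hop_star": self.p_hop_star,
            "delta_G_kBT": self.delta_G,
            "chi2_over_nu": self.chi2_over_nu,
            "iterations": self.iterations,
            "n_levels_visited": self.n_levels_visited,
            "step_size_g": self.model.model.step_size_g,
            "w_trap": self.model.model.w_trap,
            "n_steps": self.model.model.n_steps,
            "below_detection_floor": self.below_detection_floor,
        }

    def summary(self) -> str:
        m = self.model.model
        dg = ("inf" if math.isinf(self.delta_G) else f"{self.delta_G:10.4f}")
        lines = [
            "            Trap-hop HMM (Viterbi iteration)",
            "=" * 54,
            f"frames                 {self.model.displacements.size:>10d}",
            f"step size g            {m.step_size_g:>10.4f}",
            f"w_trap                 {m.w_trap:>10.4f}",
            f"ladder levels (N+1)    {m.n_steps + 1:>10d}",
            "-" * 54,
            f"P_trap*                {self.p_trap_star:>10.4f}",
            f"P_hop*                 {self.p_hop_star:>10.4f}",
            f"dG / k_B T             {dg:>10s}",
            f"chi2 / nu              {self.chi2_over_nu:>10.4f}",
            f"iterations             {self.iterations:>10d}",
            f"levels visited         {self.n_levels_visited:>10d}",
            "=" * 54,
        ]
        if self.below_detection_floor:
            lines.append("warning: P_trap* below the Nyquist detection floor")
        return "\n".join(lines)

    def plot_decoded(self, ax=None):
        """Observed displacement with the decoded trap-level ladder overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.model.displacements
        t = np.arange(r.size)
        ax.plot(t, r, "k-", lw=0.8, label="r(t)")
        ax.step(t, self.states * self.model.model.step_size_g, "r-",
                where="post", label="decoded levels")
        ax.set_xlabel("frame")
        ax.set_ylabel("displacement")
        ax.legend()
        return ax
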