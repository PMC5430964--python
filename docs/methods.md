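# Methods

`traphop` models the transport of a large flexible macromolecule (lambda-DNA
is the motivating system) through a slit-confined array of weakly attractive
microposts, and provides the statistical machinery to infer trapping
probabilities and free-energy barriers from single-molecule center-of-mass
(COM) trajectories.  This note records the models, their assumptions, the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Coarse-grained polymer model

The chain is a Gaussian (ideal) bead-spring polymer: `n_beads = 160` beads of
diameter sigma, bonded neighbours interacting through a FENE spring

    U_FENE(r)/kT = -(k_s r_o^2 / 2) ln[1 - (r/r_o)^2],   k_s = 30, r_o = 1.5,

plus a WCA repulsion (Lennard-Jones truncated at 2^(1/6) sigma and shifted).
Non-bonded beads do not interact.  One bead maps to one Kuhn segment of
dye-labelled DNA (134 nm), giving a contour length of 21.3 um and a projected
radius of gyration Rg = 3.9 sigma = 522 nm for the 160-bead chain.

Two FENE conventions exist in the literature; the canonical Kremer-Grest form
above (argument squared) is the default because the printed parameter pair
(k_s = 30 kT/sigma^2, r_o = 1.5 sigma) is the standard one for that form.
`SimConfig(printed_fene=True)` switches to the variant with an unsquared
argument for comparison; both bind, with equilibrium bond length near
0.97 sigma.

Posts are z-invariant cylinders of radius R on a triangular lattice with
surface-to-surface gap d; a bead at in-plane distance r from a post axis
feels

    U_PA(s)/kT = 4 eps [ (sigma/s)^12 - (sigma/s)^6 ],   s = r - R,

truncated at s = r_cutoff and shifted there so the energy is continuous
(attractive: r_cutoff = 2.5 sigma, well depth ~eps; purely repulsive:
r_cutoff = 1.12 sigma).  The cutoff shift changes the attractive well depth
by about 1.6% of eps.  The slit walls at z = 0 and z = H reflect specularly
(position mirrored, z-velocity negated).  The attraction is phenomenological:
no hydrodynamics, electrostatics, or microscopic adsorption mechanism.

### Integration and thermostat

Beads follow the underdamped Langevin equation integrated with velocity
Verlet at dt = 0.01 time units = 0.1 t_D, with friction -m*gamma*v
(gamma = 0.1) and a random force of zero mean and per-component standard
deviation sqrt(2 m gamma kT / dt), redrawn every step.  This is the
fluctuation-dissipation-consistent amplitude: it reproduces the single-bead
diffusivity D_0 = kT/(m gamma) = 10 sigma^2/time, the diffusion time
t_D = sigma^2/D_0 = 0.1, equipartition, and the free-chain (Rouse) COM
diffusivity D_0/N = 0.00625 sigma^2/t_D, all verified in the test suite.

Because gamma = 0.1, velocities decorrelate over 1/gamma = 100 t_D;
diffusivities are therefore fitted to MSD windows starting well beyond that
inertial crossover, with a free intercept.

`SimConfig(kick="uniform")` draws the random kicks from a variance-matched
uniform distribution instead of a Gaussian (the classic fast-Langevin trick:
each velocity integrates ~1/(gamma dt) = 1000 kicks per relaxation time, so
the velocity distribution stays Maxwellian).  The default is Gaussian; the
long property-test runs use uniform kicks for speed.

Positions are stored unwrapped; in-plane periodicity enters through
minimum-image distances in the post-force evaluation and when COM samples are
folded into a lattice cell for the PMF.  This keeps bonds contiguous and the
COM track directly usable by lag-based estimators.

### Critical adsorption caveat

With the correct thermostat the ideal chain is close to its critical
adsorption point at the weaker printed attraction strengths: at eps = 0.6 a
chain placed on a post desorbs within ~10^4 t_D, and trap-dominated
observables (intermediate-time MSD plateaus, a PMF barrier between distant
posts, the inversion of the long-term diffusivity trend) do not develop.
At eps = 1.0 — the strongest value in the study's eps scan — adsorption is
robust and all of those phenomena appear.  The package therefore runs its
trapping-dependent simulation checks at eps = 1.0 and treats the precise
location of the adsorption threshold as a known model discrepancy: a noise
amplitude read literally as "(2 m gamma kT/dt)^(1/2) variance" would cool the
thermostat to kT_eff ~ 0.22 and strengthen every printed eps by ~4.5x, which
would reproduce trapping at eps = 0.6 but break the fluctuation-dissipation
relation this package verifies.

### Problem sizes

Production-quality ensembles in this problem take ~10^7-10^8 t_D per state
point.  The package's own test runs use 10^5-10^6 t_D (one to a few trials),
chosen so each qualitative contrast (plateau vs linear MSD, barrier vs no
barrier, enhanced vs depleted perimeter density) is resolved well outside its
half-ensemble uncertainty; quantitative values from these short runs carry
10-30% sampling error and are asserted only with correspondingly wide
tolerances.

## Trajectory statistics

MSD uses all overlapping frame pairs at integer-multiple lags; the per-lag
uncertainty is the difference between the MSDs of the first and second halves
of the pair ensemble.  Diffusivities are MSD-slope/4 for 2-D tracks (slope/2
for 1-D displacement series) over a stated lag window with a free intercept.
Displacement-squared distributions are fitted on ln P vs r^2 by
count-weighted least squares (the semilog straight-line convention), with a
double-exponential refinement seeded from the tail region r^2 > 3 lambda_1
and a stretched-exponential alternative -ln P ~ (r^2)^beta.  The
characteristic diffusivity of a fitted scale is lambda/(4 dt).  Within-trap
fluctuations are fitted by a shifted Gaussian A exp[-(r-c)^2/w^2]; note the
convention has no factor 2, so Gaussian samples of standard deviation s
return w = s*sqrt(2).  This makes the fitted w directly exchangeable with
the HMM emission width.

## The trap-hop HMM

Displacement trajectories r(t) = |r(t) - r(0)| are modelled with hidden trap
levels j on a ladder r_0(j) = j*g, Gaussian emission weights
G_j(r) = exp[-(r - j g)^2 / w_trap^2] (the printed form omits the minus
sign; a positive exponent would make distant levels infinitely likely), and
a tridiagonal transition matrix: stay with P_trap, hop to a neighbour with
(1 - P_trap)/2 each (full P_hop to the single neighbour at the ladder ends).
Defaults g = 0.84 um and w_trap = 0.31 um are the experimentally motivated
hop scale (~Rg) and trap width.

Fitting is the count-matching Viterbi iteration: log-space max-product
decoding (ties to the lower level), transition counting, then refitting
P_trap by minimising the Frobenius distance between the observed and model
transition matrices over the rows the decoded path visited, each row
weighted by its occupation count.  The weighting matters: unweighted, a
level visited twice contributes a near-deterministic row that can outvote a
row occupied for hundreds of frames, biasing P_trap* downward and creating a
spurious second fixed point of the iteration; with count weights the
recovery of known trapping probabilities is unbiased and the iteration
converges to the same optimum from p0 = 0.1 and 0.95.  Convergence tolerance
is 1e-3 on P_trap (max 100 iterations; a period-2 cycle is detected and its
midpoint reported).

Fit quality is Pearson's chi^2/nu computed on count matrices — observed
transition counts against expected counts n_i * T_ij — over the nonzero
observed cells, with nu = (#nonzero cells) - 3.  On probability matrices the
same formula is available but lands far below 1 even for perfect fits; the
count scale is the one on which the chi^2/nu ~ 1 "good fit" criterion is
meaningful, and the suite verifies chi^2/nu ~ 1 on self-generated data and
worse values for a greedy nearest-level baseline that skips the Viterbi
pass.

The barrier to hopping follows from Boltzmann weighting of the hop
probability, dG = -ln(1 - P_trap*) in k_B T (infinite-barrier sentinel at
P_trap* = 1).  The smallest detectable trapping probability for a camera at
frame interval dt is exp(-dt * f_Nyq) with f_Nyq = frame_rate/2 (0.135 for
the study's imaging); fits below this floor describe hopping faster than the
camera resolves and are flagged.  The step-size scan reuses this floor:
ladders much finer than the data's true hop scale can shadow any trajectory
with near-free hopping (P_trap ~ 0), so sub-floor rows are excluded from
chi^2 minimum detection.

The ladder height defaults to ceil(max r / g); the number of levels actually
visited is an output, not an input.

## Free-energy barriers

Analytic model: hopping is a one-dimensional reach along the inter-post
coordinate x; an ideal coil's end-to-end fluctuation is Gaussian with
<x^2>_0 = <R_EE^2>_0/3 = 2 Rg^2, so

    beta F(x) = x^2/(2<x^2>_0) + (x - d)^2/(2<x^2>_0),
    beta F* = F(d/2) = d^2/(8 Rg^2).

The profile as printed is convex with its stationary point at x = d/2 even
though the accompanying narrative places minima at x = 0 and d; the package
reproduces the printed formula and the printed barrier values (0.45, 0.86,
1.6 k_B T for d = 1.6, 2.2, 3.0 um at Rg = 0.84 um — the middle value is
0.857 before rounding) and leaves the narrative inconsistency unresolved.

Simulation PMF: COM samples are folded into one rectangular two-post lattice
cell by translation symmetry only (no point-group averaging, since a finite
sample need not respect it), histogrammed, and Boltzmann-inverted,
U_eff/kT = -ln P(r_COM), min-shifted to zero.  Empty bins are undefined
(NaN), never clipped; the half-ensemble difference surface estimates the
uncertainty; the transect runs along the line joining nearest-neighbour post
centers, reported against distance from the post surface.  A transect whose
mid-gap region is entirely unvisited reports an undefined (effectively
beyond-resolution) barrier rather than a number.

## Synthetic data

The generators invert the analysis models exactly and are pure functions of
(config, seed): a trap-hop generator (latent ladder walk reflecting at level
0, observation noise of std w_trap/sqrt(2) so the fitted shifted-Gaussian
width returns w_trap, folded to non-negative displacement), a two-scale
variant mixing hop magnitudes g and 1.4g for the multiple-optimum scan, a
2-D Brownian track, and an i.i.d. trapped trace.  Defaults mirror the
long-term imaging protocol (1 frame / 3 s for 3000 s; P_trap per frame,
g = 0.84 um, w_trap = 0.31 um).

Passing round-trip tests on these generators shows the estimators are
correct for data obeying their own assumptions.  Real single-molecule traces
add localisation noise, bleaching-limited lengths, non-Gaussian within-trap
fluctuations and mid-flight frames during hops; none of these are emulated,
and the greedy-baseline contrast in particular is much starker on real data
than on the clean generator (see the chi^2 discussion above).

## Known limitations

- No hydrodynamic interactions or excluded volume (the chain is ideal by
  construction), no electrostatics, no microscopic adsorption mechanism.
- The adsorption threshold sits near the weaker printed attraction strengths
  (see above); quantitative eps-dependence near that threshold should not be
  trusted.
- PMF transects from a single trapped trajectory are anisotropic at short
  sampling; multi-trial ensembles are required (the pipeline concatenates
  trials for this reason).
- The detection floor takes the product dt * f_Nyq as given; the printed
  floor 0.135 corresponds to dt * f_Nyq = 2, which is not reconstructible
  from the stated frame rates alone.
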