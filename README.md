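# traphop

Transport of large flexible macromolecules (think lambda-DNA) through
slit-confined arrays of weakly attractive microposts.  In such arrays the
molecule's center-of-mass (COM) trajectory shows "trap-hop" dynamics: long
dwells adsorbed near a post, punctuated by rare hops to a neighbouring post
driven by large conformational fluctuations — and, counter-intuitively,
*denser* arrays can transport the molecule *faster*, because overlapping
attraction regions erase the inter-post free-energy barrier.

`traphop` packages the full computational tool chain for studying this
system:

- **Langevin polymer simulation** — a Gaussian FENE bead-spring chain
  (velocity-Verlet Langevin dynamics) in a slit of height `H` containing a
  hexagonal lattice of cylindrical posts with a shifted Lennard-Jones
  bead-post attraction of strength `eps`.
- **Trajectory statistics** — sliding-window MSD with half-ensemble errors,
  short/long-term diffusivities (`D = slope/4` in the slit plane), power-law
  exponents, displacement distributions `P(r², Δt)` with single, double
  (`C₁ e^{-r²/λ₁} + C₂ e^{-r²/λ₂}`) and stretched-exponential fits, and
  shifted-Gaussian trap widths.
- **Trap-hop HMM** — the Viterbi count-matching decoder: hidden trap levels
  `r₀(j) = j·g`, Gaussian emissions `exp[-(r - j g)²/w²]`, tridiagonal
  transition matrix with per-frame trapping probability `P_trap`; iterate
  decode → count → refit until `P_trap*` converges, judge the fit by
  Pearson's `χ²/ν`, and map the result to a barrier
  `ΔG = -ln(1 - P_trap*)` (in units of k_BT).
- **Free-energy barriers** — the analytic conformational-fluctuation model
  `βF(x) = x²/2⟨x²⟩₀ + (x-d)²/2⟨x²⟩₀` with `⟨x²⟩₀ = 2R_g²`, barrier
  `βF* = d²/8R_g²`; and the simulation potential of mean force
  `U_eff/k_BT = -ln P(r_COM)` over one lattice cell with inter-post
  transects.
- **Synthetic data** — generators that invert the analysis models (trap-hop
  ladders, Brownian tracks, trapped traces), standing in for unpublished
  experimental single-molecule data.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Fit the trap-hop HMM to a synthetic long-term trajectory (1 frame / 3 s for
3000 s) generated with trapping probability 0.6:

```python
from traphop import TrapHopHMM, SynthConfig, synth_traphop

traj = synth_traphop(SynthConfig(p_trap=0.6, step_size_g=0.84,
                                 w_trap=0.31, seed=1))
res = TrapHopHMM(traj, step_size_g=0.84, w_trap=0.31).fit()
print(res.summary())
```

```
            Trap-hop HMM (Viterbi iteration)
======================================================
frames                       1001
step size g                0.8400
w_trap                     0.3100
ladder levels (N+1)            32
------------------------------------------------------
P_trap*                    0.6083
P_hop*                     0.3917
dG / k_B T                 0.9373
chi2 / nu                  1.1828
iterations                      5
levels visited                 31
======================================================
```

The decoder recovers the generating trapping probability (0.61 vs 0.6); the
fit satisfies the `χ²/ν ≈ 1` quality criterion; and the implied barrier to
hopping is ~0.9 k_BT.  Compare with the analytic conformational-fluctuation
barrier for the measured in-slit radius of gyration `R_g = 0.84 um`:

```python
from traphop import BarrierModel, barrier_height

for d in (1.6, 2.2, 3.0):       # post gaps in um
    print(d, round(barrier_height(BarrierModel(gap_d=d, r_g=0.84)), 2))
```

```
1.6 0.45
2.2 0.86
3.0 1.59
```

Barriers of order k_BT, growing with gap size — the same scale and trend the
HMM extracts from trajectories.

The same workflow is available from the shell:

```bash
traphop synth --mode traphop --p-trap 0.6 --g 0.84 --w 0.31 \
    --dt 3 --duration 3000 --seed 1 traj.tsv
traphop hmm --g 0.84 --w 0.31 traj.tsv
traphop barrier --d 1.6 --rg 0.84
traphop pipeline config.yaml     # staged simulate/synth/msd/hmm/pmf/barrier
```

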