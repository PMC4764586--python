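# sptmap

Single-particle-tracking (SPT) analysis of mRNA and ribosome mobility in
live cells: from raw dual-channel TIRF movies (or pre-tracked trajectory
tables) to diffusion maps, displacement-CDF deconvolution, focal-adhesion
compartment comparisons, mRNA–ribosome co-movement statistics, and
two-state hidden-Markov motion annotation.

## The scientific problem

Whether a localized mRNA is actually being translated cannot be read off
a fluorescence image directly, but it leaves a mechanical signature:
ribosome load increases the effective Stokes radius of the particle, so
translating mRNAs diffuse more slowly and dwell in confined "hot-spots"
(notably near focal adhesions), while drug-released mRNAs speed up.
`sptmap` implements the trajectory-statistics toolbox needed to map this
signature:

- **MSD analysis.** The ensemble mean square displacement is linear in
  lag for free diffusion (slope 4D in 2-D) and plateaus for corralled
  motion; the plateau value is the *exploration area*. For a reflecting
  square corral of side L the equilibrium plateau is L²/3.
- **CDF deconvolution.** The cumulative distribution of radial
  single-frame displacements follows P(r, Δt) = 1 − exp(−r²/4DΔt) for
  one diffusive species; a two-species population follows
  P(r, Δt) = 1 − [A·e^(−r²/4D_slow·Δt) + (1−A)·e^(−r²/4D_fast·Δt)],
  which splits the population into slow (fraction A) and fast
  components — in practice D_slow ≈ 0.1 and D_fast ≈ 0.4 μm²/s for both
  mRNA and ribosomes.
- **Local diffusion maps.** Apparent D evaluated on a 20 nm grid from
  all displacements originating within 80 nm of each node (≥5 required),
  yielding heat maps of slow zones.
- **Co-movement.** An mRNA and a ribosome trajectory are co-moving when
  they stay within 320 nm for ≥3 consecutive frames (105 ms at 35 ms
  frames). The null model is the area-normalized cross-channel distance
  distribution, which is flat when the channels are independent.
- **Motion-state HMM.** A pooled two-state diffusion HMM with Rayleigh
  step-length emissions infers D1/D2 and switching kinetics from
  thousands of short tracks at once, Viterbi-annotates every step, and
  summarizes state-visit durations (optionally excluding visits censored
  by track ends).

Because raw tracking movies of this kind are rarely shareable, the
package ships a first-class synthetic-data generator (`sptmap.simkit`)
producing Brownian, two-state switching, corralled and tethered tracks,
adhesion-shaped slow zones, dual-channel co-moving pairs, and rendered
16-bit camera movies — with full ground truth retained, so every
estimator in the package is validated by parameter recovery.

## Worked example

Simulate 200 two-state tracks (D1 = 0.4, D2 = 0.1 μm²/s, mean state
lifetimes 0.5 s fast / 1.3 s slow, 35 ms frames) and analyze them:

```python
from sptmap import simkit, diffusion, state_switch

cfg = simkit.SimConfig(rng_seed=1, localization_sd=0.0, n_frames=101)
motion = simkit.MotionSpec(kind="two_state", D1=0.4, D2=0.1,
                           k12=2.0, k21=1 / 1.3)
tracks, truth = simkit.simulate_tracks(cfg, motion, 200, track_length=101)

d = diffusion.collect_displacements(tracks, 1, cfg.frame_interval)
one = diffusion.fit_cdf_one(d)
two = diffusion.fit_cdf_two(d, fix_D=(0.1, 0.4))
model = state_switch.fit_hmm(tracks, K=2, frame_interval=cfg.frame_interval,
                             seed=0)
```

This prints:

```
pooled displacements: 20000
one-component D_app : 0.142 um^2/s
slow fraction A     : 0.725 (D fixed at 0.1/0.4)
HMM D1, D2          : 0.394, 0.098 um^2/s
state lifetimes     : 0.56 s (fast), 1.39 s (slow)
```

Reading the numbers: the single-coefficient fit lands between the two
true coefficients (0.142 μm²/s) because the population is a mixture —
exactly the situation the two-component fit resolves. With the two
coefficients held at the shared 0.1/0.4 μm²/s convention, the fitted
slow fraction (0.725) matches the occupancy implied by the switching
rates, k12/(k12+k21) = 0.72. The pooled HMM recovers both coefficients
within a few percent and the fast/slow state lifetimes near their true
0.52 s / 1.32 s discretized means.

A full synthetic run (simulate → diffusion fits → heat map →
compartments → co-movement → HMM → report) is one command:

```bash
sptmap run-all --config run.yaml
```

with a declarative YAML config; `sptmap --help` lists the individual
stage subcommands (`simulate`, `detect-link`, `diffuse`, `map`,
`compartments`, `comove`, `hmm`, `report`).

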