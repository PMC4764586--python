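# Methods

This note documents the models, estimators, numerical choices and known
limitations of `sptmap`, in the order data flows through the package.

## Coordinate and unit conventions

Positions are in μm with the origin at the top-left of the field, x
rightward and y downward (image convention); pixel (i, j) covers the
half-open square [j·p, (j+1)·p) × [i·p, (i+1)·p) μm for pixel size p.
Trajectory tables are pandas DataFrames with columns
`track_id, frame, x_um, y_um, channel`; frames are 0-based integers.
Defaults follow a streaming TIRF acquisition: frame interval Δt = 35 ms,
pixel size 107 nm, 500 frames.

## Synthetic data (`simkit`)

The generator produces the trajectory populations the estimators are
designed for, with ground truth retained per track, per step and per
pair. Motion models:

- **Brownian**: per-frame Gaussian steps of variance 2·D·Δt per
  coordinate.
- **Two-state switching**: a per-step Markov chain between a fast state
  1 (D1 = 0.4 μm²/s default) and a slow state 2 (D2 = 0.1 μm²/s), with
  per-frame transition probabilities 1 − e^(−k·Δt) from continuous
  rates; the chain starts at its stationary distribution, so the state-2
  occupancy is k12/(k12+k21) up to discretization.
- **Confined**: diffusion inside a reflecting square corral. The wall
  reflection is implemented by *folding* the free Gaussian proposal into
  [0, L] (method of images). Folding gives the exact single-frame
  transition density of reflected Brownian motion, so no sub-stepping is
  needed and the long-lag ensemble MSD converges to the equilibrium
  value 2 × 2 × Var(Uniform[0, L]) = L²/3 — the oracle used throughout
  the tests. Tracks start uniformly inside the corral (equilibrium
  initialization).
- **Tethered**: a stationary anchor plus i.i.d. Gaussian jitter,
  emulating immobilized particles.

Track lengths are geometric (memoryless bleaching) with a configurable
mean, default 6.2 frames ≈ 200 ms; the published lifetime parameters of
real acquisitions are not known numerically, so this default is nominal.
Localization error (default 25 nm per coordinate, a typical
single-molecule precision) is added to *reported* positions only,
keeping the true walk Markovian — the standard SPT error model. Free
tracks live in an unbounded plane; only movie rendering clips to the
field, avoiding artificial confinement.

Adhesion-shaped slow zones are non-overlapping ellipses (2:1 axis
ratio, random orientation); a particle's step variance switches between
D_near and D_far according to its current true position. Dual-channel
co-moving pairs: a configurable fraction of mRNA tracks is shadowed by a
ribosome partner whose position is the mRNA's reported position plus
i.i.d. Gaussian jitter — the minimal model that satisfies the
co-movement distance criterion by construction; the partner has no
independent diffusion about the tether.

Movies render each localization as an integrated 2-D Gaussian PSF on the
pixel grid with Poisson noise on signal + background, 16-bit output.
Photophysics beyond shot noise (blinking kinetics) and directed/motor
transport are deliberately not simulated by default; a drift state for
model-selection exercises can be built from the primitives but is not a
default scenario.

**What passing tests show about real data.** The generator reproduces
the statistical structure the estimators assume (Gaussian increments,
memoryless bleaching, additive localization error, hard corral walls).
It does not emulate motion blur within the 35 ms exposure, non-uniform
background, out-of-focus PSF changes, camera registration error between
channels, or heterogeneous per-cell parameter variation — recovery on
synthetic data therefore validates the estimators' correctness, not the
full error budget of a live-cell experiment.

## Detection and linking (`detect_link`)

Frames are median-background-subtracted and smoothed with a Gaussian
filter parameterized by its half-width-at-half-maximum (default 1.3 px;
sd = HWHM/√(2 ln 2) ≈ 1.104 px). The detection threshold is a multiple
(default 5×) of the robust background noise, 1.4826 × the median
absolute deviation of the filtered image — a default to be overridden
per data series where needed. Candidate maxima are refined by local
least-squares 2-D Gaussian fits in 7×7 windows; saturated windows are
kept but flagged; detections closer than 2×HWHM merge to the brighter
one. Maxima within ~1 px of the frame border are excluded by the peak
finder.

Linking is globally greedy nearest-neighbour: all frame-to-frame pairs
within the displacement cap (default 5 px ≈ 533 nm) are sorted by
distance (ties broken by detection index) and accepted when both
endpoints are unused. There is no gap closing — a particle lost for one
frame starts a new track, which is conservative for diffusion
statistics. Tracks with fewer than 3 localizations are dropped on
export, so the shortest exported lifetime is 3·Δt = 105 ms. The greedy
rule is deterministic and documented; no equivalence with any
proprietary tracker is claimed.

## Displacement statistics (`diffusion`)

All CDF fitting uses lag-1 (single-frame) displacements, pooled over
tracks with overlapping windows. Single-lag is the conservative choice:
it keeps displacements nearly independent and matches the 35 ms
timescale of the diffusion maps. The empirical CDF (statsmodels ECDF,
right-continuous) is evaluated at 200 evenly spaced quantiles of the
data, and models are fitted by least squares on that grid — a
sample-size-independent objective. The quantile grid concentrates
evaluation points where the data are, which weights the fit similarly to
maximum likelihood without binning choices.

- One-component model: P(r, Δt) = 1 − exp(−r²/4·D_app·Δt); D_app is
  optimized in log-space over [10⁻⁴, 10] μm²/s (bounded scalar
  minimization).
- Two-component model:
  P = 1 − [A·e^(−r²/4·D_slow·Δt) + (1−A)·e^(−r²/4·D_fast·Δt)], fitted
  over (A, log D_slow, log D_fast) from three starts; the labels are
  swapped after fitting if needed so D_slow < D_fast always holds, and a
  fit with A at a boundary is flagged rather than rejected.
  `fix_D=(0.1, 0.4)` holds the coefficients at the shared two-species
  convention and fits only A, which is how conditions are compared;
  whether published analyses refit the coefficients per condition is
  ambiguous, so both modes are exposed.

Coefficients are *apparent*: localization error is not subtracted, in
keeping with the field's D_app convention; the HMM below uses the same
convention so the two are directly comparable.

The ensemble MSD pools all overlapping-window displacements per lag;
error bars are standard errors over per-track mean squared
displacements, treating tracks as the independent units. The
exploration area is the mean MSD over the last third of lags; if the
window slope still exceeds 10% of the initial slope the result is
flagged "no plateau" instead of being reported as an area. Per-track
apparent D uses lag-1 only, which stays well-defined for the dominant
3-frame tracks. Track lifetime is n_localizations × Δt (so a 3-frame
track has lifetime 105 ms).

Group comparisons (adhesion vs non-adhesion, co-moving vs free) use
two-sample Kolmogorov–Smirnov tests on per-track D_app at α = 0.01; the
percent slowdown is 100·(1 − D_slow_class/D_fast_class) from the
one-component fits.

A small helper (`sptmap.translation`) converts a protein length and a
ribosome elongation rate into a translation time (375 aa at 5.6 aa/s →
67 s), the yardstick against which second-scale motion-state lifetimes
are judged.

## Spatial maps (`spatial_maps`)

The local-diffusion map assigns every lag-1 displacement to each grid
node (20 nm spacing) within the capture radius (80 nm) of the
displacement's *origin* — the literal reading of displacements
"originating" near a node. A node needs ≥5 assigned displacements to be
defined; its value is mean(r²)/(4Δt). Because the capture radius
exceeds the spacing, one displacement contributes to ~50 nodes — an
intentional smoothing. Nodes sit on the absolute grid (integer multiples
of the spacing), so translating the data by one spacing translates the
map by exactly one node. Whether a per-node CDF fit would be preferable
to the mean-r² estimator is an open choice; mean-r²/(4Δt) is the
minimal unbiased reading and is what the homogeneity tests validate
(within 3% on uniform fields). Density maps are plain 2-D histograms of
localizations with half-open bins, extended past the data so every
point lands in exactly one bin.

## Compartments (`compartments`)

No published recipe exists for delineating adhesions from a marker
channel, so the segmentation is the module's own and fully
parameterized: Gaussian smoothing (sd 1 px), Otsu threshold, and removal
of components below a minimum area (default 0.05 μm²). Touching
structures are not split. Track partitioning is *track-level*: a track
is "adhesion" if any localization (configurable fraction) falls inside
the mask dilated by 160 nm ≈ 1.5 px — a declared default for "the
vicinity of adhesions", not an inferred one. Step-level spatial detail
is already provided by the diffusion maps. Adhesions are treated as
static over an acquisition.

## Co-movement (`comovement`)

A cross-channel pair is co-moving when there exist ≥3 *consecutive*
frames in which both particles are localized and their distance is
≤320 nm in every frame — the stringent reading of the criterion (3
frames ≡ 105 ms of continuous proximity; the printed 320 nm is kept
rather than 3 × 107 = 321 nm). The reported window is the maximal
qualifying run. Matches are many-to-many by default (one mRNA may pass
several activated ribosomes); greedy longest-overlap exclusivity is
optional. Per-frame candidate search uses a k-d tree, near-linear in
detections. Channel registration is assumed exact.

The colocalization null: the histogram of all cross-channel distances,
divided per bin by its annulus area π(r_out² − r_in²), is flat in r if
the channels are spatially independent; co-movement appears as a
short-distance (<3 px) peak above that flat baseline. A χ² test against
area-proportional expected counts (bins with expectation ≥5) quantifies
flatness. Near the field edge the annulus normalization overcorrects;
tests keep r_max well below the field size.

## Motion-state HMM (`state_switch`)

Emissions are displacement magnitudes: given state k, r is Rayleigh,
p(r|D_k) = r/(2·D_k·Δt)·exp(−r²/4·D_k·Δt) — equivalent to the 2-D
Gaussian step model under isotropy and simpler to validate.
Localization error is not modelled (apparent-D convention). Parameters
(D_k, row-stochastic per-frame transition matrix T, initial distribution
π) are *pooled*: shared across all tracks, estimated by Baum–Welch EM
with each track an independent sequence. The forward–backward pass is
scaled (not log-space) and vectorized over equal-length sequence
batches; the D update has the closed form Σγr²/(4ΔtΣγ). Convergence:
relative log-likelihood change < 10⁻⁸ or 500 iterations; best of
n_restarts randomized initializations wins. States are relabelled by
decreasing D (state 1 = fast D1, state 2 = slow D2). A state holding
<1% of posterior mass flags the model degenerate.

Model order is chosen by BIC, −2·logL + p·ln(n_steps) with
p = K + K(K−1) + (K−1) — a deliberately simple, documented criterion.
On well-separated states (4-fold D contrast) it makes the same
one-vs-two-state decision as Bayesian-evidence methods; numerical
equivalence with variational-Bayes HMM implementations is not claimed,
and no per-track model selection or >2 diffusive states are offered.

Per-track annotation is Viterbi decoding; state visits are maximal runs
of one label, with visits touching the first or last step marked as
boundary visits. Mean state lifetimes are reported as Δt/(1 − T_kk),
the mean of the geometric holding time; note this targets the
discretized value Δt/(1 − e^(−kΔt)), which exceeds the continuous 1/k
by ~Δt/2 (3.5% at k = 2 s⁻¹, Δt = 35 ms). Duration histograms can
exclude boundary visits, whose durations are censored by the finite
track length; internal-only means still carry a mild downward bias for
lifetimes comparable to track length.

## Pipeline and problem sizes

`run_pipeline` executes simulate → diffusion → maps → compartments →
co-movement → HMM from one YAML config; identical config + seed gives
byte-identical artifacts (all randomness flows from `numpy`
`default_rng(seed)`). Reports embed a config hash and package version.

Validation problem sizes were chosen so each statistical check is
decisively powered while the whole suite stays desk-scale: 10⁵ pooled
displacements for one-component recovery (bias < 2%), 3×10⁴ for
mixture-fraction recovery (±0.05), 500 tracks × 100 frames for
exploration-area recovery (±5% of L²/3), 2×10⁴ pooled steps for HMM
recovery (D within 10%, lifetimes within 20%), and ≥10⁴ cross-channel
distances for the flatness null.

## Known limitations

- No drift correction, gap closing, multi-emitter fitting or 3-D
  localization in the detection/linking stage.
- No anomalous-diffusion exponent fitting; confinement is diagnosed via
  the plateau and mixture fits only.
- The CDF fits assume displacement independence; overlapping MSD windows
  make neighboring-lag MSD values correlated (error bars per lag are
  still valid across tracks).
- Intensity-based stoichiometry (ribosomes per mRNA) is out of scope:
  sparse photoactivation tracking cannot observe absolute copy numbers.
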