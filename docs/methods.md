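# Methods

## The problem

In coherent X-ray diffraction imaging a spatially isolated, non-crystalline
particle is illuminated by a coherent beam and the far-field intensity is
recorded under oversampling conditions. The measurement yields Fourier
*amplitudes* only; the projected electron density must be recovered by
iterative phase retrieval. Real detectors lose data — a central beamstop
hides the lowest spatial frequencies, panel gaps cut stripes through the
pattern, strong reflections saturate pixels, and weak high-angle signal is
Poisson-noisy — so independent phase-retrieval trials frequently stall in
distinct, mutually inconsistent local minima, and only a fraction of trials
produce a map that resembles the true particle.

`steerpr` implements an ensemble protocol that addresses this: many trials
run in lock-step, are periodically paused, scored pairwise with a
similarity metric, and nudged toward a consensus built from the
best-agreeing maps.

## Single-trial engine

Each trial iterates the classic two-projection loop on an `m x m` grid
(zero-frequency at `(m/2, m/2)`):

1. `G = FT(rho)`;
2. reciprocal-space constraint: wherever the detector recorded valid data,
   `G' = |F_obs| * G/|G|` (phase kept, modulus replaced); invalid pixels
   (beamstop, gaps, saturation) are left completely unconstrained; a valid
   pixel with `|G| = 0` takes phase 0;
3. `rho' = Re FT^-1(G')`;
4. hybrid input-output (HIO) real-space update with feedback `beta = 0.9`:
   pixels inside the support with `rho' >= 0` take `rho'`; all others take
   `rho - beta * rho'`.

The initial support is the autocorrelation of the measured intensities
(invalid pixels zeroed) thresholded at 4% of its maximum; the initial map
is uniform random density inside that support. Every 100 cycles the
support is re-estimated by shrink-wrap (SW): blur the current map with a
periodic unit-mass Gaussian of standard deviation `zeta` pixels and keep
pixels at or above 4% of the blurred maximum.

Two `zeta` schedules:

* **ordinary** — geometric decay `2.0 * 0.99^(h-1)` per SW update,
  floored at 0.9 px. The decay rate is a package choice (the floor, start
  value and cadence are protocol constants); any slow decay to the floor
  behaves equivalently.
* **adaptive** (used by steered ensembles) — track the oversampling ratio
  `sigma = (grid area)/(support area)` at each SW event. While
  `|sigma_l - sigma_(l-1)| >= 2` (or on the first event, where no previous
  ratio exists) keep `zeta = 2`; once the change falls strictly below 2,
  drop to `zeta = 0.9` and latch there permanently. The wide-blur phase
  keeps early supports smooth so that the trial population stays spread
  out; the latch event marks the moment a trial's support has stabilized.

### Which density the support and the reports see

The raw HIO state intentionally carries density outside the support and
negative excursions — that is the feedback memory that lets HIO escape
local minima, not physical density. On noisy data this residue does not
decay with iteration; it oscillates at a level set by the measurement
noise (roughly 10% of the object height at the benchmark photon budget).
Two consequences drive the engine's conventions:

* **Shrink-wrap blurs the Fourier-consistent map** `max(rho', 0)`, not
  the raw state. Thresholding the blurred raw state makes the support
  churn between a few hundred and a few thousand pixels on noisy
  patterns and recovery collapses (benchmark similarity vs truth
  ~0.3–0.6); blurring `rho'` lets the support shrink onto the particle
  and the same trials reach ~0.04–0.11.
* **Reported maps** (snapshots, final maps, anything scored, averaged or
  analyzed) are the clipped Fourier-consistent density restricted to the
  support, `max(rho', 0) * support`. On a complete noiseless pattern
  this reproduces the phantom essentially exactly (similarity T < 1e-3
  in 10/10 test seeds), whereas the raw state plateaus near T ~ 0.15
  from out-of-support residue alone.

The steering modification, by contrast, blends the *raw* state, so the
feedback memory survives a modification scaled by `1 - w`.

### OSS refinement

The oversampling-smoothness variant replaces the out-of-support density of
the HIO output by its Gaussian low-pass filtered copy (frequency window
`exp(-k^2/(2 eta^2))`), with `eta` stepping down linearly from `m` to
`1/m` in 1000-cycle blocks. OSS trials keep an externally supplied support
fixed (no shrink-wrap); the intended workflow seeds that support from the
final map of a lowest-similarity pair of a previous ensemble.

## Similarity score and alignment

For non-negative maps (negatives clipped first),

    T_ij = sum |rho_i - rho_j| / sum (rho_i + rho_j)

so `T = 0` for identical maps, `T = 1` for maps with disjoint supports.
Empirically, pairs with `T < 0.2` both approximate the true particle; a
converged steered ensemble peaks near `T ~ 0.1`.

Because a map and its point reflection have identical diffraction
amplitudes (Friedel symmetry), and translation is unconstrained by the
amplitudes, every comparison first aligns: coarse center-of-gravity shift,
then exhaustive integer-pixel search within +-5 px for both the map and
its pi-rotation, minimizing `T`; ties prefer the smaller shift, then the
un-rotated orientation. Sub-pixel registration is deliberately not used:
integer shifts keep every score exactly reproducible, at the price of a
small registration floor (a half-pixel offset between two copies of a
disk-aggregate map costs `T` up to ~0.15–0.18). Ensemble members retrieved
from the same data typically settle on a common sub-pixel register, so
pairwise scores are barely affected; comparisons against an externally
rasterized ground truth can sit on this floor, which is why the realistic
threshold (0.2) is well above it.

## Steered ensemble

`N` trials (production scale: three sets of 280; the test scale is 16)
advance in logical lock-step with the adaptive SW rule. Once every live
trial has latched at `zeta = 0.9`, and after 100 further cycles (rounded
to the SW cadence), the first modification runs; modifications then repeat
every 500 cycles until cycle 9000, after which only HIO cycles run (no
further SW either). Between consecutive modifications exactly four SW
updates fire (+100 ... +400).

At each modification stage `s`:

1. score all pairs after center-of-gravity alignment (better of the two
   pi-orientations);
2. the lower-index member of the minimal-`T` pair becomes the reference;
   all other maps are optimally re-aligned to it and re-scored;
3. the consensus map `rho_bar` is the *unweighted* pixel-wise mean of all
   reference-aligned maps with `T < 0.2` against the reference (the
   reference itself always qualifies), rescaled to the mean contributing
   mass. Similarity-weighted averaging such as `1 - T_ij` is deliberately
   avoided: the score correlates with structure-factor phase differences,
   and down-weighting by it biases the consensus. Membership is per map
   (`T` vs the reference below threshold), not per pair — per-pair
   counting would multiply-count maps that happen to sit in many
   qualifying pairs;
4. every trial's state is aligned to the reference frame, blended as
   `(1 - w_s) * rho + w_s * rho_bar`, and mapped back to its own frame.
   The weight ladder is `w_s = min(0.05 s, 0.50)`; after stage 10 it holds
   at 0.50 until the modification stop. The slow ramp protects the early
   ensemble from a spuriously self-consistent pair of wrong maps;
5. the modified state is not re-projected onto support/positivity — the
   next HIO cycle enforces the constraints.

Steering never touches the measured amplitudes or the validity mask, only
the real-space states. Lock-step is a logical contract: trials are
advanced sequentially between barriers, so an ensemble is bit-reproducible
given (pattern, config, seeds) regardless of any execution concurrency.

Failed trials (an SW update that empties the support) are recorded,
dropped from scoring and steering, and do not stop the ensemble.

### Convergence and termination

Per stage, the histogram of all pairwise scores (bin width 0.02) is
recorded. The run is declared converged when the 3-bin moving-average
smoothed histogram has exactly one local maximum, centered in
`0.05 < T < 0.2`, with full width at half maximum below 0.1 (flat-topped
peaks count once; the plateau middle is the center). Optionally, if no
pair scores below 0.2 for three consecutive stages, the ensemble
terminates early — continued modification from a consensus no one agrees
with only wastes cycles.

## Trajectory analytics

Final maps, mutually aligned, are rows of a mean-centered matrix whose
first two principal components span the analysis plane (deterministic
sign: the largest-magnitude coordinate of each component is positive).
Snapshot trajectories — including those of a steered run — are projected
onto this plane; a 2D histogram of projected positions gives the
visit-frequency map; seeded K-means (default `K = 3`, matching the three
basins typically observed) counts the occupied regions. In synthetic mode,
the fraction of final maps with aligned `T < 0.2` against the known
phantom replaces manual inspection of which region is realistic. Both map
and truth are normalized to unit total mass before that comparison,
because reconstructions inherit the arbitrary photon-count scale of the
measured amplitudes.

## Synthetic data

The simulator emulates the two specimen classes of interest:

* **disk aggregates** — `n` equal-diameter disks of uniform density
  (default contrast 1), placed without overlap (touching allowed) at
  integer positions inside the central half-window of the field; a proxy
  for aggregates of 200–250 nm colloidal gold particles, whose known
  shape makes reconstruction quality easy to judge;
* **projected ellipsoids** — chord-length profile
  `contrast * 2c * sqrt(1 - x^2/a^2 - y^2/b^2)` with the projection-axis
  semi-axis equal to the short one, plus optional seeded internal texture;
  at 20 nm/px, axes of 17 x 21 px emulate a 340 x 420 nm cell nucleus,
  the low-contrast regime.

The forward model zero-pads the phantom by the oversampling factor
(default 2, i.e. a 64 px phantom yields a 128 x 128 pattern) and takes
the centered DFT modulus; Parseval's identity and Friedel symmetry hold
exactly. Degradation scales intensities to an expected total photon
budget (default benchmark: 1e7 photons), Poisson-samples per-pixel
counts (`amplitude = sqrt(counts)`), and invalidates the central
beamstop disk (benchmark radius 3 px), listed gap rows (one stripe), and
pixels at or above the saturation level. Saturation is invalidation, not
clipping — saturated regions carry no usable constraint.

What the simulator does *not* model: detector point-spread and
panel-to-panel gain, partial coherence, background/parasitic scattering,
multi-detector merging artifacts, and specimen-membrane contrast. Passing
benchmarks therefore demonstrate the protocol's behavior under ideal-
detector assumptions with realistic missing-data topology and shot noise,
not performance on raw facility frames.

## Benchmark scales and numerical choices

* Test-scale benchmarks use 64 px phantoms (128 x 128 patterns), 16-trial
  ensembles and 2000–3000 cycles, sized so the whole pipeline runs on one
  CPU in minutes; the protocol constants (cadences, thresholds, ladders)
  are unchanged from the production values.
* All FFTs are numpy's; periodic boundaries everywhere (the blur uses
  wrapped convolution, so total mass is conserved to machine precision).
* An OS-ratio change of exactly 2 keeps the wide blur (strict `< 2`
  switches).
* Degenerate cases raise: empty supports, zero-mass maps in alignment,
  all-invalid patterns, `w` outside [0, 1].
* Ordinary ensembles derive every trial's initial support from the same
  autocorrelation (it is a deterministic function of the pattern);
  trial-to-trial diversity comes from the random initial maps.

## Known limitations

* Integer-pixel alignment leaves a sub-pixel registration floor in scores
  against external references (see above).
* The adaptive-SW latch can, on easy data, fire on the very first pair of
  SW events, triggering steering earlier than the 500–1000-cycle window
  typical of noisy experimental patterns.
* `K` for K-means region counting is user-supplied; the package does not
  estimate it.
* 2D (projection) reconstruction only; no partial-coherence or detector
  PSF modeling; no multi-node scheduling.
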