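# Methods

This note records the modelling and numerical choices behind
`scsift`: what the circuit model and the synthetic populations assume,
which parameters matter, and what the test suite does and does not
establish about real recordings.

## Stimuli

All stimuli are Weber-contrast fields on a gray background, values in
[−1, +1] (0 = gray), sampled at 1°/pixel and 60 Hz (both
configurable).  Disks are rasterized without anti-aliasing: a pixel
belongs to the disk iff its center lies within the radius, which makes
pixel counts exactly reproducible and oracle-checkable.  Frame *k*
shows the stimulus state at time *k*/rate, so the first looming frame
(zero diameter) is exactly gray.

The standard loom expands from 0° to 30° diameter at 60°/s of diameter
growth and holds 250 ms; contracting disks run the same geometry in
reverse with the stationary period (now an empty field) at the end;
the dimming disk ramps a fixed 30° disk linearly to full darkness over
the looming duration; the moving disk translates at 55°/s along a
straight path centered on the requested location.  Checkerboards are
~3° binary checkers redrawn independently every frame from a seeded
generator; they are stored as seed + parameters and re-rendered on
demand.  Protocols (ordered, temporally disjoint events) serialize to
JSON.

## Circuit model

### LN units

Each input unit computes `g(t) = s * (F·T)` followed by
`N(g) = max(0, m·g − θ)` with `m = 1`, `θ = 0`.  Temporal kernels
(fitted to mouse alpha retinal ganglion cells; seconds):

| | τ₁ | n₁ | τ₂ | n₂ | b |
|---|---|---|---|---|---|
| center | 0.104 | 2.77 | 0.0912 | 3.94 | 1.34 |
| surround | 0.0846 | 1.24 | 0.0797 | 1.87 | 1.33 |

Two conventions required decisions the parameter table does not fix:

- **Polarity.**  With these parameters `T(t)` has a *negative* leading
  lobe followed by a positive rebound — the shape of an Off cell's
  spike-triggered average read as a causal filter.  The kernel is
  therefore applied to the raw contrast: a luminance decrement yields
  a positive transient drive with ~100 ms latency.  (Negating the
  stimulus, the textbook "Off" recipe for positive-leading kernels,
  double-flips the polarity here and produces a rebound-driven
  response that starts only after the expansion ends.)
- **Spatial normalization.**  The Gaussians are normalized to unit L2
  norm, giving the surround an effective gain σ_s/σ_c = 2.5 relative
  to the center.  This choice is load-bearing: with unit-peak
  Gaussians the surround collects (σ_s/σ_c)² ≈ 6× the center's input
  and vetoes everything including the loom; with unit-volume
  normalization it is too weak to veto translating or off-center
  stimuli (≈5% of the centered response leaks to detectors 15° away,
  destroying habituation specificity).  Energy normalization yields a
  detector with zero measured cross-talk at 15° and the intended
  figural selectivity.

Temporal kernels are truncated at 500 ms; no spatial truncation is
needed because events are rendered on bounded grids and the stimulus
is zero elsewhere.

### Looming detectors and widefield pooling

`r_LD = N(r_c − r_s)` with both rates rectified before subtraction.
Detectors sit on a 5×5 grid, 15° spacing, and pool additively onto the
widefield unit with uniform anatomical weights and plastic gains
`w_i ∈ [w_min, 1]`, all initialized fully recovered (w = 1).

### Rate units and the depression dose

The model's rate units are arbitrary, but Eq.-level depression makes
their scale meaningful: with gain `a`, one stimulus multiplies a
synapse's weight by `exp(−a∫r dt)`.  Rates are normalized so that the
time-integrated detector response to the standard centered loom equals
`loom_response_integral = 4`; with `a = 1` one loom therefore drives
its synapse to `e⁻⁴ ≈ 0.02` — near-complete single-trial habituation,
with the burst itself visibly quenched by depression within the trial.
Normalizing the *peak* rate to 1 instead would give a per-trial dose
of only ~0.2 and almost no habituation; this is why the integral, not
the peak, is the normalized quantity.

### Recovery time constant

τ is not part of the published parameter set.  The default τ = 180 s
makes the simulated recovery fraction at the longest probed interval
(121 s) come out just below 50%, matching the observation that deep
neurons do not recover beyond half their naive response after ~2 min.
It is a configuration field (`tau_rec_s`) and the single most
influential free parameter for any recovery analysis.

Note that the recovery-series fractions r_i/r_1 are *not* monotone in
ISI at the short end: the 1.5 s probe starts from a singly-depressed
synapse while later probes start from deeper accumulated depression,
so the second fraction dips below the first.  This is a property of
the protocol, not an integration artifact.

### Integration

The weight ODE is advanced with an exponential update that is exact
for a rate held constant within a frame (`w ← w∞ + (w − w∞)e^{−BΔt}`
with `B = 1/τ + a·r`).  It is unconditionally stable, needs no
sub-stepping, keeps `w` inside `[w_min, 1]` for any step size, and
makes step-halving a strict no-op — which the suite asserts.
Simulations advance synapses continuously through events and gray
gaps; long silent stretches use the closed-form recovery directly.

### What the model reproduces, and one caveat

With the defaults, the simulated detector/widefield system shows:
looming selectivity at the detector (centered loom > contracting
white, expanding white, dimming, translating disks, integrated over
the stimulus period); position invariance (CV of the widefield
response over fresh looms at the interior grid points < 10%, onset
latency identical to one frame); near-complete location-specific
habituation (10th repeat < 2% of the first; an adjacent fresh
location at 100%).

Caveat: at the *pooled* widefield level a contracting white disk still
elicits a response, because its inward-sweeping rim genuinely drives
the ring of detectors 15° from the center — those detectors see a
local dark edge arriving with no surround warning.  The selectivity
claim of the model therefore holds at the local-detector stage (which
is also where the original simulation made it), not for the raw pooled
sum over the grid.

## Synthetic populations

The generator emulates the empirical layer contrast, not any
particular recorded neuron:

- **sSC neurons** are single LN units (center temporal kernel, σ drawn
  from 2–5°) whose drive is full-wave rectified — any local contrast
  change excites them, giving broad figural tuning, reliable repeats,
  checkerboard responsiveness, and loom latencies that depend on when
  the edge reaches the receptive field.  Centers tile the 60° span on
  a jittered lattice.
- **dSC neurons** share the widefield circuit drive, inheriting
  looming selectivity, wide fields, invariant latency and
  location-specific habituation by construction, plus a small fixed
  per-neuron latency jitter.

Rates are `baseline + gain × normalized drive`.  Baselines are
log-uniform over 0.1–15 Hz (covering both the sub-1-spike background
regime the significance floor addresses and maintained firing).
Gains are uniform over 100–200 Hz, i.e. burst-like responses of
~20–60 spikes per stimulus period; the dSC drive is normalized by the
peak of the *depressed* naive loom response so that a first loom
peaks at the neuron's gain.  Spikes are drawn by thinning a
piecewise-constant-rate Poisson process (exact for this rate class;
validated by a time-rescaling Kolmogorov–Smirnov test).  There is no
refractory period, no spike-sorting noise, no behavioural covariates
(locomotion, pupil), and no correlated trial-to-trial variability:
passing tests show the analyses behave correctly under their own
Poisson assumptions, not that real SC data meet those assumptions.

A statistical consequence worth knowing: with ~20-spike bursts the
single-trial habituation index `1 − r_10/r_1` of a non-habituating
neuron has an SD of ≈ √(2/N) ≈ 0.3, so individual sSC indices scatter
well beyond ±0.25 even though their median sits at 0; the tests
therefore hold sSC below the 0.75 separator per seed and below 0.25
in the median.

## Single-neuron metrics

- Background μ: spikes in the 5 s (configurable) before onset, scaled
  to the stimulus duration; truncated (and flagged) at the recording
  start.  With short ISIs the window deliberately includes preceding
  trials, as in the experimental design.
- Poisson test: p = P(X ≥ r′) with the model mean floored at 1 when
  μ < 1; upper tail computed by the survival function, matched to a
  direct tail-sum oracle to 1e−12.  The test is conservative for
  discrete counts (null calibration asserted at ≤ α).
- Indices use background-corrected counts clamped at zero, making the
  habituation index exactly 1 for complete habituation and keeping
  selectivity within [−1, 1]; clamping only the lower side preserves
  facilitation (negative habituation indices).
- Receptive-field size: per-location maximum significant corrected
  response (Bonferroni over presentations), response-weighted center
  of mass, size = 2×(mean radial distance) + grid spacing — the
  spacing term encodes the 15° resolution floor of the measurement.
- Latency SD uses the sample (n−1) denominator over significant
  trials with first spikes ≥ 30 ms after onset; neurons qualify only
  with background below one spike and ≥ 5 significant trials.

## STA and SVD

STAs average the `n_lags` (default 30, i.e. 500 ms at 60 Hz) frames
preceding each spike, per-spike (spikes sharing a frame each count).
The (lag × space) unfolding is decomposed by SVD; components carry
unit-norm spatial maps with amplitudes on the temporal courses, and
the sign ambiguity is fixed by orienting each temporal course's
near-spike extremum negative (the Off convention, matching the large
Off majority among checkerboard-responsive neurons).  A 300 s
checkerboard suffices to recover a simulated unit's field center to
within one checker and its temporal kernel at |r| > 0.9.

## Decoding

Logistic regression (L2, C = 1, iteration cap 5000, multinomial for
the 25-way location task) on raw spike counts, scored by mean 4-fold
cross-validated accuracy; folds are stratified when every class allows
it, otherwise seeded shuffled folds redrawn to cover all classes in
training.  No feature scaling.  Chance levels are label statistics:
max-location share (location) and non-novel share (novelty).

Virtual-neuron augmentation shifts a neuron's response profile to the
eight 3×3-neighbourhood offsets; retention requires the shifted
significant-response profile to stay inside the presentation grid, and
responses are relabeled from the source's trials at the shifted
location, matched in order of occurrence (trials mapping off-grid draw
from the source's background-only locations).  For wide-field dSC
profiles whose support spans the whole grid, only the unshifted copy
survives this rule, so the default dissociation analysis uses real
populations large enough (≥ 300 per layer) not to need augmentation.

The subsampling analysis at 300 neurons per layer uses 20 subsamples
by default (the separation between layers is tens of SDs, so the
subsample SD is estimated adequately); reps are configurable.

## Problem sizes

Defaults throughout are desk-scale by design: 100-trial protocols,
5×5 grids, 300 s checkerboards, populations of hundreds, 1000-protocol
chance-level simulations.  All were chosen so a complete run of the
suite plus the acceptance script executes in well under an hour on one
CPU while keeping every statistical check far from its decision
boundary (except where a boundary is the point, as documented above).
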