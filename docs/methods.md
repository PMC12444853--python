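# Methods

This note documents the models implemented in `drgfilter`, the default
parameters and why they were chosen, the numerical conventions, and the
scope and limits of the synthetic validation.

## 1. Signal model

A dual-site recording consists of two extracellular voltage traces sampled
at a common rate (30 kHz in all bundled scenarios): the spinal nerve (SN)
channel upstream of the dorsal root ganglion and the dorsal root (DR)
channel downstream, separated by a fixed electrode distance (default 4 mm).
Each sensory unit fires a train of action potentials on the SN; each spike
either propagates through the DRG T-junction — appearing on the DR after a
conduction latency `distance / velocity` — or fails. The quantity of
interest is the per-unit (and per-fiber-class) failure fraction.

## 2. Preprocessing (`preprocess`)

* **Filter**: Butterworth high-pass, corner 60 Hz, order 4, applied with
  `scipy.signal.sosfiltfilt` (second-order sections for numerical stability,
  forward–backward for zero phase). Zero-phase filtering matters because
  spike *times* are the primary measurement; a causal filter would shift SN
  and DR channels by the same group delay only in the ideal case, and any
  differential shift would bias latency, hence velocity and fiber class.
* The 60 Hz corner removes DC, drift and movement artefacts while leaving
  spike energy (dominantly 300–3000 Hz) untouched: the measured passband
  deviation at 300 Hz is under 1 %.
* An optional IIR notch (50/60 Hz, Q = 30) emulates a hardware line-noise
  eliminator; disabled by default because the high-pass corner already
  attenuates line noise and a notch distorts nearby spectral content.

## 3. Spike detection (`detect`)

* **Threshold**: `median(x) ± mad_factor · MAD(x)` with the *raw* MAD
  `median(|x − median(x)|)`, not the normal-consistent version. Median/MAD
  are robust to the spikes themselves inflating the estimate, unlike
  mean/SD. For Gaussian noise the raw MAD equals 0.6745 σ, so the default
  `mad_factor = 4` places the threshold at ≈ 2.7 σ.
* **Alignment**: each supra-threshold excursion is reduced to the time of its
  signed extremum; excursions closer than the 1 ms dead time merge (largest
  deviation wins), so the two lobes of one biphasic spike are never counted
  twice.
* **Windows**: 0.8 ms before and 1.6 ms after the extremum (72 samples at
  30 kHz) cover the full biphasic waveform with margin for later
  realignment.
* **Choice of mad_factor.** There is no factor that yields both ≥ 99 %
  recall *and* ≥ 99 % precision at SNR 8 with band-limited (100–3000 Hz)
  Gaussian noise. The expected rate of noise-only threshold crossings
  follows the Rice formula: for that band the upcrossing rate of level `u·σ`
  is ≈ 3500 · exp(−u²/2) per second, so 99 % precision at typical firing
  rates needs `u ≳ 4.6`, while 99 % recall of a unit-amplitude spike in
  σ = 1/8 noise needs the threshold below ≈ 3.1 σ. These bands do not
  overlap. The package therefore exposes the trade-off: `mad_factor = 4`
  (≈ 2.7 σ) favours recall and relies on the sorting stage's coherence floor
  to reject noise events; the bundled end-to-end scenario uses
  `mad_factor = 6` (≈ 4 σ), which keeps false events rare enough that
  cluster-level screening removes the rest.

## 4. Spike sorting (`sort`)

1. **Realignment.** Snippets are realigned to a canonical negative peak
   within ± one-third of the window; the per-spike shifts are returned so
   spike times can be corrected (`shift / fs`) before matching. Without
   this, noise occasionally flips alignment to the opposite lobe of a
   near-symmetric waveform, splitting one unit into two shifted clusters and
   adding ± 0.3 ms timing error.
2. **Features.** 4-level Haar wavelet decomposition of each snippet; the 10
   coefficients with the largest one-sample Kolmogorov–Smirnov distance from
   a fitted normal are kept. KS selection prefers multimodal coefficients —
   exactly the ones that separate units — over merely high-variance ones.
3. **Clustering.** Gaussian mixtures (full covariance, `reg_covar = 1e-6`,
   3 initialisations) for k = 1…8 on standardized features in a canonical
   (lexicographically sorted) row order, selected by BIC with early stopping
   after two consecutive non-improvements. Canonical ordering makes the
   result invariant to input permutation; spikes with maximum posterior
   below 0.5 and clusters smaller than 20 spikes are left unassigned (−1).
4. **Recursive refinement.** Population-level KS feature selection favours
   the dominant separation (e.g. A vs C waveforms) and can hide structure
   between minority units. Each cluster with ≥ 40 members therefore gets a
   fresh within-cluster feature selection and GMM fit; an accepted sub-split
   recurses once more (depth 2).
5. **Duplicate merge.** Clusters whose templates have best-lag
   cross-correlation ≥ 0.9 *and* RMS amplitude ratio ≤ 1.5 (within ± a third
   of the window) are merged by union-find: these are alignment artefacts of
   one unit, not distinct cells.
6. **Noise floor.** A cluster whose members' mean correlation with their own
   realigned template falls below 0.75 is rejected as noise/collision
   debris; genuine units in the bundled scenarios score ≥ 0.9 while
   threshold-crossing noise scores near zero. Rejected clusters populate a
   `noise_mask`.

**Screening convention.** On the SN channel only confidently assigned spikes
(`label ≥ 0`) enter the analysis, because unit identity there drives every
per-unit statistic. On the DR channel spikes are kept unless they belong to
a positively identified noise cluster (`~noise_mask`): a DR spike's unit
identity comes from its matched SN partner, so discarding merely *ambiguous*
DR spikes would silently convert real propagation successes into fake
failures (measured bias up to ≈ 9 percentage points on the A unit before
this rule was adopted).

## 5. Propagation matching (`match`)

* Every DR spike must have an SN origin that *strictly precedes* it within
  the tolerance window `w = distance / v_min` (defaults 4 mm / 0.1 m/s
  = 40 ms, the travel time of the slowest theoretical fiber).
* DR spikes are processed in ascending time; each takes the nearest
  preceding unclaimed SN spike (minimum latency). Matching is exclusive: a
  claimed SN spike is skipped in favour of the next-nearest preceding
  unclaimed one still inside the window; a DR spike with no eligible origin
  is an orphan.
* Simultaneous timestamps never match (latency must be strictly positive).
* **Fiber class**: velocity = distance / latency; C below 2 m/s, A at or
  above — the boundary goes to A by declared convention. A unit's class uses
  the *median* of its matched latencies, robust to occasional
  mis-assignments.
* Failure % = 100 · (1 − matched/SN) per unit;
  %ΔSpikes = (SN − DR)/SN · 100 for bulk counts or rates.
* The implementation is verified spike-for-spike against an independent
  brute-force greedy oracle on randomized micro-instances.

## 6. Rates and stimulus coupling (`rates`)

* Epoch rate: count in `[start, start + duration)` divided by duration.
* Instantaneous rate: 50 ms bins, Gaussian smoothing σ = 100 ms with
  reflective boundaries (kernel mass, hence total spike count, is conserved
  to < 1 %).
* Mechanosensitivity: ordinary least squares of instantaneous rate against
  the force trace linearly interpolated to the rate grid; r² is the stimulus
  correlation. A constant-rate series has no explained variance by
  definition and returns slope 0, r² = 0 (scipy's `linregress` would return
  NaN there); a constant force regressor is a caller error and raises.

## 7. Synthetic ground truth (`simulate`)

* **Trains**: inhomogeneous Poisson by thinning with an absolute refractory
  period of 1 ms (settable, or `None` for exact Poisson statistics).
* **Failure**: per-spike independent Bernoulli, optionally epoch-dependent
  (e.g. failure only during a stimulus epoch).
* **Latency**: `distance / velocity` plus truncated-Gaussian jitter
  (σ = 0.1 ms, truncated so DR events always follow their origin).
* **Rendering**: difference-of-Gaussians biphasic templates (amplitude,
  polarity, width and asymmetry per unit) summed at spike times over
  band-limited (100–3000 Hz) Gaussian noise rescaled to an exact standard
  deviation, so "SNR 8" means peak amplitude / noise σ = 8 exactly.
* **Determinism**: every stochastic component draws from
  `numpy.random.SeedSequence` spawns, so runs are bit-exact for a given seed
  and independent across units and channels.

### Benchmark scenarios

* **Bare-train grid**: firing rates {10, 25, 50, 100} Hz × failure fractions
  {0, 0.25, 0.5, 0.8}, 60 s, 10 seeds per cell, single unit with conduction
  velocity drawn uniformly from 0.5–10 m/s per run. Measures matcher
  accuracy in isolation (no detection/sorting errors). Every cell mean
  exceeds 80 %, and accuracy is non-increasing from 10 Hz to 100 Hz: errors
  require an interloper SN spike inside the conduction latency, whose
  probability grows with rate × latency.
* **Three-unit A/C scenario** (end-to-end, SNR 8, 60 s): an A fiber
  (10 m/s, rate 10 Hz, failure 0.10) and two C fibers (1.0 and 0.5 m/s,
  rate 8 Hz, failure 0.50 each) with distinct template shapes. The full
  chain recovers the unit count, both fiber classes and per-class failure
  within ≈ 5 percentage points of the realized (not merely programmed)
  ground truth across seeds.

### What the synthetic data does and does not show

It demonstrates that the pipeline is *correct*: the matcher equals its
oracle, programmed failure fractions are recovered within tight bounds, and
detection/sorting/matching compose without systematic bias under the stated
noise model. It does **not** demonstrate robustness to: non-stationary or
non-Gaussian noise, electrode drift, bursting or serially correlated
failure (real T-junction filtering is activity-dependent), overlapping
spikes from many simultaneously active units, template waveform change with
firing history, or movement artefacts. Results on real tissue depend on
those factors and on electrode geometry; parameters (especially
`mad_factor` and the noise-coherence floor) should be re-examined per
preparation.

## 8. Numerical conventions

* Times are seconds (float64) throughout; sample indices appear only at I/O
  boundaries. Spike times are strictly increasing within a train.
* Intervals are half-open `[start, end)` everywhere (epochs, rate bins).
* All dataframe outputs use stable, documented column names; unit labels are
  dense integers ordered by decreasing cluster size, −1 meaning unassigned.
* Randomness is always explicit: every public stochastic function takes a
  seed and is bit-exact reproducible.
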