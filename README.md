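# drgfilter

Analysis of dual-site peripheral nerve recordings to quantify **spike
propagation failure at the dorsal root ganglion (DRG)**.

## Background

Sensory action potentials travel from the periphery along the spinal nerve
(SN), through the DRG, and into the dorsal root (DR) toward the spinal cord.
The DRG is not a passive relay: at the T-junction of each sensory neuron a
fraction of spikes fails to propagate, so the DRG acts as a **filter** of
afferent traffic. Recording the same axons simultaneously on the SN (before
the ganglion) and the DR (after it) makes this filtering directly measurable:
every SN spike that never appears on the DR within its conduction-latency
window is a propagation failure.

`drgfilter` implements the complete analysis chain for such recordings:

1. **Preprocessing** — zero-phase Butterworth high-pass (60 Hz, order 4),
   optional line-noise notch (`drgfilter.preprocess`).
2. **Spike detection** — robust threshold at median ± 4 × MAD, signed-extremum
   alignment, 1 ms dead time, 0.8/1.6 ms waveform windows
   (`drgfilter.detect`).
3. **Spike sorting** — negative-peak realignment, Haar-wavelet features with
   Kolmogorov–Smirnov selection, Gaussian-mixture clustering with BIC model
   selection, recursive within-cluster refinement, shifted-duplicate merging
   and a waveform-coherence noise floor (`drgfilter.sort`).
4. **Propagation matching** — each DR spike is paired with the nearest
   strictly-preceding unclaimed SN spike within the conduction window
   w = electrode distance / slowest velocity (4 mm / 0.1 m/s = 40 ms);
   unmatched SN spikes are propagation failures. Conduction velocity
   = distance / latency classifies fibers (C < 2 m/s ≤ A)
   (`drgfilter.match`).
5. **Stimulus quantification** — epoch firing rates, Gaussian-smoothed
   instantaneous rates, rate-vs-force regression, %ΔSpikes
   = (SN − DR)/SN × 100 (`drgfilter.rates`).
6. **Ground-truth simulation** — Poisson trains with refractoriness,
   per-epoch Bernoulli propagation failure, latency jitter, biphasic
   templates and band-limited noise rendering, for end-to-end validation
   (`drgfilter.simulate`).

## Worked example

The bundled demo simulates a 60 s two-channel recording with three units —
one A fiber (10 m/s, 10 % programmed failure) and two C fibers (1.0 and
0.5 m/s, 50 % programmed failure each) at SNR 8 — then runs the full chain
(filter → detect → sort → match → summarise) with no access to the ground
truth:

```sh
$ drgfilter demo --seed 0
recovered 3 unit(s); propagation summary:
 unit_id  n_sn  n_matched  success_pct  failure_pct  mean_latency_s  median_latency_s  velocity_mps fiber_class
       0   590        511    86.610169    13.389831        0.000453          0.000400     10.000000           A
       1   471        254    53.927813    46.072187        0.004924          0.004000      1.000000           C
       2   454        224    49.339207    50.660793        0.008132          0.007967      0.502092           C

per fiber class (estimated vs programmed failure %):
fiber_class  est_failure_pct  true_failure_pct  n_units_est
          A        13.389831         11.024845            1
          C        48.324324         49.629318            2
```

All three units are recovered with the correct fiber class, conduction
velocities within a few percent, and per-class failure estimates within a
few percentage points of the realized ground truth.

The same chain is scriptable:

```python
from drgfilter.benchmark import end_to_end_run, three_unit_scenario

result = end_to_end_run(seed=0)
print(result["summary"])       # the per-unit table above
```

## Command-line interface

```text
drgfilter simulate   # synthetic recording + ground-truth event tables
drgfilter run        # full pipeline on a recording or simulated scenario
drgfilter detect     # filter one channel, extract threshold-crossing spikes
drgfilter sort       # cluster spike waveforms into putative units
drgfilter match      # match DR spikes to SN origins, summarise propagation
drgfilter demo       # end-to-end three-unit A/C scenario
drgfilter benchmark  # bare-train matching-accuracy grid
```

Run `drgfilter COMMAND --help` for options. `drgfilter run` consumes a YAML
configuration describing channels, epochs and parameters and writes CSV
outputs (spike trains, unit tables, match table, propagation summary, rates).

## Documentation

`docs/methods.md` describes the models, every default parameter and its
rationale, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Limitations

The synthetic generator validates the *analysis*, not the biology: templates
are stereotyped biphasic shapes, noise is stationary band-limited Gaussian,
and failure is Bernoulli-independent per spike. Real recordings add
electrode drift, bursting, overlapping spikes and activity-dependent failure
dynamics that this benchmark does not probe; see `docs/methods.md`.
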