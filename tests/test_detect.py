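"""Threshold computation and spike detection behaviour."""

import numpy as np
import pytest

from drgfilter.detect import (DetectionParams, compute_prominence,
                              compute_threshold, detect_spikes)
from drgfilter.errors import DegenerateSignalError, ParameterError
from drgfilter.simulate import _bandlimited_noise, biphasic_template

FS = 30_000.0


# --------------------------------------------------------------------------
# compute_threshold
# --------------------------------------------------------------------------

def test_threshold_hand_vector_symmetric():
    med, mad, lo, hi = compute_threshold(np.array([-2.0, -1, 0, 1, 2]), 4.0)
    assert med == 0.0 and mad == 1.0
    assert (lo, hi) == (-4.0, 4.0)


def test_threshold_constant_tail_is_degenerate():
    with pytest.raises(DegenerateSignalError):
        compute_threshold(np.array([1.0, 1, 1, 1, 9]), 4.0)


def test_threshold_respects_offset_median():
    med, mad, lo, hi = compute_threshold(np.array([8.0, 9, 10, 11, 12]), 2.0)
    assert med == 10.0 and mad == 1.0
    assert (lo, hi) == (8.0, 12.0)


def test_mad_of_standard_normal_near_phi_quantile(rng):
    x = rng.normal(size=1_000_000)
    _, mad, _, _ = compute_threshold(x, 4.0)
    assert mad == pytest.approx(0.6745, rel=0.01)


# --------------------------------------------------------------------------
# compute_prominence
# --------------------------------------------------------------------------

def test_prominence_hand_vector():
    assert compute_prominence(np.array([0.0, -5, 0, 2, 0])) == 7.0


def test_prominence_of_flat_waveform_is_zero():
    assert compute_prominence(np.zeros(10)) == 0.0


def test_prominence_scales_linearly_with_template_amplitude():
    base = biphasic_template(FS, amplitude=1.0)
    amps = np.arange(1.0, 11.0)
    proms = np.array([compute_prominence(a * base) for a in amps])
    slope = np.polyfit(amps, proms, 1)[0]
    r2 = np.corrcoef(amps, proms)[0, 1] ** 2
    assert slope == pytest.approx(proms[0], rel=1e-9)
    assert r2 == pytest.approx(1.0, abs=1e-12)


# --------------------------------------------------------------------------
# detect_spikes
# --------------------------------------------------------------------------

def noisy_trace(duration, spike_times, rng, peak=1.0, noise_mad=0.125):
    """Band-limited Gaussian noise plus biphasic spikes of the given peak.

    The template is strongly asymmetric (asym 0.2) so the signed extremum is
    unambiguous; near-symmetric shapes let noise flip the alignment to the
    opposite lobe, which is a sorting-stage concern, not a recall one.
    """
    n = int(duration * FS)
    sd = noise_mad / 0.6745
    trace = _bandlimited_noise(rng, n, FS, sd, (100.0, 3000.0))
    tmpl = biphasic_template(FS, amplitude=peak, asym=0.2)
    k0 = int(np.argmax(np.abs(tmpl)))
    for t in spike_times:
        k = int(round(t * FS)) - k0
        trace[k:k + len(tmpl)] += tmpl
    return trace


def sine_background(n, amp=0.01, freq=137.0):
    """Deterministic non-degenerate background that never crosses the
    threshold: MAD of a sinusoid is ~0.707*amp, so 6*MAD ~ 4.2*amp > amp."""
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / FS)


def test_single_pulse_detected_at_its_extremum():
    trace = sine_background(int(FS))
    tmpl = biphasic_template(FS, amplitude=1.0)
    k = 15_000 - int(np.argmax(np.abs(tmpl)))
    trace[k:k + len(tmpl)] += tmpl
    train = detect_spikes(trace, FS, DetectionParams(mad_factor=6.0))
    assert len(train) == 1
    assert train.times[0] == pytest.approx(15_000 / FS, abs=1e-4)


def test_dead_time_merges_twin_pulses():
    trace = sine_background(int(FS))
    tmpl = biphasic_template(FS, amplitude=1.0)
    k0 = int(np.argmax(np.abs(tmpl)))
    for t in (0.5, 0.5005):  # 0.5 ms apart, dead_time 1 ms
        k = int(round(t * FS)) - k0
        trace[k:k + len(tmpl)] += tmpl
    train = detect_spikes(trace, FS, DetectionParams(mad_factor=6.0))
    assert len(train) == 1


def test_recall_above_99_percent_at_snr_eight(rng):
    # at mad_factor 4 the threshold sits at half the peak, leaving ample
    # margin for recall (precision is a separate matter at this factor)
    spike_times = 0.05 + np.arange(200) * 0.02
    trace = noisy_trace(4.1, spike_times, rng)
    train = detect_spikes(trace, FS, DetectionParams(mad_factor=4.0))
    hits = sum(np.min(np.abs(train.times - t)) <= 3e-4 for t in spike_times)
    assert hits / len(spike_times) >= 0.99


def test_raising_mad_factor_never_adds_spikes(rng):
    spike_times = 0.05 + np.arange(30) * 0.03
    trace = noisy_trace(1.0, spike_times, rng)
    counts = [len(detect_spikes(trace, FS, DetectionParams(mad_factor=m)))
              for m in (3.0, 4.0, 5.0, 6.0, 8.0)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_false_positive_rate_lower_at_factor_four_than_three(rng):
    noise = _bandlimited_noise(rng, int(20 * FS), FS, 1.0, (100.0, 3000.0))
    n4 = len(detect_spikes(noise, FS, DetectionParams(mad_factor=4.0)))
    n3 = len(detect_spikes(noise, FS, DetectionParams(mad_factor=3.0)))
    assert n4 < n3


def test_detection_is_deterministic(rng):
    trace = noisy_trace(1.0, [0.2, 0.5, 0.8], rng)
    a = detect_spikes(trace, FS, DetectionParams(mad_factor=6.0))
    b = detect_spikes(trace, FS, DetectionParams(mad_factor=6.0))
    np.testing.assert_array_equal(a.times, b.times)
    np.testing.assert_array_equal(a.waveforms, b.waveforms)


def test_edge_spike_dropped():
    trace = sine_background(3000)
    trace[2] = 5.0  # extremum too close to the start for a full window
    train = detect_spikes(trace, FS, DetectionParams(mad_factor=6.0))
    assert len(train) == 0


def test_waveform_window_and_alignment_shape(rng):
    trace = noisy_trace(1.0, [0.3, 0.6], rng)
    params = DetectionParams(mad_factor=6.0)
    train = detect_spikes(trace, FS, params)
    pre = int(round(params.window_pre * FS))
    post = int(round(params.window_post * FS))
    assert train.waveforms.shape[1] == pre + post == 72
    assert train.align_index == pre


def test_invalid_params_rejected():
    with pytest.raises(ParameterError):
        DetectionParams(mad_factor=-1.0).validate()
    with pytest.raises(ParameterError):
        DetectionParams(window_pre=1e-4, window_post=1e-4,
                        dead_time=1e-3).validate()
    with pytest.raises(ParameterError):
        DetectionParams(polarity="sideways").validate()
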