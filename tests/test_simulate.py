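"""Ground-truth generator: trains, rendering and scoring."""

import numpy as np
import pytest

from drgfilter.errors import ParameterError
from drgfilter.io import EpochSpec
from drgfilter.match import match_spikes
from drgfilter.simulate import (GroundTruth, UnitSpec, biphasic_template,
                                ramp_and_hold_force, render_traces,
                                score_matching, simulate_trains)

FS = 30_000.0


def one_unit(rate=20.0, velocity=1.0, failure=0.0, **kw):
    return UnitSpec(unit_id=0, base_rate=rate, velocity=velocity,
                    failure_prob=failure, **kw)


# --------------------------------------------------------------------------
# simulate_trains
# --------------------------------------------------------------------------

def test_lossless_unit_propagates_every_spike_at_fixed_latency():
    gt = simulate_trains([one_unit()], 100.0, jitter_sd=0.0, seed=0)
    assert len(gt.dr_times) == len(gt.sn_times) > 0
    lat = gt.dr_times[np.argsort(gt.dr_origin)] - gt.sn_times
    np.testing.assert_allclose(lat, 0.004 / 1.0, rtol=0, atol=1e-12)


def test_total_failure_yields_no_dr_events():
    gt = simulate_trains([one_unit(failure=1.0)], 50.0, seed=1)
    assert len(gt.sn_times) > 0
    assert len(gt.dr_times) == 0
    assert gt.true_failure_pct() == pytest.approx(100.0)


def test_realized_failure_fraction_matches_bernoulli_mean():
    fracs = [simulate_trains([one_unit(failure=0.5)], 100.0, seed=s)
             .true_failure_pct() / 100.0 for s in range(50)]
    assert np.mean(fracs) == pytest.approx(0.5, abs=0.02)


def test_refractory_period_enforced():
    gt = simulate_trains([one_unit(rate=100.0)], 30.0, seed=2)
    assert np.min(np.diff(gt.sn_times)) >= 1e-3


def test_poisson_dispersion_with_refractory_disabled():
    """Counts in disjoint 1 s windows have variance/mean within [0.9, 1.1]."""
    lam, n_windows = 5.0, 10_000
    gt = simulate_trains([one_unit(rate=lam)], float(n_windows), seed=3,
                         refractory=None, jitter_sd=0.0)
    counts, _ = np.histogram(gt.sn_times, bins=np.arange(n_windows + 1.0))
    fano = counts.var() / counts.mean()
    assert 0.9 <= fano <= 1.1


def test_epoch_dependent_failure_probability():
    epochs = [EpochSpec("control", 0.0, 50.0), EpochSpec("stimulus", 50.0, 50.0)]
    unit = one_unit(rate=40.0, failure={"default": 0.0, "stimulus": 1.0})
    gt = simulate_trains([unit], 100.0, epochs=epochs, seed=4)
    early = gt.sn_failed[gt.sn_times < 50.0]
    late = gt.sn_failed[gt.sn_times >= 50.0]
    assert not early.any()
    assert late.all()


def test_seeded_determinism_is_bit_exact():
    a = simulate_trains([one_unit()], 30.0, seed=7)
    b = simulate_trains([one_unit()], 30.0, seed=7)
    np.testing.assert_array_equal(a.sn_times, b.sn_times)
    np.testing.assert_array_equal(a.dr_times, b.dr_times)
    np.testing.assert_array_equal(a.dr_origin, b.dr_origin)


def test_dr_times_always_after_their_origin():
    gt = simulate_trains([one_unit(velocity=10.0)], 60.0,
                         jitter_sd=5e-4, seed=8)
    assert np.all(gt.dr_times - gt.sn_times[gt.dr_origin] > 0)


def test_nonpositive_duration_rejected():
    with pytest.raises(ParameterError):
        simulate_trains([one_unit()], 0.0)


# --------------------------------------------------------------------------
# render_traces
# --------------------------------------------------------------------------

def test_single_event_renders_template_exactly():
    tmpl = biphasic_template(FS, amplitude=1.0)
    unit = one_unit(template=tmpl)
    gt = GroundTruth(sn_times=np.array([0.05]), sn_units=np.array([0]),
                     sn_epochs=np.array(["baseline"], dtype=object),
                     sn_failed=np.array([False]),
                     dr_times=np.empty(0), dr_units=np.empty(0, dtype=int),
                     dr_origin=np.empty(0, dtype=int), distance=0.004,
                     duration=0.1, units=[unit])
    rec = render_traces(gt, [unit], fs=FS, noise_sd=0.0, seed=0)
    peak_sample = int(np.argmax(np.abs(rec.sn_trace)))
    assert peak_sample == int(round(0.05 * FS))
    assert np.max(np.abs(rec.sn_trace)) == pytest.approx(np.max(np.abs(tmpl)))
    assert np.allclose(rec.dr_trace, 0.0)


def test_pure_noise_standard_deviation_calibrated():
    unit = one_unit(template=biphasic_template(FS))
    gt = GroundTruth(sn_times=np.empty(0), sn_units=np.empty(0, dtype=int),
                     sn_epochs=np.empty(0, dtype=object),
                     sn_failed=np.empty(0, dtype=bool),
                     dr_times=np.empty(0), dr_units=np.empty(0, dtype=int),
                     dr_origin=np.empty(0, dtype=int), distance=0.004,
                     duration=1_000_000 / FS, units=[unit])
    rec = render_traces(gt, [unit], fs=FS, noise_sd=0.25, seed=1)
    assert rec.sn_trace.std() == pytest.approx(0.25, rel=0.02)


def test_coincident_events_superpose():
    tmpl = biphasic_template(FS, amplitude=1.0)
    unit = one_unit(template=tmpl)
    gt = GroundTruth(sn_times=np.array([0.05, 0.05]),
                     sn_units=np.array([0, 0]),
                     sn_epochs=np.array(["baseline"] * 2, dtype=object),
                     sn_failed=np.array([False, False]),
                     dr_times=np.empty(0), dr_units=np.empty(0, dtype=int),
                     dr_origin=np.empty(0, dtype=int), distance=0.004,
                     duration=0.1, units=[unit])
    rec = render_traces(gt, [unit], fs=FS, noise_sd=0.0, seed=0)
    assert np.max(np.abs(rec.sn_trace)) == pytest.approx(
        2 * np.max(np.abs(tmpl)))


def test_render_includes_force_channel():
    force = ramp_and_hold_force(1.0, onset=0.2, ramp=0.2, hold=0.3, peak=8.0)
    unit = one_unit(template=biphasic_template(FS))
    gt = simulate_trains([unit], 1.0, force=force, seed=0)
    rec = render_traces(gt, [unit], fs=FS, noise_sd=0.01, seed=0, force=force)
    assert rec.force_trace is not None
    assert rec.force_trace.max() == pytest.approx(8.0, rel=0.01)


# --------------------------------------------------------------------------
# score_matching
# --------------------------------------------------------------------------

def test_perfect_matching_scores_hundred_percent():
    """Lossless scenario with conduction latency far below the typical ISI:
    every DR spike has exactly one plausible origin."""
    gt = simulate_trains([one_unit(rate=2.0, velocity=10.0)], 60.0, seed=9)
    assert np.min(np.diff(gt.sn_times)) > 0.004 / 10.0
    table = match_spikes(gt.sn_times, gt.dr_times)
    score = score_matching(gt, table)
    assert score["pair_accuracy"] == pytest.approx(100.0)
    assert score["recovered_pct"] == pytest.approx(100.0)


def test_low_rate_matching_accuracy_near_perfect():
    """Mis-assignment needs an interloper SN spike inside the conduction
    latency (0.4 ms at 10 m/s); at 5 Hz that chance is ~0.2%, so accuracy
    must exceed 99%."""
    accs = []
    for seed in range(5):
        gt = simulate_trains([one_unit(rate=5.0, velocity=10.0,
                                       failure=0.3)], 120.0, seed=seed)
        table = match_spikes(gt.sn_times, gt.dr_times)
        accs.append(score_matching(gt, table)["pair_accuracy"])
    assert np.mean(accs) >= 99.0


def test_empty_match_flagged_undefined():
    gt = simulate_trains([one_unit(failure=1.0)], 10.0, seed=10)
    table = match_spikes(gt.sn_times, gt.dr_times)
    score = score_matching(gt, table)
    assert not score["defined"]
    assert np.isnan(score["pair_accuracy"])
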