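"""Synthetic dual-site recordings with full ground truth.

The generator emulates the statistical structure of a spinal-nerve /
dorsal-root preparation: several firing units on the SN with distinct
biphasic waveform templates, (inhomogeneous) Poisson firing optionally
driven by a ramp-and-hold force stimulus, a per-unit conduction velocity
over the inter-electrode distance, per-spike Bernoulli propagation failure
at the T-junction that may depend on the analysis epoch, and additive
band-limited Gaussian noise on the rendered voltage traces.

Two modes exist. Bare-train mode (:func:`simulate_trains` followed directly
by matching) benchmarks the matcher itself against known origins, mirroring
a validation on Poisson-generated trains; rendered mode
(:func:`render_traces`) additionally exercises filtering, detection and
sorting end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ParameterError
from .io import Recording, EpochSpec

DEFAULT_JITTER_SD = 1e-4      # s; conduction latency jitter, small by design
DEFAULT_REFRACTORY = 1e-3     # s; per-unit absolute refractory period
DEFAULT_DISTANCE = 0.004      # m
DEFAULT_NOISE_BAND = (100.0, 3000.0)  # Hz, emulating the acquisition bandpass


def biphasic_template(fs: float, amplitude: float = 1.0, width: float = 2e-4,
                      polarity: int = -1, asym: float = 0.6,
                      pre: float = 0.8e-3, post: float = 1.6e-3) -> np.ndarray:
    """Difference-of-Gaussians extracellular spike shape.

    The dominant lobe (signed by ``polarity``, sd ``width``/2) sits at the
    alignment point ``pre`` seconds into the snippet; a slower opposite lobe
    of relative amplitude ``asym`` follows. ``amplitude`` is the absolute
    peak in trace units.
    """
    if fs * (pre + post) < 8:
        raise ParameterError("sampling rate too low to represent the template")
    n = int(round(fs * (pre + post)))
    t = (np.arange(n) - round(pre * fs)) / fs
    main = polarity * np.exp(-0.5 * (t / (width / 2)) ** 2)
    second = -polarity * asym * np.exp(-0.5 * ((t - 1.5 * width) / width) ** 2)
    shape = main + second
    return amplitude * shape / np.max(np.abs(shape))


@dataclass
class UnitSpec:
    """Generator parameters for one firing unit."""

    unit_id: int
    base_rate: float                      # Hz
    velocity: float                       # m/s, conduction over the distance
    failure_prob: dict | float = 0.0      # epoch name -> Bernoulli failure p
    force_gain: float = 0.0               # Hz per gram; 0 = not mechanosensitive
    template: Optional[np.ndarray] = None  # rendered waveform; None in bare mode

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ParameterError("base_rate must be >= 0")
        if not self.velocity > 0:
            raise ParameterError("velocity must be positive")
        probs = (self.failure_prob.values()
                 if isinstance(self.failure_prob, dict) else [self.failure_prob])
        for p in probs:
            if not 0 <= p <= 1:
                raise ParameterError("failure probabilities must lie in [0, 1]")

    def failure_at(self, epoch_name: str) -> float:
        if isinstance(self.failure_prob, dict):
            return float(self.failure_prob.get(
                epoch_name, self.failure_prob.get("default", 0.0)))
        return float(self.failure_prob)


@dataclass
class GroundTruth:
    """Simulator-emitted events with unit labels, origins and failure flags."""

    sn_times: np.ndarray
    sn_units: np.ndarray
    sn_epochs: np.ndarray          # epoch label per SN spike
    sn_failed: np.ndarray          # bool; True = programmed propagation failure
    dr_times: np.ndarray
    dr_units: np.ndarray
    dr_origin: np.ndarray          # index into the SN arrays
    distance: float
    duration: float
    units: list = field(default_factory=list)

    @property
    def failed_sn(self) -> np.ndarray:
        return np.flatnonzero(self.sn_failed)

    def sn_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.sn_times, "unit_id": self.sn_units,
                             "epoch": self.sn_epochs, "failed": self.sn_failed})

    def dr_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.dr_times, "unit_id": self.dr_units,
                             "origin_sn_index": self.dr_origin})

    def true_failure_pct(self, unit_id: int | None = None) -> float:
        sel = slice(None) if unit_id is None else self.sn_units == unit_id
        failed = self.sn_failed[sel]
        return 100.0 * failed.mean() if len(failed) else np.nan


def _epoch_label(t: float, epochs: list[EpochSpec]) -> str:
    for e in epochs:
        if e.start <= t < e.end:
            return e.name
    return "baseline"


def _poisson_times(rng: np.random.Generator, duration: float,
                   base_rate: float, force_gain: float,
                   force: Optional[Callable[[np.ndarray], np.ndarray]],
                   refractory: float | None) -> np.ndarray:
    """Inhomogeneous Poisson times by thinning, then refractory pruning."""
    if force is None or force_gain == 0.0:
        lam_max = base_rate
        rate_fn = None
    else:
        probe = np.linspace(0.0, duration, 2049)
        lam_t = base_rate + force_gain * force(probe)
        lam_max = float(np.max(lam_t))
        rate_fn = lambda t: np.clip(base_rate + force_gain * force(t), 0.0, None)
    if lam_max <= 0:
        return np.empty(0)
    n = rng.poisson(lam_max * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    if rate_fn is not None:
        keep = rng.uniform(0.0, lam_max, size=len(t)) < rate_fn(t)
        t = t[keep]
    if refractory:
        kept = []
        last = -np.inf
        for ti in t:
            if ti - last >= refractory:
                kept.append(ti)
                last = ti
        t = np.asarray(kept)
    return t


def simulate_trains(units: list[UnitSpec], duration: float,
                    epochs: Optional[list[EpochSpec]] = None,
                    force: Optional[tuple] = None,
                    jitter_sd: float = DEFAULT_JITTER_SD,
                    seed: int | np.random.SeedSequence = 0,
                    distance: float = DEFAULT_DISTANCE,
                    refractory: float | None = DEFAULT_REFRACTORY) -> GroundTruth:
    """Draw ground-truth SN/DR event trains for the given units.

    Per unit, SN times follow a Poisson process of rate
    ``base_rate + force_gain * force(t)`` (clipped at zero), thinned to a
    per-unit refractory period. Each SN spike propagates to the DR with
    probability ``1 - failure_prob(epoch)``; a propagated spike appears at
    the SN time plus ``distance / velocity`` plus Gaussian jitter truncated
    so the DR time stays after the SN time. Fully reproducible given a seed.

    ``force`` is an optional ``(times, grams)`` pair, linearly interpolated.
    """
    if not duration > 0:
        raise ParameterError("duration must be positive")
    epochs = epochs or []
    force_fn = None
    if force is not None:
        ft, fv = np.asarray(force[0], float), np.asarray(force[1], float)
        force_fn = lambda t: np.interp(t, ft, fv)

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    child_seeds = ss.spawn(len(units))

    sn_t, sn_u, sn_e, sn_f = [], [], [], []
    dr_records = []  # (time, unit, local sn position placeholder)
    for unit, cs in zip(units, child_seeds):
        rng = np.random.Generator(np.random.PCG64(cs))
        t = _poisson_times(rng, duration, unit.base_rate, unit.force_gain,
                           force_fn, refractory)
        labels = [_epoch_label(ti, epochs) for ti in t]
        p_fail = np.array([unit.failure_at(l) for l in labels])
        failed = rng.uniform(size=len(t)) < p_fail
        latency = distance / unit.velocity
        start = len(sn_t)
        sn_t.extend(t)
        sn_u.extend([unit.unit_id] * len(t))
        sn_e.extend(labels)
        sn_f.extend(failed.tolist())
        for k in np.flatnonzero(~failed):
            jitter = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
            tries = 0
            while latency + jitter <= 0 and tries < 100:
                jitter = rng.normal(0.0, jitter_sd)
                tries += 1
            if latency + jitter <= 0:
                jitter = -latency + 1e-6
            dr_records.append((t[k] + latency + jitter, unit.unit_id,
                               start + k))

    sn_t = np.asarray(sn_t)
    order = np.argsort(sn_t, kind="stable")
    inverse = np.empty(len(order), dtype=int)
    inverse[order] = np.arange(len(order))

    sn_times = sn_t[order]
    sn_units = np.asarray(sn_u, dtype=int)[order]
    sn_epochs = np.asarray(sn_e, dtype=object)[order]
    sn_failed = np.asarray(sn_f, dtype=bool)[order]

    if dr_records:
        dr_records.sort(key=lambda r: r[0])
        dr_times = np.asarray([r[0] for r in dr_records])
        dr_units = np.asarray([r[1] for r in dr_records], dtype=int)
        dr_origin = inverse[np.asarray([r[2] for r in dr_records], dtype=int)]
    else:
        dr_times = np.empty(0)
        dr_units = np.empty(0, dtype=int)
        dr_origin = np.empty(0, dtype=int)

    return GroundTruth(sn_times=sn_times, sn_units=sn_units,
                       sn_epochs=sn_epochs, sn_failed=sn_failed,
                       dr_times=dr_times, dr_units=dr_units,
                       dr_origin=dr_origin, distance=distance,
                       duration=duration, units=list(units))


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       sd: float, band: tuple | None) -> np.ndarray:
    noise = rng.standard_normal(n)
    if band is not None:
        lo, hi = band
        hi = min(hi, 0.45 * fs)
        sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
        noise = signal.sosfiltfilt(sos, noise)
    s = noise.std()
    if s > 0:
        noise *= sd / s
    return noise


def render_traces(gt: GroundTruth, units: list[UnitSpec], fs: float,
                  noise_sd: float, seed: int | np.random.SeedSequence = 0,
                  force: Optional[tuple] = None,
                  noise_band: tuple | None = DEFAULT_NOISE_BAND) -> Recording:
    """Render ground-truth events into two-channel voltage traces.

    Each event adds its unit's template (linear superposition; coincident
    events sum) with the template's alignment extremum at the event sample.
    Additive Gaussian noise of standard deviation ``noise_sd`` (band-limited
    to the acquisition passband by default) is drawn independently per
    channel. The optional force profile is resampled onto the voltage grid.
    """
    by_id = {u.unit_id: u for u in units}
    for u in units:
        if u.template is None:
            raise ParameterError(f"unit {u.unit_id} has no waveform template")
        if len(u.template) < 8:
            raise ParameterError(
                f"unit {u.unit_id}: template too short (< 8 samples)"
            )
    n = int(round(gt.duration * fs))
    sn = np.zeros(n)
    dr = np.zeros(n)

    def add_events(trace: np.ndarray, times: np.ndarray, unit_ids: np.ndarray):
        for t, uid in zip(times, unit_ids):
            tmpl = by_id[uid].template
            align = int(np.argmax(np.abs(tmpl)))
            k = int(round(t * fs)) - align
            a, b = max(0, k), min(n, k + len(tmpl))
            if a < b:
                trace[a:b] += tmpl[a - k:b - k]

    add_events(sn, gt.sn_times, gt.sn_units)
    add_events(dr, gt.dr_times, gt.dr_units)

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng_sn, rng_dr = (np.random.Generator(np.random.PCG64(s))
                      for s in ss.spawn(2))
    if noise_sd > 0:
        sn += _bandlimited_noise(rng_sn, n, fs, noise_sd, noise_band)
        dr += _bandlimited_noise(rng_dr, n, fs, noise_sd, noise_band)

    force_trace = None
    if force is not None:
        ft, fv = np.asarray(force[0], float), np.asarray(force[1], float)
        force_trace = np.interp(np.arange(n) / fs, ft, fv)

    return Recording(sn_trace=sn, dr_trace=dr, force_trace=force_trace,
                     sampling_rate=fs, electrode_distance=gt.distance)


def ramp_and_hold_force(duration: float, onset: float, ramp: float,
                        hold: float, peak: float, release: float | None = None,
                        dt: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Randall-Selitto-style force profile in grams: ramp up, hold, release."""
    release = ramp if release is None else release
    t = np.arange(0.0, duration, dt)
    f = np.zeros_like(t)
    f += np.clip((t - onset) / ramp, 0.0, 1.0) * peak
    end_hold = onset + ramp + hold
    f *= np.clip(1.0 - (t - end_hold) / release, 0.0, 1.0)
    return t, f


def align_times(true_times, observed_times, tol: float = 3e-4) -> np.ndarray:
    """Greedy one-to-one alignment: observed index per true event, -1 if none.

    Both inputs sorted ascending; each true event takes the nearest unclaimed
    observed event within ``tol`` seconds, in time order.
    """
    true_times = np.asarray(true_times, float)
    obs = np.asarray(observed_times, float)
    out = np.full(len(true_times), -1, dtype=int)
    used = np.zeros(len(obs), dtype=bool)
    j = 0
    for i, t in enumerate(true_times):
        lo = np.searchsorted(obs, t - tol)
        best, best_d = -1, tol
        for j in range(lo, len(obs)):
            if obs[j] > t + tol:
                break
            d = abs(obs[j] - t)
            if not used[j] and d <= best_d:
                best, best_d = j, d
        if best >= 0:
            used[best] = True
            out[i] = best
    return out


def score_matching(gt: GroundTruth, match) -> dict:
    """Score a match table against ground truth (bare-train mode).

    ``pair_accuracy`` is the percentage of matched DR spikes whose assigned
    SN index equals their true origin; ``recovered_pct`` the percentage of
    truly propagated SN spikes that received a DR partner; ``rate_error_hz``
    the absolute difference between the matched-pair rate and the true DR
    rate. Per-unit programmed vs estimated failure is also reported.
    """
    pairs = match.pairs
    matched = pairs[pairs["matched"]]
    if len(matched) == 0:
        return {"pair_accuracy": np.nan, "recovered_pct": np.nan,
                "rate_error_hz": np.nan, "per_unit": pd.DataFrame(),
                "defined": False}
    assigned_sn = matched["sn_index"].to_numpy(int)
    dr_idx = matched["dr_index"].to_numpy(int)
    correct = assigned_sn == gt.dr_origin[dr_idx]
    pair_accuracy = 100.0 * correct.mean()

    propagated = ~gt.sn_failed
    recovered = pairs["matched"].to_numpy()[propagated].mean() * 100.0 \
        if propagated.any() else np.nan
    rate_error = abs(len(matched) - len(gt.dr_times)) / gt.duration

    rows = []
    for u in sorted(set(gt.sn_units.tolist())):
        sel = gt.sn_units == u
        est_fail = 100.0 * (1.0 - pairs["matched"].to_numpy()[sel].mean())
        rows.append({"unit_id": u,
                     "true_failure_pct": gt.true_failure_pct(u),
                     "est_failure_pct": est_fail})
    return {"pair_accuracy": float(pair_accuracy),
            "recovered_pct": float(recovered),
            "rate_error_hz": float(rate_error),
            "per_unit": pd.DataFrame(rows),
            "defined": True}
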