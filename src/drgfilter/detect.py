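"""Threshold-based extracellular spike detection and waveform extraction.

The detection threshold is robust: median(x) +/- mad_factor * MAD(x), where
MAD is the raw median absolute deviation median(|x - median(x)|). Excursions
beyond either threshold (configurable polarity) are reduced to the time of
their signed extremum; excursions closer together than the dead time are
merged and the largest deviation wins. Waveform snippets of
[t - window_pre, t + window_post] are cut around each kept extremum, and
spike prominence is the snippet's peak-to-trough amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, ParameterError
from .io import SpikeTrain

log = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    mad_factor: float = 4.0
    window_pre: float = 0.8e-3    # s before the alignment extremum
    window_post: float = 1.6e-3   # s after
    dead_time: float = 1e-3       # s, merges excursions of one biphasic spike
    polarity: str = "both"        # {negative, positive, both}

    def validate(self) -> None:
        if not self.mad_factor > 0:
            raise ParameterError("mad_factor must be positive")
        if self.window_pre < 0 or self.window_post <= 0:
            raise ParameterError("window_pre/window_post must be non-negative/positive")
        if self.window_pre + self.window_post < self.dead_time:
            raise ParameterError("window_pre + window_post must be >= dead_time")
        if self.polarity not in ("negative", "positive", "both"):
            raise ParameterError(f"unknown polarity {self.polarity!r}")


def compute_threshold(trace: np.ndarray, mad_factor: float = 4.0):
    """Robust detection thresholds from the signal's median and MAD.

    Returns ``(median, mad, threshold_low, threshold_high)`` with
    ``threshold_{low,high} = median -/+ mad_factor * mad``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ParameterError("empty trace")
    med = float(np.median(trace))
    mad = float(np.median(np.abs(trace - med)))
    if mad == 0.0:
        raise DegenerateSignalError(
            "median absolute deviation is zero; cannot set a threshold"
        )
    return med, mad, med - mad_factor * mad, med + mad_factor * mad


def compute_prominence(waveform: np.ndarray) -> float:
    """Peak-to-trough amplitude of a waveform snippet (always >= 0)."""
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise ParameterError("empty waveform")
    return float(waveform.max() - waveform.min())


def _excursion_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as (start, stop) index pairs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts, stops))


def detect_spikes(trace: np.ndarray, fs: float,
                  params: DetectionParams | None = None,
                  channel: str = "sn") -> SpikeTrain:
    """Detect spikes on a filtered trace and extract aligned snippets.

    Each spike time is the sample of the signed extremum (largest absolute
    deviation from the median) of its threshold-crossing excursion; excursion
    extrema separated by less than ``dead_time`` are merged, keeping the
    largest deviation (ties go to the earlier one). Spikes whose snippet
    window would run off the trace are dropped and counted in the log.
    """
    params = params or DetectionParams()
    params.validate()
    trace = np.asarray(trace, dtype=float)
    med, mad, lo, hi = compute_threshold(trace, params.mad_factor)

    if params.polarity == "positive":
        mask = trace > hi
    elif params.polarity == "negative":
        mask = trace < lo
    else:
        mask = (trace > hi) | (trace < lo)

    dev = np.abs(trace - med)
    candidates = []  # (sample, |deviation|)
    for start, stop in _excursion_runs(mask):
        k = start + int(np.argmax(dev[start:stop]))
        candidates.append((k, dev[k]))

    # merge candidates within the dead time, keeping the largest deviation
    dead_samples = max(1, int(round(params.dead_time * fs)))
    kept: list[tuple[int, float]] = []
    for k, a in candidates:
        if kept and k - kept[-1][0] < dead_samples:
            if a > kept[-1][1]:
                kept[-1] = (k, a)
        else:
            kept.append((k, a))

    pre = int(round(params.window_pre * fs))
    post = int(round(params.window_post * fs))
    times, waveforms = [], []
    n_edge = 0
    for k, _ in kept:
        if k - pre < 0 or k + post > len(trace):
            n_edge += 1
            continue
        times.append(k / fs)
        waveforms.append(trace[k - pre:k + post])
    if n_edge:
        log.info("dropped %d edge spike(s) whose window exceeds the trace", n_edge)

    if times:
        waveforms = np.asarray(waveforms)
        prominences = waveforms.max(axis=1) - waveforms.min(axis=1)
    else:
        waveforms = np.empty((0, pre + post))
        prominences = np.empty(0)
    return SpikeTrain(channel=channel, times=np.asarray(times, float),
                      waveforms=waveforms, align_index=pre,
                      prominences=prominences)
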