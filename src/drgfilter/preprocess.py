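"""Digital filtering of raw traces before spike detection.

The analysis chain high-pass filters each channel with a Butterworth filter
(default corner 60 Hz, order 4) applied forward and backward so that spike
times are not shifted. An optional 50/60 Hz IIR notch emulating a hardware
line-noise eliminator is available but disabled by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .errors import ParameterError

DEFAULT_CORNER_LOW = 60.0  # Hz
DEFAULT_ORDER = 4


@dataclass
class FilterSpec:
    kind: str = "highpass"          # {highpass, bandpass}
    corner_low: float = DEFAULT_CORNER_LOW
    corner_high: Optional[float] = None
    order: int = DEFAULT_ORDER
    notch_enabled: bool = False
    notch_freq: float = 50.0
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not 0 < self.corner_low < nyq:
            raise ParameterError(
                f"corner_low {self.corner_low} Hz outside (0, Nyquist={nyq})"
            )
        if self.kind == "bandpass":
            if self.corner_high is None:
                raise ParameterError("bandpass filter requires corner_high")
            if not self.corner_low < self.corner_high < nyq:
                raise ParameterError(
                    f"corner_high {self.corner_high} Hz must lie in "
                    f"(corner_low, Nyquist={nyq})"
                )
        elif self.kind != "highpass":
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")


def butter_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    spec.validate(fs)
    if spec.kind == "highpass":
        return signal.butter(spec.order, spec.corner_low, btype="highpass",
                             fs=fs, output="sos")
    return signal.butter(spec.order, [spec.corner_low, spec.corner_high],
                         btype="bandpass", fs=fs, output="sos")


def filter_trace(trace: np.ndarray, fs: float,
                 spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth filtering; output length equals input length.

    Forward-backward application squares the magnitude response, so the
    effective attenuation at a frequency f is |H(f)|^2 of the designed filter.
    """
    spec = spec or FilterSpec()
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ParameterError("trace must be one-dimensional")
    min_len = 3 * (2 * spec.order + 1)
    if len(trace) <= min_len:
        raise ParameterError(
            f"trace too short ({len(trace)} samples) for order-{spec.order} filter"
        )
    sos = butter_sos(spec, fs)
    y = signal.sosfiltfilt(sos, trace)
    if spec.notch_enabled:
        b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
        y = signal.filtfilt(b, a, y)
    return y


def butter_magnitude(spec: FilterSpec, fs: float, freqs) -> np.ndarray:
    """Analytic single-pass magnitude response |H(f)| at the given frequencies."""
    sos = butter_sos(spec, fs)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freqs, float)), fs=fs)
    return np.abs(h)
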