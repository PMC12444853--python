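"""Core data model and file I/O.

A :class:`Recording` holds the two simultaneously sampled extracellular
voltage traces — spinal nerve (SN, peripheral to the dorsal root ganglion)
and dorsal root (DR, central to it) — plus an optional synchronized force
channel in grams and the acquisition/geometry metadata every downstream
stage needs (sampling rate, inter-electrode distance).

Two on-disk layouts are supported:

* ``flatbin`` — interleaved little-endian float32 samples in the channel
  order given by a YAML sidecar (``<file>.yaml``) that also carries
  ``sampling_rate`` and ``electrode_distance``;
* ``delimited`` — CSV/TSV with a header row ``time,sn,dr[,force]`` whose
  time column must be uniformly sampled to 1 part in 1e6.

Event tables (spike trains, match tables, summaries) round-trip through
plain CSV with times written to nanosecond precision.

All times are seconds (float); sample indices exist only inside detection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, MetadataError, ParameterError

DEFAULT_SAMPLING_RATE = 30_000.0   # Hz
DEFAULT_ELECTRODE_DISTANCE = 0.004  # m, SN-to-DR hook electrode separation
DEFAULT_DEAD_TIME = 1e-3            # s, refractory guard against double counts

_TIME_FMT = "%.9f"  # nanosecond precision for CSV round trips


@dataclass
class Recording:
    """Aligned SN/DR voltage traces with optional force channel."""

    sn_trace: np.ndarray
    dr_trace: np.ndarray
    force_trace: Optional[np.ndarray] = None
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    electrode_distance: float = DEFAULT_ELECTRODE_DISTANCE
    channel_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sn_trace = np.asarray(self.sn_trace, dtype=float)
        self.dr_trace = np.asarray(self.dr_trace, dtype=float)
        if self.force_trace is not None:
            self.force_trace = np.asarray(self.force_trace, dtype=float)
        if self.sn_trace.ndim != 1 or self.dr_trace.ndim != 1:
            raise FormatError("traces must be one-dimensional")
        if len(self.sn_trace) != len(self.dr_trace):
            raise FormatError(
                f"channel length mismatch: sn={len(self.sn_trace)} "
                f"dr={len(self.dr_trace)}"
            )
        if self.force_trace is not None and len(self.force_trace) != len(self.sn_trace):
            raise FormatError("force trace length differs from voltage traces")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be positive")
        if not self.electrode_distance > 0:
            raise ParameterError("electrode_distance must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.sn_trace)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        name = name.lower()
        if name == "sn":
            return self.sn_trace
        if name == "dr":
            return self.dr_trace
        if name == "force":
            if self.force_trace is None:
                raise MetadataError("recording has no force channel")
            return self.force_trace
        raise ParameterError(f"unknown channel {name!r}")


@dataclass
class SpikeTrain:
    """Detected spike times and aligned waveform snippets for one channel.

    ``times`` are strictly increasing seconds; ``waveforms`` has one row per
    spike; ``align_index`` is the sample of the alignment extremum within the
    snippet window; ``prominences`` is the peak-to-trough amplitude per spike.
    """

    channel: str
    times: np.ndarray
    waveforms: np.ndarray
    align_index: int
    prominences: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
        self.prominences = np.asarray(self.prominences, dtype=float)
        if self.times.size == 0:
            self.waveforms = self.waveforms.reshape(0, self.waveforms.shape[-1])
        if len(self.times) != self.waveforms.shape[0]:
            raise FormatError("waveform row count differs from spike count")
        if len(self.times) != len(self.prominences):
            raise FormatError("prominence count differs from spike count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def window_samples(self) -> int:
        return self.waveforms.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "channel": self.channel,
                "prominence": self.prominences,
            }
        )


@dataclass
class EpochSpec:
    """A named analysis window: control / stimulus / recover or a user label."""

    name: str
    start: float
    duration: float

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ParameterError(f"epoch {self.name!r}: duration must be positive")

    @property
    def end(self) -> float:
        return self.start + self.duration

    def contains(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t)
        return (t >= self.start) & (t < self.end)


def check_epochs(epochs: list[EpochSpec]) -> None:
    """Raise if epochs within one analysis overlap."""
    ordered = sorted(epochs, key=lambda e: e.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ParameterError(f"epochs {a.name!r} and {b.name!r} overlap")


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in {".csv", ".tsv", ".txt"}:
        return "delimited"
    return "flatbin"


def write_recording(rec: Recording, path, format: str | None = None) -> Path:
    """Write a recording as flat float32 binary + sidecar, or delimited text."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "flatbin":
        channels = ["sn", "dr"] + (["force"] if rec.force_trace is not None else [])
        stack = [rec.sn_trace, rec.dr_trace]
        if rec.force_trace is not None:
            stack.append(rec.force_trace)
        interleaved = np.vstack(stack).T.astype("<f4")
        interleaved.tofile(path)
        meta = {
            "channels": channels,
            "sampling_rate": float(rec.sampling_rate),
            "electrode_distance": float(rec.electrode_distance),
            "channel_meta": dict(rec.channel_meta),
        }
        _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    elif fmt == "delimited":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        cols = {"time": rec.times, "sn": rec.sn_trace, "dr": rec.dr_trace}
        if rec.force_trace is not None:
            cols["force"] = rec.force_trace
        pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.9g")
    else:
        raise ParameterError(f"unknown recording format {fmt!r}")
    return path


def read_recording(path, format: str | None = None) -> Recording:
    """Read a recording written by :func:`write_recording` (or compatible)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "flatbin":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise MetadataError(f"missing sidecar metadata file {sidecar}")
        meta = yaml.safe_load(sidecar.read_text())
        for key in ("channels", "sampling_rate"):
            if key not in meta:
                raise MetadataError(f"sidecar {sidecar} lacks required key {key!r}")
        channels = [str(c).lower() for c in meta["channels"]]
        raw = np.fromfile(path, dtype="<f4")
        n_ch = len(channels)
        if n_ch == 0 or raw.size % n_ch:
            raise FormatError(
                f"{path}: sample count {raw.size} not divisible by "
                f"{n_ch} channels"
            )
        mat = raw.reshape(-1, n_ch).astype(float)
        by_name = {c: mat[:, i] for i, c in enumerate(channels)}
        if "sn" not in by_name or "dr" not in by_name:
            raise MetadataError("sidecar channel list must include 'sn' and 'dr'")
        return Recording(
            sn_trace=by_name["sn"],
            dr_trace=by_name["dr"],
            force_trace=by_name.get("force"),
            sampling_rate=float(meta["sampling_rate"]),
            electrode_distance=float(
                meta.get("electrode_distance", DEFAULT_ELECTRODE_DISTANCE)
            ),
            channel_meta=dict(meta.get("channel_meta", {})),
        )
    if fmt == "delimited":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        df.columns = [c.strip().lower() for c in df.columns]
        for col in ("time", "sn", "dr"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r}")
        t = df["time"].to_numpy(float)
        if len(t) < 2:
            raise FormatError(f"{path}: need at least two samples")
        dt = np.diff(t)
        dt0 = np.median(dt)
        if dt0 <= 0 or np.any(np.abs(dt - dt0) > 1e-6 * dt0):
            raise FormatError(f"{path}: time column is not uniformly sampled")
        return Recording(
            sn_trace=df["sn"].to_numpy(float),
            dr_trace=df["dr"].to_numpy(float),
            force_trace=df["force"].to_numpy(float) if "force" in df.columns else None,
            sampling_rate=1.0 / dt0,
        )
    raise ParameterError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# Event-table I/O
# ---------------------------------------------------------------------------

def write_events(obj, path) -> Path:
    """Write a spike train, match table or summary as one-row-per-event CSV."""
    path = Path(path)
    if isinstance(obj, SpikeTrain):
        df = obj.to_frame()
    elif isinstance(obj, pd.DataFrame):
        df = obj
    elif hasattr(obj, "to_frame"):
        df = obj.to_frame()
    else:
        raise ParameterError(f"cannot serialise object of type {type(obj).__name__}")
    df = df.copy()
    for col in df.columns:
        if col.endswith("_s") or col in ("time_s", "latency_s"):
            df[col] = df[col].map(
                lambda v: "" if pd.isna(v) else _TIME_FMT % v
            )
    df.to_csv(path, index=False)
    return path


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_waveforms(train: SpikeTrain, path) -> Path:
    """Store waveform snippets as float32 rows next to the event CSV."""
    path = Path(path)
    train.waveforms.astype("<f4").tofile(path)
    meta = {"n_spikes": int(len(train)), "window_samples": int(train.window_samples),
            "align_index": int(train.align_index), "channel": train.channel}
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_waveforms(path) -> tuple[np.ndarray, int]:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing sidecar metadata file {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    wf = np.fromfile(path, dtype="<f4").reshape(
        meta["n_spikes"], meta["window_samples"]
    ).astype(float)
    return wf, int(meta["align_index"])


def spike_train_from_frame(df: pd.DataFrame, waveforms: np.ndarray,
                           align_index: int) -> SpikeTrain:
    return SpikeTrain(
        channel=str(df["channel"].iloc[0]) if len(df) else "sn",
        times=df["time_s"].to_numpy(float),
        waveforms=waveforms,
        align_index=align_index,
        prominences=df["prominence"].to_numpy(float),
    )


def asdict_shallow(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
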