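"""Latency matching of dorsal-root spikes to their spinal-nerve origin.

A spike recorded on the DR must have crossed the dorsal root ganglion; its
origin is sought among the SN spikes that strictly precede it within a
tolerance window w = electrode_distance / v_min, the travel time of the
slowest theoretical fiber (defaults 4 mm / 0.1 m/s = 40 ms). Each DR spike,
processed in ascending time, is paired with the nearest preceding unclaimed
SN spike (minimum latency) inside the window; with exclusive matching an SN
spike can originate at most one DR spike. SN spikes left without a DR
partner are propagation failures.

Conduction velocity = distance / latency classifies fibers: C below
2 m/s, A at or above (the boundary itself goes to A by declared convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError, ParameterError

log = logging.getLogger(__name__)

DEFAULT_DISTANCE = 0.004  # m
DEFAULT_V_MIN = 0.1       # m/s, slowest theoretical conduction velocity
DEFAULT_V_SPLIT = 2.0     # m/s, C/A boundary


@dataclass
class MatchParams:
    distance: float = DEFAULT_DISTANCE
    v_min: float = DEFAULT_V_MIN
    v_split: float = DEFAULT_V_SPLIT
    exclusive: bool = True

    def __post_init__(self) -> None:
        if not self.distance > 0:
            raise ParameterError("distance must be positive")
        if not 0 < self.v_min < self.v_split:
            raise ParameterError("need 0 < v_min < v_split")

    @property
    def window(self) -> float:
        """Tolerance window in seconds (derived, never set directly)."""
        return self.distance / self.v_min


@dataclass
class MatchTable:
    """One row per SN spike plus the list of orphan DR spikes."""

    pairs: pd.DataFrame             # sn_index, dr_index, latency_s, velocity_mps,
                                    # fiber_class, unit_id, matched
    orphan_dr: np.ndarray           # DR indices with no eligible SN spike
    params: MatchParams = field(default_factory=MatchParams)
    n_dr: int = 0

    @property
    def n_sn(self) -> int:
        return len(self.pairs)

    @property
    def n_matched(self) -> int:
        return int(self.pairs["matched"].sum())

    def to_frame(self) -> pd.DataFrame:
        return self.pairs


def classify_fiber(latency: float, params: MatchParams | None = None) -> str:
    """Fiber class from conduction latency: 'C' below v_split, else 'A'."""
    params = params or MatchParams()
    if not latency > 0:
        raise DomainError(f"latency must be positive, got {latency}")
    if latency > params.window:
        raise DomainError(
            f"latency {latency}s exceeds tolerance window {params.window}s"
        )
    velocity = params.distance / latency
    return "C" if velocity < params.v_split else "A"


def match_spikes(sn_times, dr_times, params: MatchParams | None = None,
                 unit_labels=None) -> MatchTable:
    """Pair each DR spike with its nearest preceding SN spike within the window.

    DR spikes are processed in ascending time. With ``exclusive=True`` a
    claimed SN spike is skipped in favour of the next-nearest preceding
    unclaimed SN spike still inside the window; DR spikes with no eligible
    SN spike are reported as orphans. Latency must be strictly positive, so
    simultaneous timestamps never match.
    """
    params = params or MatchParams()
    sn = np.asarray(sn_times, dtype=float)
    dr = np.asarray(dr_times, dtype=float)
    for name, arr in (("sn_times", sn), ("dr_times", dr)):
        if arr.ndim != 1:
            raise ParameterError(f"{name} must be one-dimensional")
        if len(arr) > 1 and np.any(np.diff(arr) < 0):
            raise ParameterError(f"{name} must be sorted ascending")
    if unit_labels is not None:
        unit_labels = np.asarray(unit_labels)
        if len(unit_labels) != len(sn):
            raise ParameterError("unit_labels length differs from sn_times")

    w = params.window
    dr_of_sn = np.full(len(sn), -1, dtype=int)
    lat_of_sn = np.full(len(sn), np.nan)
    claimed = np.zeros(len(sn), dtype=bool)
    orphans = []

    ins = np.searchsorted(sn, dr, side="left")  # first SN index >= dr time
    for j, t in enumerate(dr):
        i = ins[j] - 1  # latest SN spike strictly before t
        while i >= 0 and t - sn[i] <= w:
            if claimed[i]:
                if params.exclusive:
                    i -= 1
                    continue
                break  # non-exclusive: SN row keeps its first (shortest) latency
            claimed[i] = True
            dr_of_sn[i] = j
            lat_of_sn[i] = t - sn[i]
            break
        else:
            orphans.append(j)

    matched = dr_of_sn >= 0
    with np.errstate(over="ignore", divide="ignore"):
        # a vanishing latency legitimately maps to an enormous velocity
        velocity = np.where(matched,
                            params.distance / np.where(matched, lat_of_sn, 1.0),
                            np.nan)
    fiber = np.where(matched,
                     np.where(velocity < params.v_split, "C", "A"), None)
    pairs = pd.DataFrame({
        "sn_index": np.arange(len(sn)),
        "dr_index": pd.array(np.where(matched, dr_of_sn, -1), dtype="Int64"),
        "latency_s": lat_of_sn,
        "velocity_mps": velocity,
        "fiber_class": fiber,
        "unit_id": unit_labels if unit_labels is not None
                   else np.full(len(sn), -1, dtype=int),
        "matched": matched,
    })
    pairs.loc[~matched, "dr_index"] = pd.NA
    return MatchTable(pairs=pairs, orphan_dr=np.asarray(orphans, dtype=int),
                      params=params, n_dr=len(dr))


def summarize_propagation(match: MatchTable) -> pd.DataFrame:
    """Per-unit propagation summary: counts, success/failure %, latency, class.

    Units labelled -1 (unassigned spikes) are excluded; a unit's fiber class
    comes from the median of its matched latencies (robust to stragglers).
    Units with zero SN spikes cannot occur by construction; units with zero
    matched spikes get NaN latency/velocity and no fiber class.
    """
    rows = []
    pairs = match.pairs
    for unit in sorted(pairs.loc[pairs["unit_id"] >= 0, "unit_id"].unique()):
        sub = pairs[pairs["unit_id"] == unit]
        n_sn = len(sub)
        n_matched = int(sub["matched"].sum())
        lat = sub.loc[sub["matched"], "latency_s"]
        med_lat = float(lat.median()) if n_matched else np.nan
        velocity = match.params.distance / med_lat if n_matched else np.nan
        rows.append({
            "unit_id": int(unit),
            "n_sn": n_sn,
            "n_matched": n_matched,
            "success_pct": 100.0 * n_matched / n_sn,
            "failure_pct": 100.0 * (1.0 - n_matched / n_sn),
            "mean_latency_s": float(lat.mean()) if n_matched else np.nan,
            "median_latency_s": med_lat,
            "velocity_mps": velocity,
            "fiber_class": (classify_fiber(med_lat, match.params)
                            if n_matched else None),
        })
    return pd.DataFrame(rows)


def pct_delta_spikes(n_sn: float, n_dr: float) -> float:
    """Bulk relative activity drop across the ganglion.

    %dSpikes = (SN - DR) / SN * 100, applicable to spike counts or rates.
    """
    if not n_sn > 0:
        raise DomainError("SN spike count/rate must be positive")
    return (n_sn - n_dr) / n_sn * 100.0


def correlate_prominence_filtering(prominence, pct_delta):
    """OLS of per-unit %dSpikes against spike prominence: (slope, intercept, r2)."""
    x = np.asarray(prominence, dtype=float)
    y = np.asarray(pct_delta, dtype=float)
    if len(x) != len(y):
        raise ParameterError("prominence and pct_delta lengths differ")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 units for a correlation")
    if np.ptp(y) == 0:
        # constant response: flat line, no explained variance
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
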