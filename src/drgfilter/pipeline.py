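"""Pipeline orchestration: configuration, staging and reproducible runs.

A :class:`PipelineConfig` gathers every stage default in one document
(YAML on disk); unknown keys are rejected by name so a typo cannot silently
fall back to a default. :func:`run_pipeline` executes
filter -> detect (SN, DR) -> sort (SN) -> match -> summarise -> rates on a
recording (measured or simulated) and writes every table, the fully
resolved configuration and a run log next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import DetectionParams, detect_spikes
from .errors import ParameterError
from .io import EpochSpec, Recording, check_epochs, write_events
from .match import MatchParams, match_spikes, summarize_propagation
from .preprocess import FilterSpec, filter_trace
from .rates import (DEFAULT_GRID_DT, DEFAULT_SMOOTH_SIGMA, instantaneous_rate,
                    regress_on_stimulus, resample_force)
from .simulate import (UnitSpec, biphasic_template, ramp_and_hold_force,
                       render_traces, simulate_trains)
from .sort import sort_spikes

log = logging.getLogger(__name__)


def _from_mapping(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ParameterError(
            f"unknown {context} key(s): {', '.join(sorted(unknown))}"
        )
    return cls(**data)


@dataclass
class SortingConfig:
    n_keep: int = 10
    min_cluster_size: int = 20
    max_units: int = 8


@dataclass
class RateConfig:
    grid_dt: float = DEFAULT_GRID_DT
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA


@dataclass
class PipelineConfig:
    filter: FilterSpec = field(default_factory=FilterSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    sorting: SortingConfig = field(default_factory=SortingConfig)
    matching: MatchParams = field(default_factory=MatchParams)
    rate: RateConfig = field(default_factory=RateConfig)
    epochs: list = field(default_factory=list)   # EpochSpec entries
    seed: int = 0
    out_dir: str = "drgfilter_out"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sections = {
            "filter": FilterSpec, "detection": DetectionParams,
            "sorting": SortingConfig, "matching": MatchParams,
            "rate": RateConfig,
        }
        known = set(sections) | {"epochs", "seed", "out_dir"}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        kwargs = {}
        for name, section_cls in sections.items():
            if name in data:
                kwargs[name] = _from_mapping(section_cls, data[name] or {}, name)
        if "epochs" in data:
            kwargs["epochs"] = [
                _from_mapping(EpochSpec, e, "epoch") for e in data["epochs"] or []
            ]
        for scalar in ("seed", "out_dir"):
            if scalar in data:
                kwargs[scalar] = data[scalar]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_scenario(path) -> dict:
    """Parse a simulation scenario document into generator arguments.

    Schema (all keys optional unless noted): ``duration`` (s), ``fs`` (Hz),
    ``distance`` (m), ``snr`` (peak over noise MAD) or ``noise_sd``,
    ``jitter_sd`` (s), ``units`` (required: list of unit_id, base_rate,
    velocity, failure_prob, force_gain, template {amplitude, width,
    polarity, asym}), ``epochs`` (name/start/duration), ``force`` (onset,
    ramp, hold, peak, optional release).
    """
    doc = yaml.safe_load(Path(path).read_text())
    return scenario_from_dict(doc)


def scenario_from_dict(doc: dict) -> dict:
    doc = dict(doc or {})
    known = {"duration", "fs", "distance", "snr", "noise_sd", "jitter_sd",
             "units", "epochs", "force"}
    unknown = set(doc) - known
    if unknown:
        raise ParameterError(
            f"unknown scenario key(s): {', '.join(sorted(unknown))}"
        )
    if "units" not in doc or not doc["units"]:
        raise ParameterError("scenario must define at least one unit")
    fs = float(doc.get("fs", 30_000.0))
    units = []
    for u in doc["units"]:
        u = dict(u)
        tmpl_args = u.pop("template", {}) or {}
        template = biphasic_template(
            fs,
            amplitude=float(tmpl_args.get("amplitude", 1.0)),
            width=float(tmpl_args.get("width", 2e-4)),
            polarity=int(tmpl_args.get("polarity", -1)),
            asym=float(tmpl_args.get("asym", 0.6)),
        )
        units.append(_from_mapping(UnitSpec, {**u, "template": template}, "unit"))
    epochs = [_from_mapping(EpochSpec, e, "epoch")
              for e in doc.get("epochs", []) or []]
    check_epochs(epochs)
    duration = float(doc.get("duration", 60.0))
    force = None
    if "force" in doc and doc["force"]:
        f = dict(doc["force"])
        force = ramp_and_hold_force(duration, onset=float(f["onset"]),
                                    ramp=float(f["ramp"]), hold=float(f["hold"]),
                                    peak=float(f["peak"]),
                                    release=f.get("release"))
    peak = max(np.max(np.abs(u.template)) for u in units)
    if "noise_sd" in doc:
        noise_sd = float(doc["noise_sd"])
    else:
        noise_sd = peak / (float(doc.get("snr", 8.0)) * 0.6745)
    return {"units": units, "duration": duration, "fs": fs,
            "distance": float(doc.get("distance", 0.004)),
            "jitter_sd": float(doc.get("jitter_sd", 1e-4)),
            "epochs": epochs, "force": force, "noise_sd": noise_sd}


def simulate_recording(scenario: dict, seed: int = 0):
    """Generate (Recording, GroundTruth) from a parsed scenario."""
    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    gt = simulate_trains(scenario["units"], duration=scenario["duration"],
                         epochs=scenario["epochs"], force=scenario["force"],
                         jitter_sd=scenario["jitter_sd"], seed=ss,
                         distance=scenario["distance"])
    rec = render_traces(gt, scenario["units"], fs=scenario["fs"],
                        noise_sd=scenario["noise_sd"], seed=ss.spawn(1)[0],
                        force=scenario["force"])
    return rec, gt


def run_pipeline(config: PipelineConfig, recording: Recording,
                 ground_truth=None, out_dir=None) -> Path:
    """Execute the full analysis chain and write all outputs.

    Stages: zero-phase filtering, threshold detection on both channels,
    waveform sorting on the SN (DR detections are screened for noise with
    the same machinery but never given independent identities), latency
    matching, per-unit propagation summary, instantaneous rates and — when
    a force channel exists — per-unit force regressions.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fs = recording.sampling_rate
    run_log: list[str] = []

    def stage(name):
        run_log.append(name)
        log.info("stage: %s", name)

    try:
        stage("filter")
        sn_f = filter_trace(recording.sn_trace, fs, config.filter)
        dr_f = filter_trace(recording.dr_trace, fs, config.filter)

        stage("detect")
        sn_spikes = detect_spikes(sn_f, fs, config.detection, channel="sn")
        dr_spikes = detect_spikes(dr_f, fs, config.detection, channel="dr")
        write_events(sn_spikes, out / "sn_spikes.csv")
        write_events(dr_spikes, out / "dr_spikes.csv")

        stage("sort")
        sorted_sn = sort_spikes(sn_spikes.waveforms,
                                n_keep=config.sorting.n_keep,
                                min_cluster_size=config.sorting.min_cluster_size,
                                max_units=config.sorting.max_units,
                                seed=config.seed,
                                align_index=sn_spikes.align_index)
        sorted_dr = sort_spikes(dr_spikes.waveforms,
                                n_keep=config.sorting.n_keep,
                                min_cluster_size=config.sorting.min_cluster_size,
                                max_units=config.sorting.max_units,
                                seed=config.seed + 1,
                                align_index=dr_spikes.align_index)
        pd.DataFrame({"spike_index": np.arange(len(sorted_sn.labels)),
                      "unit_id": sorted_sn.labels}).to_csv(
            out / "units.csv", index=False)

        stage("match")
        sn_keep = sorted_sn.labels >= 0
        # DR spikes are kept unless positively identified as noise; spikes
        # ambiguous between units are real and inherit identity via matching
        dr_keep = ~sorted_dr.noise_mask
        params = dataclasses.replace(config.matching,
                                     distance=recording.electrode_distance)
        # negative-peak realignment makes SN and DR timestamps refer to the
        # same waveform landmark, keeping conduction latencies consistent
        sn_t = sn_spikes.times[sn_keep] + sorted_sn.shifts[sn_keep] / fs
        dr_t = dr_spikes.times[dr_keep] + sorted_dr.shifts[dr_keep] / fs
        sn_order = np.argsort(sn_t, kind="stable")
        dr_order = np.argsort(dr_t, kind="stable")
        table = match_spikes(sn_t[sn_order], dr_t[dr_order], params,
                             unit_labels=sorted_sn.labels[sn_keep][sn_order])
        write_events(table.pairs, out / "matches.csv")

        stage("summarize")
        summary = summarize_propagation(table)
        summary.to_csv(out / "prop_summary.csv", index=False)

        stage("rates")
        rate_rows = []
        regressions = []
        duration = recording.duration
        for unit in sorted(set(sorted_sn.labels[sorted_sn.labels >= 0])):
            times = sn_spikes.times[sn_keep][
                sorted_sn.labels[sn_keep] == unit]
            series = instantaneous_rate(times, duration,
                                        grid_dt=config.rate.grid_dt,
                                        smooth_sigma=config.rate.smooth_sigma,
                                        scope=f"unit{unit}")
            rate_rows.append(pd.DataFrame({"time_s": series.grid_times,
                                           "rate_hz": series.rate,
                                           "unit_id": unit}))
            if recording.force_trace is not None:
                force_grid = resample_force(recording.force_trace, fs,
                                            series.grid_times)
                reg = regress_on_stimulus(series, force_grid, unit_id=unit)
                regressions.append(dataclasses.asdict(reg))
        if rate_rows:
            pd.concat(rate_rows, ignore_index=True).to_csv(
                out / "rates.csv", index=False)
        if regressions:
            pd.DataFrame(regressions).to_csv(out / "regressions.csv",
                                             index=False)
        if ground_truth is not None:
            ground_truth.sn_frame().to_csv(out / "truth_sn.csv", index=False)
            ground_truth.dr_frame().to_csv(out / "truth_dr.csv", index=False)
    except Exception as exc:
        failed_stage = run_log[-1] if run_log else "init"
        (out / "run_log.json").write_text(json.dumps(
            {"status": "error", "stage": failed_stage, "error": str(exc),
             "stages_completed": run_log[:-1]}, indent=2))
        raise

    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(),
                                                    sort_keys=False))
    (out / "run_log.json").write_text(json.dumps(
        {"status": "ok", "stages": run_log, "seed": config.seed,
         "version": __version__, "python": platform.python_version(),
         "n_sn_spikes": int(len(sn_spikes)), "n_dr_spikes": int(len(dr_spikes)),
         "n_units": int(sorted_sn.n_units)}, indent=2))
    return out
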