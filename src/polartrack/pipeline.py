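"""Run configuration and stage orchestration.

A :class:`RunConfig` names the stage to run, its inputs, and every stage
parameter (defaults match the conventional quantification settings: 3×3 and
4×4 smoothing windows, line width 10, 10-px bins stepped 5 px, 5-µm ROI
diameter, ratio scale 4000, correlation cutoff 0.8, 5-min spike anchor).
``run_pipeline`` executes the stage, writes its outputs plus a structured
log and the resolved config next to them, and is deterministic under a
fixed seed and config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calcium, comigration, imaging, io, kymo, polarity, syndata
from .errors import InputError, ParameterError

__all__ = ["RunConfig", "DEFAULT_PARAMS", "run_pipeline"]

DEFAULT_PARAMS: dict = {
    "smooth_window_kymo": 3,
    "smooth_window_calcium": 4,
    "line_width": 10,
    "bin_height_px": 10,
    "step_px": 5,
    "roi_diameter_um": 5.0,
    "ratio_scale": 4000.0,
    "cfp_floor": None,
    "drop_fraction": 0.15,
    "drop_window_s": 120.0,
    "search_window_s": 900.0,
    "anchor_min": 5.0,
    "prominence": 0.05,
    "min_separation_min": 1.0,
    "lag_window_min": 5.0,
    "cutoff": 0.8,
    "min_area_px": 4,
    "mad_k": 5.0,
    "pixel_size": 0.2,
    "frame_interval": 3.0,
}

STAGES = ("simulate", "kymo", "calcium", "polarity", "comigrate", "callose")
SCENARIOS = ("tube", "grain", "fret", "fractions", "callose")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline run."""

    stage: str
    out_dir: str
    seed: int = 0
    scenario: str | None = None
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ParameterError(f"unknown stage {self.stage!r}; one of {STAGES}")
        if self.stage == "simulate" and self.scenario not in SCENARIOS:
            raise ParameterError(f"simulate requires scenario, one of {SCENARIOS}")
        unknown = set(self.params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ParameterError(f"unknown config parameter(s): {sorted(unknown)}")

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**obj)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def resolved_params(self) -> dict:
        return {**DEFAULT_PARAMS, **self.params}


def _log(lines: list, out: Path, stage: str, message: str) -> None:
    line = f"[{stage}] {message}"
    lines.append(line)
    (out / "run.log").write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute one configured stage and write its outputs.

    Returns a dict of the stage's headline results (also serialized to
    ``results.json`` in the output directory alongside the resolved config
    and a one-line-per-step log).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.resolved_params()
    resolved = {
        "stage": config.stage,
        "scenario": config.scenario,
        "seed": config.seed,
        "inputs": config.inputs,
        "params": {k: v for k, v in p.items()},
        "out_dir": str(out),
    }
    (out / "config.resolved.json").write_text(json.dumps(resolved, indent=2, default=str) + "\n")
    log: list = []
    results: dict

    if config.stage == "simulate":
        results = _run_simulate(config, p, out, log)
    elif config.stage == "kymo":
        results = _run_kymo(config, p, out, log)
    elif config.stage == "calcium":
        results = _run_calcium(config, p, out, log)
    elif config.stage == "polarity":
        results = _run_polarity(config, p, out, log)
    elif config.stage == "comigrate":
        results = _run_comigrate(config, p, out, log)
    else:
        results = _run_callose(config, p, out, log)

    (out / "results.json").write_text(json.dumps(results, indent=2, default=str) + "\n")
    _log(log, out, config.stage, "done")
    return results


def _run_simulate(config: RunConfig, p: dict, out: Path, log: list) -> dict:
    seed = config.seed
    scenario = config.scenario
    _log(log, out, "simulate", f"scenario={scenario} seed={seed}")
    if scenario == "tube":
        sim = syndata.simulate_tube_movie(seed=seed)
        io.write_stack(out / "tube.tif", sim.stack)
        io.write_path_csv(out / "path.csv", sim.paths)
        truth = {
            "band_distance_um": sim.truth.params["band_distance_um"],
            "n_frames": sim.stack.n_frames,
        }
    elif scenario == "grain":
        sim = syndata.simulate_grain_dual_channel(seed=seed)
        io.write_stack(out / "ch1.tif", sim.channel1)
        io.write_stack(out / "ch2.tif", sim.channel2)
        io.write_roi_json(out / "site_roi.json", sim.site_roi)
        io.write_roi_json(out / "grain_roi.json", sim.grain_roi)
        truth = {"lag_min": sim.truth.params["lag_min"]}
    elif scenario == "fret":
        sim = syndata.simulate_fret_movie(seed=seed)
        io.write_stack(out / "cfp.tif", sim.cfp)
        io.write_stack(out / "yfp.tif", sim.yfp)
        io.write_roi_json(out / "roi.json", sim.roi)
        truth = {"spike_time_min": sim.truth.params["spike_time_min"]}
    elif scenario == "fractions":
        sim = syndata.simulate_fraction_table(seed=seed)
        sim.table.abundances.to_csv(out / "fractions.csv")
        truth = {
            "n_comigrating": sim.truth.params["n_comigrating"],
            "bait_id": sim.table.bait_id,
        }
        (out / "planted_ids.txt").write_text(
            "\n".join(sorted(sim.truth.params["planted_set"])) + "\n"
        )
    else:  # callose
        sim = syndata.simulate_callose_zstack(seed=seed)
        for g, slices in enumerate(sim.grains):
            io.write_stack(out / f"grain_{g:03d}.tif", np.stack(slices))
        truth = {"spot_prevalence": sim.truth.params["spot_prevalence"]}
    (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str) + "\n")
    return {"scenario": scenario, "truth": truth}


def _run_kymo(config: RunConfig, p: dict, out: Path, log: list) -> dict:
    stack = io.read_stack(
        config.inputs["stack"], p["pixel_size"], p["frame_interval"], "Venus"
    )
    paths = io.read_path_csv(config.inputs["path"], line_width=p["line_width"])
    if len(paths) == 1:
        paths = paths[0]
    _log(log, out, "kymo", f"{stack.n_frames} frames, smoothing {p['smooth_window_kymo']}x")
    smoothed = imaging.moving_average(stack, p["smooth_window_kymo"])
    k = kymo.build_kymograph(smoothed, paths)
    io.write_kymograph_csv(out / "kymograph.csv", k)
    io.write_stack(out / "kymograph.tif", k.matrix[None, :, :])
    res = kymo.binned_tip_distances(k, p["bin_height_px"], p["step_px"])
    pd.DataFrame(
        {"bin": range(res.n_bins), "distance_um": res.bin_distances}
    ).to_csv(out / "tip_distances.csv", index=False)
    _log(log, out, "kymo", f"average_distance_um={res.average_distance:.4f} n_bins={res.n_bins}")
    return {
        "average_distance_um": res.average_distance,
        "n_bins": res.n_bins,
        "n_rows": k.n_rows,
    }


def _run_calcium(config: RunConfig, p: dict, out: Path, log: list) -> dict:
    meta = dict(pixel_size=p["pixel_size"], frame_interval=p["frame_interval"])
    cfp = io.read_stack(config.inputs["cfp"], channel_label="CFP", **meta)
    yfp = io.read_stack(config.inputs["yfp"], channel_label="YFP", **meta)
    roi = io.read_roi_json(config.inputs["roi"])
    w = p["smooth_window_calcium"]
    ratio = calcium.ratio_stack(
        imaging.moving_average(yfp, w),
        imaging.moving_average(cfp, w),
        scale=p["ratio_scale"],
        cfp_floor=p["cfp_floor"],
    )
    trace = polarity.normalize_to_first(calcium.ratio_roi_trace(ratio, roi))
    io.write_trace_csv(out / "ratio_trace.csv", trace)
    timing = calcium.spike_time(
        trace,
        drop_fraction=p["drop_fraction"],
        drop_window_s=p["drop_window_s"],
        search_window_s=p["search_window_s"],
    )
    pd.DataFrame(
        [
            {
                "detected": timing.detected,
                "spike_time_min": timing.spike_time,
                "drop_time_min": timing.drop_time,
                "peak_value": timing.peak_value,
            }
        ]
    ).to_csv(out / "spike_timing.csv", index=False)
    if timing.detected:
        aligned = calcium.align_to_spike([trace], [timing], anchor_min=p["anchor_min"])[0]
        io.write_trace_csv(out / "ratio_trace_aligned.csv", aligned)
    _log(log, out, "calcium", f"detected={timing.detected} spike_time_min={timing.spike_time}")
    return {"detected": timing.detected, "spike_time_min": timing.spike_time}


def _run_polarity(config: RunConfig, p: dict, out: Path, log: list) -> dict:
    meta = dict(pixel_size=p["pixel_size"], frame_interval=p["frame_interval"])
    ch1 = io.read_stack(config.inputs["ch1"], channel_label="ch1", **meta)
    ch2 = io.read_stack(config.inputs["ch2"], channel_label="ch2", **meta)
    site = io.read_roi_json(config.inputs["site_roi"])
    traces = []
    for label, ch in (("ch1", ch1), ("ch2", ch2)):
        tr = polarity.normalize_to_first(imaging.roi_mean_trace(ch, site))
        io.write_trace_csv(out / f"{label}_trace.csv", tr)
        traces.append(tr)
    peaks = [
        polarity.detect_local_peaks(tr, p["prominence"], p["min_separation_min"])
        for tr in traces
    ]
    for label, ps in zip(("ch1", "ch2"), peaks):
        pd.DataFrame(
            {"peak_time_min": ps.peak_times, "peak_value": ps.peak_values}
        ).to_csv(out / f"{label}_peaks.csv", index=False)
    lag = polarity.peak_lag(peaks[0], peaks[1], window_min=p["lag_window_min"])
    pd.DataFrame({"lag_min": lag.paired_lags}).to_csv(out / "paired_lags.csv", index=False)
    _log(log, out, "polarity", f"mean_lag_min={lag.mean_lag} n_pairs={lag.n_pairs}")
    return {
        "mean_lag_min": lag.mean_lag,
        "sd_lag_min": lag.sd_lag,
        "n_pairs": lag.n_pairs,
        "unmatched_reference": lag.unmatched_reference,
    }


def _run_comigrate(config: RunConfig, p: dict, out: Path, log: list) -> dict:
    table = comigration.FractionProfileTable.from_csv(
        config.inputs["table"], bait_id=config.inputs["bait"]
    )
    normed, excluded = comigration.normalize_profiles(table)
    result = comigration.bait_correlation(normed, cutoff=p["cutoff"])
    result.to_frame().to_csv(out / "comigration.csv")
    if excluded:
        (out / "excluded_ids.txt").write_text("\n".join(map(str, excluded)) + "\n")
    res = {
        "n_detected": result.n_detected,
        "n_passing": result.n_passing,
        "n_excluded_zero_total": len(excluded),
    }
    if "coip_bait" in config.inputs:
        bait_ids = _read_id_list(config.inputs["coip_bait"])
        ctrl_ids = _read_id_list(config.inputs["coip_control"])
        comp = comigration.coip_unique(bait_ids, ctrl_ids)
        overlap = comigration.cross_reference(comp, result)
        pd.Series(sorted(comp.unique_to_bait), name="protein_id").to_csv(
            out / "coip_unique.csv", index=False
        )
        overlap.to_csv(out / "overlap.csv")
        res["n_unique_to_bait"] = len(comp.unique_to_bait)
        res["n_overlap"] = len(overlap)
    _log(log, out, "comigrate", f"n_passing={res['n_passing']}/{res['n_detected']}")
    return res


def _run_callose(config: RunConfig, p: dict, out: Path, log: list) -> dict:
    stack_paths = sorted(Path(config.inputs["stack_dir"]).glob("*.tif"))
    if not stack_paths:
        raise InputError(f"no TIFF z-stacks in {config.inputs['stack_dir']}")
    calls = []
    for sp in stack_paths:
        stack = io.read_stack(sp, p["pixel_size"], 1.0)
        proj = imaging.z_project(list(stack.frames), method="max")
        calls.append(
            imaging.count_spots(
                proj, min_area_px=p["min_area_px"], mad_k=p["mad_k"], pixel_size=p["pixel_size"]
            )
        )
    pct = imaging.fraction_with_spot(calls)
    pd.DataFrame(
        {"grain": [sp.name for sp in stack_paths], "n_spots": [c.n_spots for c in calls]}
    ).to_csv(out / "spot_counts.csv", index=False)
    _log(log, out, "callose", f"fraction_with_spot={pct:.2f}% of {len(calls)} grains")
    return {"fraction_with_spot_pct": pct, "n_grains": len(calls)}


def _read_id_list(path) -> set:
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}
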