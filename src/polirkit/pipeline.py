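"""End-to-end runs: plan -> gcode -> simulate -> analyze -> qc.

Each stage writes its artifacts under the config's output directory together
with the config hash that produced them, and appends a JSON-lines log record
(stage, timing, seed).  plan/gcode/simulate are bit-reproducible for a given
(config, seed).
"""

from __future__ import annotations

import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    DetectionRule,
    ROILayout,
    color_index,
    call_susceptibility,
    detect_growth,
    extract_series,
)
from .config import RunConfig, config_hash, dump_config, load_config
from .instrument import FrameStack, render_bar_target, render_timelapse
from .kinetics import MatrixModel
from .layout import HomingPolicy, ImagingArea, ScanTile, emit_gcode, plan_timelapse, tile_area
from .optics import JitterModel, NoiseModel, OpticsModel, calibrate_jitter, jitter_for_policy
from .qc import dof_width, positional_stats, resolution_from_target
from .scenarios import STRIP_LANES, color_full_range, reference_trace, strip_scene
from . import kinetics as kin

__all__ = ["run_pipeline", "PipelineError"]

STAGES = ("plan", "gcode", "simulate", "analyze", "qc")


class PipelineError(RuntimeError):
    pass


def _optics_from(cfg: RunConfig) -> OpticsModel:
    o = cfg["optics"]
    return OpticsModel(
        sensor_px=tuple(o["sensor_px"]),
        fov_mm=tuple(o["fov_mm"]),
        working_distance_mm=o["working_distance_mm"],
        focus_z_mm=o["focus_z_mm"],
        dof_mm=o["dof_mm"],
        sigma_min_px=o["sigma_min_px"],
        blur_slope_px_per_mm=o["blur_slope_px_per_mm"],
        noise=NoiseModel(**o["noise"]),
        channels=o["channels"],
    )


def _jitter_from(cfg: RunConfig) -> JitterModel:
    j = cfg["jitter"]
    if j["mad_x_um"] is not None and j["mad_y_um"] is not None:
        return calibrate_jitter(j["mad_x_um"], j["mad_y_um"])
    return jitter_for_policy(j["policy"])


def _log(out: Path, record: dict) -> None:
    with (out / "log.jsonl").open("a") as fh:
        fh.write(json.dumps(record) + "\n")


def run_pipeline(config, stages=STAGES) -> dict:
    """Run the requested stages; returns {stage: artifact path}.

    Stage dependencies are checked up front: ``analyze`` needs the stack
    from ``simulate`` (in this run or a previous one in the same out_dir).
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    dump_config(cfg, out / "config.yaml")
    (out / "config.hash").write_text(chash + "\n")

    optics = _optics_from(cfg)
    deck = ImagingArea(**cfg["deck"])
    artifacts: dict = {}

    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    plan = None
    for stage in stages:
        t0 = time.perf_counter()
        if stage == "plan":
            plan = _stage_plan(cfg, deck, optics)
            artifacts["plan"] = out / "plan.json"
            _write_plan(plan, artifacts["plan"], chash)
        elif stage == "gcode":
            plan = plan or _stage_plan(cfg, deck, optics)
            artifacts["gcode"] = out / "scan.gcode"
            artifacts["gcode"].write_text(
                f";CONFIG {chash}\n" + emit_gcode(plan, deck)
            )
        elif stage == "simulate":
            plan = plan or _stage_plan(cfg, deck, optics)
            artifacts["simulate"] = _stage_simulate(cfg, plan, optics, out)
        elif stage == "analyze":
            stack_dir = out / "stack"
            if not (stack_dir / "manifest.csv").exists():
                raise PipelineError(
                    "analyze requires a simulated stack; run the simulate stage first"
                )
            artifacts["analyze"] = _stage_analyze(cfg, optics, out)
        elif stage == "qc":
            artifacts["qc"] = _stage_qc(cfg, optics, out)
        _log(out, {
            "stage": stage, "seconds": round(time.perf_counter() - t0, 3),
            "seed": cfg.seed, "config_hash": chash, "version": __version__,
        })
    return artifacts


def _stage_plan(cfg: RunConfig, deck: ImagingArea, optics: OpticsModel):
    s = cfg["scan"]
    tiles = tile_area(deck, optics.fov_mm, s["overlap_frac"], z_mm=s["z_mm"], dwell_s=s["dwell_s"])
    return plan_timelapse(
        tiles, s["interval_min"], s["duration_h"], s["homing"], s["feedrate_mm_min"]
    )


def _write_plan(plan, path: Path, chash: str) -> None:
    d = {
        "config_hash": chash,
        "cycle_interval_min": plan.cycle_interval_min,
        "n_cycles": plan.n_cycles,
        "homing_policy": plan.homing_policy.value,
        "feedrate_mm_min": plan.feedrate_mm_min,
        "tiles": [
            {"index": t.index, "center_mm": list(t.center_mm), "z_mm": t.z_mm, "dwell_s": t.dwell_s}
            for t in plan.tiles
        ],
    }
    path.write_text(json.dumps(d, indent=1))


def _scenario_scene(cfg: RunConfig):
    sc = cfg["scenario"]
    matrix = MatrixModel(milk_fraction=sc["milk_fraction"])
    info = kin.GROWTH_PACKS[sc["pack"]]
    t_grid = np.arange(0.0, cfg["scan"]["duration_h"] * 60.0 + 1e-9, 1.0)
    lanes = []
    for i, lane in enumerate(STRIP_LANES):
        if sc["control_fails"]:
            trace = None
        else:
            exposure = None
            if lane != "control":
                exposure = kin.AntibioticExposure(
                    drug=lane, present=True, susceptible=info[f"{lane}_susceptible"]
                )
            trace = reference_trace(
                sc["pack"], mode=sc["mode"], matrix=matrix, t_grid=t_grid,
                pathlength_mm=sc["pathlength_mm"], exposure=exposure,
            )
        lanes.append((f"cap{i:02d}_{lane}", trace))
    return strip_scene(
        lanes, origin_mm=tuple(sc["strip_origin_mm"]),
        length_mm=sc["capillary_length_mm"], matrix=matrix,
    ), matrix


def _stage_simulate(cfg: RunConfig, plan, optics: OpticsModel, out: Path) -> Path:
    scene, _ = _scenario_scene(cfg)
    channels = ("fluor",) if cfg["scenario"]["mode"] == "fluorescence" else ("rgb",)
    stack = render_timelapse(
        plan, [scene], optics, out / "stack",
        jitter=_jitter_from(cfg), seed=cfg.seed, channels=channels,
    )
    return stack.directory


def _stage_analyze(cfg: RunConfig, optics: OpticsModel, out: Path) -> Path:
    stack = FrameStack.load(out / "stack")
    scene, _ = _scenario_scene(cfg)
    sc, an = cfg["scenario"], cfg["analysis"]
    tile0 = stack.manifest.tile.min()
    plan_tile = _stage_plan(cfg, ImagingArea(**cfg["deck"]), optics).tiles[int(tile0)]
    layout = ROILayout.from_scene(scene, plan_tile.center_mm)
    channel = "fluor" if sc["mode"] == "fluorescence" else "rgb"
    series = extract_series(stack, layout, optics, channel=channel, tile=int(tile0))

    rows = []
    for sid, s in series.items():
        df = s.frame()
        df.insert(0, "site", sid)
        rows.append(df)
    series_path = out / "series.csv"
    pd.concat(rows, ignore_index=True).to_csv(series_path, index=False)

    if sc["mode"] == "fluorescence":
        rule = DetectionRule(mode="fluorescence", baseline_frames=an["baseline_frames"],
                             k_sd=an["k_sd"], rel_increase=an["rel_increase"])
        signal_of = lambda s: s.corrected
    else:
        rule = DetectionRule(
            mode="colorimetric", baseline_frames=an["baseline_frames"], k_sd=an["k_sd"],
            abs_floor_frac=an["abs_floor_frac"],
            min_range=an["min_range_frac"] * color_full_range(250.0, sc["pathlength_mm"]),
        )
        signal_of = color_index

    calls = {}
    for sid, s in series.items():
        calls[sid] = detect_growth(s.t_min, signal_of(s), rule, sid)
    control = [c for sid, c in calls.items() if sid.endswith("control")]
    per_drug = {
        drug: [c for sid, c in calls.items() if sid.endswith(drug)]
        for drug in ("gentamicin", "ampicillin")
    }
    verdicts = call_susceptibility(control, per_drug, isolate=sc["pack"])
    calls_path = out / "calls.csv"
    pd.DataFrame(
        [
            {
                "isolate": v.isolate, "drug": v.drug, "verdict": v.verdict,
                "control_ttp_min": v.control_ttp_min,
                "drug_ttps_min": ";".join(f"{t:.1f}" for t in v.drug_ttps_min),
            }
            for v in verdicts
        ]
    ).to_csv(calls_path, index=False)
    return calls_path


def _stage_qc(cfg: RunConfig, optics: OpticsModel, out: Path) -> Path:
    from .optics import sample_pose_errors

    q = cfg["qc"]
    jitter = _jitter_from(cfg)
    locs = sample_pose_errors(jitter, int(q["n_positional"]), cfg.seed)
    stats = positional_stats(locs)
    pd.DataFrame([stats]).to_csv(out / "qc_position.csv", index=False)

    rows = []
    for z in np.arange(-q["z_sweep_mm"], q["z_sweep_mm"] + 1e-9, q["z_step_mm"]):
        img, groups = render_bar_target(optics, z_offset_mm=float(z))
        rows.append({"z_mm": float(z), "lp_per_mm": resolution_from_target(img, groups)})
    curve = pd.DataFrame(rows)
    curve["dof_width_mm"] = dof_width(curve)
    curve.to_csv(out / "qc_resolution.csv", index=False)
    return out / "qc_resolution.csv"
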