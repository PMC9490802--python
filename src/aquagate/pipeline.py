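"""End-to-end orchestration: configuration, staged execution, manifest.

Stages run in a fixed order and communicate only through the documented
CSV/JSON artifacts in the output directory, so any stage can be re-run in
isolation from the manifest.  With a synthetic input block the stages are

    simulate -> count -> states -> dataset -> fit -> predict -> report

(simulate also emits a toy water trajectory whose planted crossings the
count stage must recover); with trajectory inputs the counting path is
run on the supplied portable-CSV trajectories.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .gating import state_populations
from .intervals import IntervalScheme
from .model import (
    ModelSpec,
    check_convergence,
    fit,
    predict_all_states,
)
from .permeation import (
    CylinderSpec,
    SpuriousFilterCriteria,
    assign_compartments,
    detect_permeation_events,
    filter_spurious_events,
    transit_time_stats,
)
from .structures import read_trajectory, write_trajectory_csv
from .synthetic import (
    SyntheticSpec,
    default_spec,
    recovery_spec,
    simulate_flux_counts,
    simulate_state_traces,
    simulate_toy_trajectory,
    truth_report,
)

log = logging.getLogger("aquagate.pipeline")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    outdir: Path
    seed: int = 0
    synthetic: SyntheticSpec | None = None
    trajectories: dict[str, list[str]] | None = None
    cylinder: CylinderSpec = field(default_factory=CylinderSpec)
    scheme: IntervalScheme | None = None
    filter_criteria: SpuriousFilterCriteria = field(default_factory=SpuriousFilterCriteria)
    chains: int = 2
    iterations: int = 2000
    warmup: int = 1000
    log_level: str = "info"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.trajectories is None):
            raise ConfigurationError(
                "exactly one of synthetic/trajectory inputs must be configured"
            )
        if self.scheme is None and self.synthetic is not None:
            s = self.synthetic
            self.scheme = IntervalScheme(
                analysis_start=s.time_origin_ns,
                analysis_end=s.time_origin_ns + s.duration_ns,
            )


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    inp = raw.get("input", {})
    synthetic = None
    trajectories = None
    if "synthetic" in inp and inp["synthetic"] is not None:
        block = inp["synthetic"] or {}
        preset = block.get("preset", "default")
        if preset == "recovery":
            synthetic = recovery_spec()
        elif preset == "default":
            synthetic = default_spec()
        else:
            raise ConfigurationError(f"unknown synthetic preset {preset!r}")
        overrides = {
            k: block[k]
            for k in ("duration_ns", "frame_period_ps", "time_origin_ns", "replicas")
            if k in block
        }
        if "variants" in block:
            overrides["variants"] = tuple(block["variants"])
        if "chains" in block:
            overrides["chains"] = tuple(block["chains"])
        if overrides:
            synthetic = dataclasses.replace(synthetic, **overrides)
    if "trajectory" in inp and inp["trajectory"] is not None:
        trajectories = {
            str(k): list(v) for k, v in (inp["trajectory"].get("pores") or {}).items()
        }
        for pore, paths in trajectories.items():
            for p in paths:
                if not Path(p).exists():
                    raise ConfigurationError(f"trajectory path {p} (pore {pore}) not found")
    cyl = CylinderSpec(**(raw.get("cylinder") or {}))
    scheme = IntervalScheme(**raw["scheme"]) if raw.get("scheme") else None
    model_block = raw.get("model") or {}
    return PipelineConfig(
        outdir=Path(raw.get("outdir", "aquagate_out")),
        seed=int(raw.get("seed", 0)),
        synthetic=synthetic,
        trajectories=trajectories,
        cylinder=cyl,
        scheme=scheme,
        filter_criteria=SpuriousFilterCriteria(**(raw.get("filter") or {})),
        chains=int(model_block.get("chains", 2)),
        iterations=int(model_block.get("iterations", 2000)),
        warmup=int(model_block.get("warmup", 1000)),
        log_level=str(raw.get("log_level", "info")),
    )


def _config_hash(config: PipelineConfig) -> str:
    payload = repr(config).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest (also written to disk).

    Idempotent given identical config and seed; a stage failure aborts the
    run with the stage name while earlier stage outputs remain on disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    stage = "setup"
    try:
        if config.synthetic is not None:
            _run_synthetic(config, out, manifest)
        else:
            _run_trajectory(config, out, manifest)
    except Exception as exc:
        stage = manifest.get("failed_stage", stage)
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _mark(manifest, stage, path):
    manifest["stages"][stage] = str(path)
    log.info("stage %s -> %s", stage, path)


def _run_synthetic(config: PipelineConfig, out: Path, manifest: dict) -> None:
    spec = config.synthetic
    scheme = config.scheme
    seed = config.seed

    manifest["failed_stage"] = "simulate"
    traces = simulate_state_traces(spec, seed=seed)
    traces_path = out / "state_traces.csv"
    _write_traces_csv(traces, traces_path)
    toy_traj, toy_truth = simulate_toy_trajectory(spec.toy, seed=seed)
    toy_path = out / "toy_trajectory.csv"
    write_trajectory_csv(toy_traj, toy_path)
    truth_df = truth_report(spec)
    truth_df.to_csv(out / "truth.csv", index=False)
    _mark(manifest, "simulate", traces_path)

    manifest["failed_stage"] = "count"
    trace = assign_compartments(
        toy_traj,
        CylinderSpec(
            length=config.cylinder.length,
            radius=config.cylinder.radius,
            center_mode="fixed",
        ),
        water_atom_ids=toy_traj.atom_ids,
    )
    events = detect_permeation_events(trace, z_sf=config.filter_criteria.z_sf)
    kept, removed = filter_spurious_events(events, config.filter_criteria)
    ev_df = pd.DataFrame(
        {
            "water_id": [e.water_id for e in kept],
            "direction": [e.direction for e in kept],
            "entry_ns": [e.entry_time_ns for e in kept],
            "exit_ns": [e.exit_time_ns for e in kept],
            "transit_ns": [e.transit_time_ns for e in kept],
            "max_radial_nm": [e.max_radial_excursion_nm for e in kept],
        }
    )
    events_path = out / "toy_events.csv"
    ev_df.to_csv(events_path, index=False)
    counting = {
        "detected_total": len(events),
        "kept_after_filter": len(kept),
        "removed_spurious": len(removed),
        "planted_crossings": len(toy_truth),
    }
    if kept:
        mean_t, f1, f3 = transit_time_stats(kept)
        counting.update({"mean_transit_ns": mean_t, "frac_lt_1ns": f1, "frac_lt_3ns": f3})
    (out / "toy_counting.json").write_text(json.dumps(counting, indent=2))
    _mark(manifest, "count", events_path)

    manifest["failed_stage"] = "states"
    pops = []
    for pore, per_res in traces.items():
        for rid, tr in per_res.items():
            for state, frac in state_populations(tr).items():
                pops.append(
                    {
                        "variant": pore[0],
                        "replica": pore[1],
                        "chain": pore[2],
                        "residue": rid,
                        "state": state,
                        "fraction": frac,
                    }
                )
    pops_path = out / "state_populations.csv"
    pd.DataFrame(pops).to_csv(pops_path, index=False)
    _mark(manifest, "states", pops_path)

    manifest["failed_stage"] = "dataset"
    dataset, u_true = simulate_flux_counts(traces, scheme, spec, seed=seed)
    dataset_path = out / "dataset.csv"
    dataset.to_csv(dataset_path, index=False)
    _mark(manifest, "dataset", dataset_path)

    manifest["failed_stage"] = "fit"
    mspec = ModelSpec(
        state_space={
            rid: (proc.state_labels, proc.reference_state)
            for rid, proc in spec.residues.items()
        }
    )
    post = fit(
        dataset,
        mspec,
        chains=config.chains,
        iterations=config.iterations,
        warmup=config.warmup,
        seed=seed,
    )
    report = check_convergence(post)
    summary_path = out / "posterior_summary.json"
    summary_path.write_text(
        json.dumps(
            {
                "sampler": post.sampler_meta,
                "rhat_max": max(report.rhat.values()),
                "ess_min": min(report.ess.values()),
                "converged": report.passed,
                "offenders": report.offenders,
            },
            indent=2,
        )
    )
    _mark(manifest, "fit", summary_path)

    manifest["failed_stage"] = "predict"
    preds = predict_all_states(post)
    preds_path = out / "state_flux_predictions.csv"
    preds.to_csv(preds_path, index=False)
    _mark(manifest, "predict", preds_path)

    manifest["failed_stage"] = "report"
    merged = preds.merge(truth_df, on=["residue", "state"], how="left")
    merged["covered"] = (merged["lo95"] <= merged["expected_per_5ns"]) & (
        merged["expected_per_5ns"] <= merged["hi95"]
    )
    report_payload = {
        "n_rows": int(len(dataset)),
        "n_pores": int(dataset["pore_id"].nunique()),
        "mean_flux_count": float(dataset["flux_count"].mean()),
        "converged": report.passed,
        "predictions": merged.to_dict(orient="records"),
        "toy_counting": counting,
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report_payload, indent=2, default=str))
    _mark(manifest, "report", report_path)
    manifest.pop("failed_stage", None)


def _run_trajectory(config: PipelineConfig, out: Path, manifest: dict) -> None:
    manifest["failed_stage"] = "count"
    all_events = []
    for pore, paths in config.trajectories.items():
        traj = read_trajectory(paths)
        cyl = CylinderSpec(
            length=config.cylinder.length,
            radius=config.cylinder.radius,
            center_mode="fixed",
            center_point=config.cylinder.center_point,
        )
        trace = assign_compartments(traj, cyl, water_atom_ids=traj.atom_ids)
        events = detect_permeation_events(trace, z_sf=config.filter_criteria.z_sf)
        kept, _ = filter_spurious_events(events, config.filter_criteria)
        for e in kept:
            all_events.append(
                {
                    "pore_id": pore,
                    "water_id": e.water_id,
                    "direction": e.direction,
                    "entry_ns": e.entry_time_ns,
                    "exit_ns": e.exit_time_ns,
                    "transit_ns": e.transit_time_ns,
                    "max_radial_nm": e.max_radial_excursion_nm,
                }
            )
    events_path = out / "events.csv"
    pd.DataFrame(all_events).to_csv(events_path, index=False)
    _mark(manifest, "count", events_path)
    manifest["failed_stage"] = "report"
    report_path = out / "report.json"
    report_path.write_text(
        json.dumps({"n_events": len(all_events), "pores": list(config.trajectories)}, indent=2)
    )
    _mark(manifest, "report", report_path)
    manifest.pop("failed_stage", None)


def _write_traces_csv(traces, path: Path) -> None:
    """Run-length encoded state traces (one row per constant-state segment),
    keeping multi-microsecond traces at CSV-friendly size."""
    rows = []
    for pore, per_res in traces.items():
        for rid, tr in per_res.items():
            s = tr.states
            bounds = np.flatnonzero(np.diff(s)) + 1
            starts = np.concatenate([[0], bounds])
            ends = np.concatenate([bounds, [s.size]])
            for a, b in zip(starts, ends):
                rows.append(
                    {
                        "variant": pore[0],
                        "replica": pore[1],
                        "chain": pore[2],
                        "residue": rid,
                        "start_frame": int(a),
                        "n_frames": int(b - a),
                        "state": tr.state_labels[s[a]],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
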