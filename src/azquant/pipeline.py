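"""Configuration, orchestration, and reporting for end-to-end runs.

A run is described by one declarative config (YAML or dict): a seed, an
output directory, the stages to execute, and per-stage parameter blocks.
Unknown keys are rejected with a suggestion; every run writes the resolved
config and a reconciled report (inputs = passed + excluded per stage) next
to its outputs. All randomness derives from the single top-level seed, so
(config, seed) determine every artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import time
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, coloc, counting, ephys, io
from .synthetic import (
    BleachSimConfig,
    StimProtocol,
    SynapseSimConfig,
    TevcSimConfig,
    simulate_bleach_movie,
    simulate_synapse_stack,
    simulate_tevc_sweeps,
)
from . import puncta as puncta_mod

__all__ = ["load_config", "resolve_config", "config_hash", "run_pipeline"]

ALL_STAGES = ("simulate", "count", "coloc", "puncta", "ephys")

_STAGE_PARAM_DEFAULTS = {
    "count": {"penalty": None, "peak_window_frac": 0.25, "min_az_per_animal": 30},
    "coloc": {"mask_smooth_sigma": 1.0, "mask_min_component": 10},
    "puncta": {"k_mad": 6.0, "min_separation_voxels": 3, "dilation_radius": 0},
    "ephys": {
        "filter_hz": 360.0,
        "response_window": 0.02,
        "ppr_ipis_ms": [10.0, 30.0, 100.0],
        "ppr_sweeps": 3,
        "train_hz": 1.0,
        "train_duration": 30.0,
    },
}


def _sim_defaults(cls) -> dict:
    return {f.name: getattr(cls(), f.name) for f in dc_fields(cls)}


def _defaults() -> dict:
    return {
        "seed": 0,
        "output_dir": "azquant_run",
        "stages": list(ALL_STAGES),
        "bleach": {**_sim_defaults(BleachSimConfig),
                   "n_az": 4, "n_frames": 1200, "uv_onset_frame": 100,
                   "noise_sd": 2.0},
        "synapse": _sim_defaults(SynapseSimConfig),
        "tevc": _sim_defaults(TevcSimConfig),
        **{k: dict(v) for k, v in _STAGE_PARAM_DEFAULTS.items()},
    }


def _check_keys(given: dict, known: dict, context: str) -> None:
    for key in given:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f'; did you mean "{hint[0]}"?' if hint else ""
            raise ValueError(f'unknown config key "{key}" in {context}{suggestion}')


def resolve_config(overrides: dict | None = None) -> dict:
    """Fill defaults and validate; raises on unknown keys or bad stages."""
    overrides = overrides or {}
    base = _defaults()
    _check_keys(overrides, base, "top level")
    resolved = dict(base)
    for key, value in overrides.items():
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f'config key "{key}" must be a mapping')
            _check_keys(value, base[key], f'"{key}"')
            resolved[key] = {**base[key], **value}
        else:
            resolved[key] = value
    bad = set(resolved["stages"]) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stages {sorted(bad)}; valid: {ALL_STAGES}")
    return resolved


def load_config(path) -> dict:
    """Load a YAML run config, validate, and fill defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    return resolve_config(raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config: dict) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sim_config(cls, block: dict, seed: int):
    params = dict(block)
    params["seed"] = seed
    if cls is BleachSimConfig and isinstance(params.get("channels_per_az"), list):
        params["channels_per_az"] = tuple(params["channels_per_az"])
    for key in ("drift_per_frame", "stack_shape", "voxel_size", "psf_sigma"):
        if key in params and isinstance(params[key], list):
            params[key] = tuple(params[key])
    return cls(**params)


def run_pipeline(config: dict, output_dir=None) -> dict:
    """Execute the selected stages in dependency order; returns the report.

    Stage outputs are CSV/TIFF files under ``output_dir``; the resolved
    config echo (``config.json``) and the report (``report.json``) are
    written alongside. A stage exception aborts its dependents; the report
    records partial completion and the failure.
    """
    config = resolve_config(config if "stages" in config else config)
    out = Path(output_dir or config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    (out / "config.json").write_text(
        json.dumps(_jsonable(config), sort_keys=True, indent=1)
    )

    report: dict = {
        "version": __version__,
        "config_hash": config_hash(config),
        "stages": {},
    }
    state: dict = {}
    failed = False
    for stage in ALL_STAGES:
        if stage not in config["stages"]:
            continue
        if failed:
            report["stages"][stage] = {"status": "skipped: upstream failure"}
            continue
        t0 = time.perf_counter()
        try:
            record = _STAGE_RUNNERS[stage](config, seed, out, state)
            record["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - report and halt dependents
            record = {"status": f"failed: {type(exc).__name__}: {exc}"}
            failed = True
        record["seconds"] = round(time.perf_counter() - t0, 3)
        report["stages"][stage] = record

    report["ok"] = not failed
    (out / "report.json").write_text(json.dumps(_jsonable(report), sort_keys=True, indent=1))
    return report


# ---------------------------------------------------------------------------
# stage runners


def _run_simulate(config, seed, out, state):
    bcfg = _sim_config(BleachSimConfig, config["bleach"], seed)
    movie, btruth = simulate_bleach_movie(bcfg)
    io.save_tiff(out / "bleach_movie.tif", movie, pixel_size_nm=bcfg.pixel_size)
    btruth.to_csv(out / "bleach_truth.csv", index=False)

    scfg = _sim_config(SynapseSimConfig, config["synapse"], seed + 1)
    channels, struth = simulate_synapse_stack(scfg)
    for name in ("cac", "cac_a", "cac_b", "brp", "hrp"):
        io.save_tiff(out / f"stack_{name}.tif", channels[name],
                     pixel_size_nm=scfg.voxel_size[1])
    struth.to_csv(out / "synapse_truth.csv", index=False)
    struth.attrs["az_table"].to_csv(out / "synapse_truth_az.csv", index=False)

    state["bleach"] = (bcfg, movie, btruth)
    state["synapse"] = (scfg, channels, struth)
    state["tevc_cfg"] = _sim_config(TevcSimConfig, config["tevc"], seed + 2)
    n = int(bcfg.n_az) + len(struth)
    return {"n_input": n, "n_passed": n, "n_excluded": 0}


def _run_count(config, seed, out, state):
    if "bleach" not in state:
        raise RuntimeError("count stage requires the simulate stage")
    bcfg, movie_arr, btruth = state["bleach"]
    movie = counting.Movie(
        frames=movie_arr,
        frame_interval=1.0 / bcfg.frame_rate,
        pixel_size=bcfg.pixel_size,
        uv_onset_frame=bcfg.uv_onset_frame,
    )
    params = config["count"]
    rows = []
    n_excluded = 0
    for _, roi in btruth.iterrows():
        trace = counting.extract_roi_trace(
            movie, (int(round(roi["row"])), int(round(roi["col"])))
        )
        est = counting.count_channels_from_trace(
            trace, penalty=params["penalty"],
            peak_window_frac=params["peak_window_frac"],
        )
        if not est.qc_pass:
            n_excluded += 1
        rows.append(
            {"az_id": int(roi["az_id"]), "true_channels": int(roi["n_channels"]),
             "peak_intensity": est.peak_intensity,
             "unitary_intensity": est.unitary_intensity,
             "n_channels": est.n_channels,
             "n_unitary_events": est.n_unitary_events,
             "qc_pass": est.qc_pass, "qc_reasons": ";".join(est.qc_reasons)}
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "counts.csv", index=False)
    return {"n_input": len(df), "n_passed": len(df) - n_excluded,
            "n_excluded": n_excluded}


def _run_coloc(config, seed, out, state):
    if "synapse" not in state:
        raise RuntimeError("coloc stage requires the simulate stage")
    _, channels, _ = state["synapse"]
    params = config["coloc"]
    mask = coloc.build_mask(
        channels["hrp"], smooth_sigma=params["mask_smooth_sigma"],
        min_component_voxels=params["mask_min_component"],
    )
    res = coloc.colocalize(channels["cac"], channels["brp"], mask)
    df = pd.DataFrame([dataclasses.asdict(res)])
    df["flags"] = ";".join(res.flags)
    df.to_csv(out / "coloc.csv", index=False)
    return {"n_input": 1, "n_passed": 0 if res.flags else 1,
            "n_excluded": 1 if res.flags else 0}


def _run_puncta(config, seed, out, state):
    if "synapse" not in state:
        raise RuntimeError("puncta stage requires the simulate stage")
    scfg, channels, truth = state["synapse"]
    params = config["puncta"]
    hrp_mask = coloc.build_mask(channels["hrp"])
    kwargs = dict(
        voxel_size=scfg.voxel_size, k_mad=params["k_mad"],
        min_separation_voxels=params["min_separation_voxels"],
    )
    cac_p = puncta_mod.detect_puncta(channels["cac"], hrp_mask, channel_label="cac", **kwargs)
    brp_p = puncta_mod.detect_puncta(channels["brp"], hrp_mask, channel_label="brp", **kwargs)
    distances, n_skip = puncta_mod.nearest_brp_distance(cac_p, brp_p)
    per_az, global_mean, labels = puncta_mod.masked_intensity(
        channels["cac"], channels["brp"], dilation_radius=params["dilation_radius"]
    )
    # per-AZ isoform content within the brp-derived AZ labels
    bg_sel = hrp_mask.values & (labels == 0)
    ia = [channels["cac_a"][labels == az].mean() for az in per_az["az_id"]]
    ib = [channels["cac_b"][labels == az].mean() for az in per_az["az_id"]]
    classes, fractions = puncta_mod.classify_az_content(
        ia, ib, channels["cac_a"][bg_sel], channels["cac_b"][bg_sel]
    )
    per_az = per_az.assign(intensity_a=ia, intensity_b=ib, content_class=classes)
    per_az.to_csv(out / "az_measurements.csv", index=False)
    pd.DataFrame({"distance_nm": distances}).to_csv(out / "distances.csv", index=False)
    (out / "cohort.json").write_text(json.dumps(
        {"content_fractions": fractions,
         "median_distance_nm": float(np.median(distances)) if distances.size else None,
         "n_cac_puncta": len(cac_p), "n_brp_puncta": len(brp_p),
         "n_distance_excluded": n_skip,
         "global_cac_mean": global_mean},
        sort_keys=True, indent=1))
    return {"n_input": len(cac_p), "n_passed": len(cac_p) - n_skip,
            "n_excluded": n_skip}


def _run_ephys(config, seed, out, state):
    if "tevc_cfg" not in state:
        raise RuntimeError("ephys stage requires the simulate stage")
    base_cfg: TevcSimConfig = state["tevc_cfg"]
    params = config["ephys"]
    rows = []
    # paired pulses per IPI
    for i, ipi in enumerate(params["ppr_ipis_ms"]):
        cfg = dataclasses.replace(base_cfg, seed=base_cfg.seed + 10 + i)
        protocol = StimProtocol.paired_pulse(ipi)
        sweeps, _ = simulate_tevc_sweeps(cfg, protocol, n_sweeps=int(params["ppr_sweeps"]))
        a1, a2 = [], []
        for sweep in sweeps:
            filt = ephys.gaussian_lowpass(sweep, params["filter_hz"])
            m1 = ephys.measure_epsc(filt, protocol.stimulus_times[0],
                                    response_window=min(params["response_window"], ipi / 1e3))
            m2 = ephys.measure_epsc(filt, protocol.stimulus_times[1],
                                    response_window=params["response_window"])
            a1.append(m1.amplitude)
            a2.append(m2.amplitude)
        ppr = ephys.compute_ppr(a1, a2, ipi_ms=ipi)
        rows.append({"metric": "ppr_scheme_a", "ipi_ms": ipi, "value": ppr.scheme_a})
        rows.append({"metric": "ppr_scheme_b", "ipi_ms": ipi, "value": ppr.scheme_b})
    # 1 Hz depression train
    cfg = dataclasses.replace(base_cfg, seed=base_cfg.seed + 50)
    protocol = StimProtocol.train(params["train_hz"], params["train_duration"])
    sweeps, truth = simulate_tevc_sweeps(cfg, protocol, n_sweeps=1)
    filt = ephys.gaussian_lowpass(sweeps[0], params["filter_hz"])
    amps = [ephys.measure_epsc(filt, t, response_window=params["response_window"]).amplitude
            for t in protocol.stimulus_times]
    fit = ephys.fit_depression(protocol.stimulus_times, amps)
    rows.append({"metric": "depression_tau_s", "ipi_ms": np.nan, "value": fit.tau_s})
    rows.append({"metric": "depression_plateau_fraction", "ipi_ms": np.nan,
                 "value": fit.plateau_fraction})
    # mean quantal content from truth mEPSC amplitudes (detector-free input)
    mepscs = truth.attrs["mepscs"]
    if len(mepscs) >= 2 and len(amps) >= 1:
        q = ephys.mean_quantal_content(amps[:5], mepscs["amplitude_nA"])
        rows.append({"metric": "mean_quantal_content", "ipi_ms": np.nan, "value": q.mqc})
    df = pd.DataFrame(rows, columns=["metric", "ipi_ms", "value"])
    df.to_csv(out / "ephys_metrics.csv", index=False)
    return {"n_input": len(df), "n_passed": len(df), "n_excluded": 0}


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "count": _run_count,
    "coloc": _run_coloc,
    "puncta": _run_puncta,
    "ephys": _run_ephys,
}
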