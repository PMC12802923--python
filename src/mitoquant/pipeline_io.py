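"""Run configuration, file dialects, and the end-to-end demo pipeline.

A run is fully determined by a YAML config plus its referenced inputs: the
config carries a seed for every stochastic stage, unknown keys are rejected
up front, and each output CSV records the config hash and seed in a comment
header, so rerunning the same config reproduces every output byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bridges as bridge_mod
from . import chip as chip_mod
from . import image_quant, locus_dynamics, synth
from . import stats as stats_mod

logger = logging.getLogger("mitoquant")

__all__ = ["RunConfig", "load_config", "run_pipeline", "write_csv_with_header"]


DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "results/run",
    "stages": ["nuclei", "bridges", "loci", "chip"],
    "nuclei": {
        "n_scenes_per_condition": 2,
        "conditions": {"diffuse": 0.0, "focal": 0.5},
        "n_cells": 3,
        "mean_intensity": 1000.0,
        "noise_read_sd": 20.0,
        "expand_radius_px": 5.0,
        "target_nm": 65.0,
    },
    "bridges": {
        "n_scenes": 4,
        "bridge_fraction": 0.5,
        "bridge_channel": "DAPI",
        "dapi_threshold": 4000.0,
        "nop1_threshold": 5200.0,
    },
    "loci": {
        "n_cells_per_category": 5,
        "n_timepoints": 40,
        "sep_thr_um": 2.0,
        "eps_um": 0.25,
    },
    "chip": {
        "enrichment": 5.0,
        "spike_mix": 1.0,
        "ip_efficiency_exp": 0.2,
        "ip_efficiency_cal": 0.1,
        "total_reads": 200000,
        "flank_bp": 3000,
        "bin_bp": 50,
    },
}


class RunConfig(dict):
    """Validated nested config; access stage sections as items."""

    @property
    def hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        params = {k: v for k, v in self.items() if k != "out_dir"}
        canon = yaml.safe_dump(params, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _merge(defaults: dict, given: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in given.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and key != "conditions":
            if not isinstance(val, dict):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge(defaults[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; ``None`` gives the demo defaults."""
    given: dict = {}
    if path is not None:
        with open(path) as fh:
            given = yaml.safe_load(fh) or {}
        if not isinstance(given, dict):
            raise ValueError("config file must contain a mapping")
    if overrides:
        given = {**given, **overrides}
    return RunConfig(_merge(DEFAULTS, given))


def write_csv_with_header(df: pd.DataFrame, path: str | Path, config: RunConfig) -> Path:
    """Write a CSV with a reproducibility comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.10g")
    with open(path, "w") as fh:
        fh.write(f"# mitoquant config_hash={config.hash} seed={config['seed']}\n")
        fh.write(buf.getvalue())
    return path


def _stage_nuclei(config: RunConfig, out_dir: Path) -> list[Path]:
    p = config["nuclei"]
    rows = []
    for ci, (cond, ff) in enumerate(sorted(p["conditions"].items())):
        for s in range(p["n_scenes_per_condition"]):
            spec = synth.SceneSpec(
                n_cells=p["n_cells"],
                focal_fraction=float(ff),
                mean_intensity=p["mean_intensity"],
                noise=synth.NoiseModel(read_sd=p["noise_read_sd"]),
                seed=int(config["seed"]) * 1000 + 17 * s + 97 * ci,
            )
            stack, _, _ = synth.simulate_cell_stack(spec)
            df = image_quant.quantify_stack(
                stack, target_nm=p["target_nm"], expand_radius_px=p["expand_radius_px"]
            )
            df.insert(0, "condition", cond)
            df.insert(1, "scene", s)
            rows.append(df)
    nuclei = pd.concat(rows, ignore_index=True)
    out1 = write_csv_with_header(nuclei, out_dir / "nuclei.csv", config)

    groups = {c: g["CV"].dropna().to_numpy() for c, g in nuclei.groupby("condition")}
    usable = {c: v for c, v in groups.items() if len(v) >= 2}
    stat_rows = []
    if len(usable) >= 2:
        kw = stats_mod.kruskal_wallis(list(usable.values()), list(usable))
        stat_rows.append({"test": kw.test, "labels": "|".join(usable), "statistic": kw.statistic,
                          "pvalue": kw.pvalue})
        for r in stats_mod.mann_whitney_posthoc(usable):
            stat_rows.append({"test": r.test, "labels": "|".join(r.labels),
                              "statistic": r.statistic, "pvalue": r.pvalue})
    out2 = write_csv_with_header(pd.DataFrame(stat_rows), out_dir / "nuclei_stats.csv", config)
    return [out1, out2]


def _stage_bridges(config: RunConfig, out_dir: Path) -> list[Path]:
    p = config["bridges"]
    thr = bridge_mod.BridgeThresholds(dapi=p["dapi_threshold"], nop1=p["nop1_threshold"])
    n_bridge = int(round(p["n_scenes"] * p["bridge_fraction"]))
    rows = []
    for s in range(p["n_scenes"]):
        with_bridge = s < n_bridge
        spec = synth.SceneSpec(
            field_shape=(25, 96, 96),
            n_cells=1,
            anaphase=True,
            dapi_intensity=3 * p["dapi_threshold"],  # masses brighter than bridge
            nop1_intensity=0.3 * p["nop1_threshold"],
            bridge=synth.BridgeSpec(
                channel=p["bridge_channel"], intensity=2 * p["dapi_threshold"]
            ) if with_bridge else None,
            background=0.25 * p["dapi_threshold"],
            seed=int(config["seed"]) * 1000 + 31 * s,
        )
        stack, _, _ = synth.simulate_cell_stack(spec)
        iso = image_quant.resample_isotropic(stack, 65.0)
        try:
            call = bridge_mod.score_stack(iso, thr, cell=f"cell{s}")
        except bridge_mod.NotAnaphase:
            rows.append({"cell": f"cell{s}", "stat_dapi": np.nan, "stat_nop1": np.nan,
                         "class": "not_anaphase", "truth_bridge": with_bridge})
            continue
        rows.append({"cell": call.cell, "stat_dapi": call.stat_dapi,
                     "stat_nop1": call.stat_nop1, "class": call.klass,
                     "truth_bridge": with_bridge})
    return [write_csv_with_header(pd.DataFrame(rows), out_dir / "bridges.csv", config)]


def _stage_loci(config: RunConfig, out_dir: Path) -> list[Path]:
    p = config["loci"]
    rows = []
    for k, cat in enumerate(["not_separated", "breathing", "separated"]):
        spec = synth.TrajectorySpec(
            category=cat, n_timepoints=p["n_timepoints"],
            sep_thr_um=p["sep_thr_um"], eps_um=p["eps_um"],
            seed=int(config["seed"]) * 1000 + k,
        )
        for j, (t, d) in enumerate(synth.simulate_trajectories(spec, p["n_cells_per_category"])):
            call = locus_dynamics.classify_trajectory(
                d, t, sep_thr=p["sep_thr_um"], eps=p["eps_um"], cell=f"{cat}_{j}"
            )
            rows.append({"cell": call.cell, "truth": cat, "class": call.klass,
                         "max_distance_um": call.max_distance_um,
                         "first_crossing_min": call.first_crossing_min})
    return [write_csv_with_header(pd.DataFrame(rows), out_dir / "loci.csv", config)]


def _stage_chip(config: RunConfig, out_dir: Path) -> list[Path]:
    p = config["chip"]
    spec = synth.ChipSimSpec(
        spike_mix=p["spike_mix"],
        ip_efficiency_exp=p["ip_efficiency_exp"],
        ip_efficiency_cal=p["ip_efficiency_cal"],
        total_input_reads=p["total_reads"], total_ip_reads=p["total_reads"],
        enrichment=p["enrichment"], bin_bp=p["bin_bp"],
        seed=int(config["seed"]) * 1000 + 7,
    )
    sim = synth.simulate_chip_counts(spec)
    or_hat = chip_mod.occupancy_ratio(sim.summary)
    track = chip_mod.calibrate_track(sim.bins_ip_exp, sim.bin_bp, or_hat)
    prof = chip_mod.pileup_centromere(track, spec.layout_exp, p["flank_bp"], p["bin_bp"])
    df = prof.to_dataframe()
    df.insert(0, "or_estimated", or_hat)
    df.insert(1, "or_truth", sim.true_or)
    return [write_csv_with_header(df, out_dir / "chip_pileup.csv", config)]


_STAGES = {
    "nuclei": _stage_nuclei,
    "bridges": _stage_bridges,
    "loci": _stage_loci,
    "chip": _stage_chip,
}


def run_pipeline(config: RunConfig) -> list[Path]:
    """Execute the configured stages in order; returns the written files.

    A stage failure aborts the run with the stage name in the message.
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    for stage in config["stages"]:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r} (have {sorted(_STAGES)})")
        logger.info("running stage %s", stage)
        try:
            outputs.extend(_STAGES[stage](config, out_dir))
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return outputs
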