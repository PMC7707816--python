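"""Run configuration and end-to-end orchestration.

A run is described by a single structured text (YAML) config with
per-module blocks; unknown keys anywhere are rejected.  Every random
operation derives its seed deterministically from the global seed, so the
same config reproduces a run bit-for-bit; the manifest written with each
run echoes the config, seeds, and output files (no timestamps, so repeated
runs produce byte-identical manifests).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coloc import (
    ColocConfig,
    DetectionParams,
    Thresholds,
    analyze_volume,
    boutons_to_frame,
    summaries_to_frame,
    summarize_regions,
)
from .errors import ConfigError
from .evoked import analyze_train, compute_kinetics
from .io import save_channel_stack, save_sweepset, save_table
from .minis import MiniDetectParams, detect_minis
from .scenarios import SCENARIOS, simulate_scenario
from .synth_imaging import BoutonPopulation, VolumeSpec, generate_volume, truth_to_frame

logger = logging.getLogger("synaptiq")


def _build(cls, data: dict, context: str):
    """Instantiate a (possibly nested) dataclass, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        f = names[k]
        if dataclasses.is_dataclass(f.type) and isinstance(v, dict):
            kwargs[k] = _build(f.type, v, f"{context}.{k}")
        elif isinstance(v, list):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def _build_coloc_config(data: dict) -> ColocConfig:
    data = dict(data)
    thr = data.pop("thresholds", None)
    det = data.pop("detection", None)
    cfg = _build(ColocConfig, data, "coloc")
    if thr is not None:
        cfg = dataclasses.replace(cfg, thresholds=_build(Thresholds, thr,
                                                         "coloc.thresholds"))
    if det is not None:
        cfg = dataclasses.replace(cfg, detection=_build(DetectionParams, det,
                                                        "coloc.detection"))
    return cfg


@dataclass
class RunConfig:
    """Validated run description (see ``examples/configs``)."""

    seed: int = 0
    imaging: dict | None = None  # {volume: {...}, population: {...}, coloc: {...}}
    ephys: dict | None = None  # {scenario, n_trials, noise_sd, duration, window_ms}
    minis: dict | None = None  # {duration, noise_sd, detector: {...}}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        unknown = set(data) - {"seed", "imaging", "ephys", "minis"}
        if unknown:
            raise ConfigError(f"config: unknown keys {sorted(unknown)}")
        cfg = cls(
            seed=int(data.get("seed", 0)),
            imaging=data.get("imaging"),
            ephys=data.get("ephys"),
            minis=data.get("minis"),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self):
        if self.imaging is not None:
            allowed = {"volume", "population", "coloc"}
            unknown = set(self.imaging) - allowed
            if unknown:
                raise ConfigError(f"imaging: unknown keys {sorted(unknown)}")
        for name, block in (("ephys", self.ephys), ("minis", self.minis)):
            if block is None:
                continue
            allowed = {"scenario", "n_trials", "noise_sd", "duration",
                       "window_ms", "detector"}
            unknown = set(block) - allowed
            if unknown:
                raise ConfigError(f"{name}: unknown keys {sorted(unknown)}")
            scen = block.get("scenario")
            if name == "ephys" and scen is not None and scen not in SCENARIOS:
                raise ConfigError(f"ephys: unknown scenario '{scen}'")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages and write all outputs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s)
        for name, s in zip(("imaging", "ephys", "minis"), ss.generate_state(3))
    }
    outputs: list[str] = []

    def emit(path: Path):
        outputs.append(path.name)

    if config.imaging is not None:
        blk = config.imaging
        vspec = _build(VolumeSpec, {**blk.get("volume", {}),
                                    "seed": stage_seeds["imaging"]}, "volume")
        pop = _build(BoutonPopulation, blk.get("population", {}), "population")
        ccfg = _build_coloc_config(blk.get("coloc", {}))
        stack, truth = generate_volume(vspec, pop)
        emit(save_channel_stack(stack, outdir / "volume.tif"))
        emit(save_table(truth_to_frame(truth), outdir / "volume_truth.csv"))
        records = analyze_volume(stack, ccfg)
        emit(save_table(boutons_to_frame(records), outdir / "boutons.csv"))
        summaries = summarize_regions(records)
        emit(save_table(summaries_to_frame(summaries), outdir / "regions.csv"))
        logger.info("imaging stage: %d boutons detected", len(records))

    if config.ephys is not None:
        blk = config.ephys
        scenario = blk.get("scenario", "sync")
        result = simulate_scenario(
            scenario,
            seed=stage_seeds["ephys"],
            n_trials=int(blk.get("n_trials", 50)),
            noise_sd=float(blk.get("noise_sd", 2.0)),
        )
        sweep_sets = (
            {"sweeps_m60": result[0], "sweeps_0mv": result[1]}
            if isinstance(result, tuple)
            else {"sweeps": result}
        )
        rows = []
        for tag, sw in sweep_sets.items():
            emit(save_sweepset(sw, outdir / f"{tag}.csv"))
            if sw.truth is not None:
                emit(outdir / f"{tag}_truth.csv")
            if len(sw.acquisition.stimulus_times) > 1:
                tr = analyze_train(sw)
                for k, (q, nq) in enumerate(
                    zip(tr.charges_pc, tr.normalized_charge), start=1
                ):
                    rows.append({"sweeps": tag, "stimulus": k, "charge_pc": q,
                                 "normalized_charge": nq,
                                 "last_ipsc_decay_tau_ms": tr.last_ipsc_decay_tau_ms})
            else:
                window = tuple(blk.get("window_ms", (0.0, 100.0)))
                kin = compute_kinetics(sw, window_ms=window)
                rows.append({"sweeps": tag, "jitter_ms": kin.jitter_ms,
                             "half_rise_ms": kin.half_rise_ms,
                             "decay_tau_ms": kin.decay_tau_ms,
                             "peak_amplitude_pa": kin.peak_amplitude_pa,
                             "charge_pc": kin.charge_pc})
        import pandas as pd

        emit(save_table(pd.DataFrame(rows), outdir / "kinetics.csv"))
        logger.info("ephys stage: scenario '%s'", scenario)

    if config.minis is not None:
        blk = config.minis
        sw = simulate_scenario(
            "minis",
            seed=stage_seeds["minis"],
            noise_sd=float(blk.get("noise_sd", 2.0)),
            duration=float(blk.get("duration", 60.0)),
        )
        emit(save_sweepset(sw, outdir / "minis.csv"))
        emit(outdir / "minis_truth.csv")
        params = _build(MiniDetectParams, blk.get("detector", {}), "minis.detector")
        events = detect_minis(sw, params=params)
        import pandas as pd

        ev = pd.DataFrame(
            [
                {"onset_s": e.onset_s, "amplitude_pa": e.amplitude_pa,
                 "decay_ms": e.decay_ms, "charge_pc": e.charge_pc}
                for e in events
            ],
            columns=["onset_s", "amplitude_pa", "decay_ms", "charge_pc"],
        )
        emit(save_table(ev, outdir / "mini_events.csv"))
        logger.info("minis stage: %d events detected", len(events))

    manifest = {
        "package": "synaptiq",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "config": {
            "seed": config.seed,
            "imaging": config.imaging,
            "ephys": config.ephys,
            "minis": config.minis,
        },
        "outputs": sorted(set(outputs)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest
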