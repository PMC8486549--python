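"""End-to-end orchestration: simulate → preprocess → features → stats → classify.

A single :class:`PipelineConfig` (JSON or YAML on disk) drives all stages;
one master seed deterministically derives per-stage seeds, so two runs
with the same config produce byte-identical result tables, and each stage
can be re-run independently. Every run writes a ``manifest.json`` holding
the config snapshot, derived seeds, stage timings, per-stage outputs and
epoch counts before/after artifact rejection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import CLASSIFIER_NAMES, benchmark_all, normalize_rows
from .containers import EpochSet
from .features import assemble_dataset
from .io import (
    load_epochs,
    read_events,
    read_raw_recording,
    save_epochs,
    write_events,
    write_feature_tsv,
    write_raw_recording,
)
from .montage import REPORT_BANDS
from .preprocess import preprocess_recording
from .simulate import SimulationConfig, simulate_subject
from .stats import run_stat_battery

logger = logging.getLogger(__name__)

_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)} - {"effect_table", "coherence_specs", "montage"}


@dataclass
class PipelineConfig:
    """Knobs of a full run; everything not listed uses package defaults."""

    seed: int = 0
    simulation: dict = field(default_factory=dict)
    ptp_threshold_uv: float | None = 100.0
    low_hz: float = 0.1
    high_hz: float = 40.0
    components: tuple[str, ...] = ("P300", "LPP")
    bands: tuple[str, ...] = REPORT_BANDS
    datasets: tuple[str, ...] = ("1", "2", "3")
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    k_folds: int = 10
    modes: tuple[str, ...] = ("pooled", "per_subject")
    run_stats: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.simulation) - _SIM_KEYS
        if unknown:
            raise ValueError(f"unknown simulation config key(s): {sorted(unknown)}")
        for key, value in self.simulation.items():
            if key.endswith(("_per_block",)) or key in ("n_subjects", "blocks"):
                if value <= 0:
                    raise ValueError(f"simulation.{key} must be positive, got {value}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for name in ("components", "bands", "datasets", "classifiers", "modes"):
            if name in raw:
                raw[name] = tuple(str(x) for x in raw[name])
        return cls(**raw)

    def simulation_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(seed=seed, **self.simulation)


def derive_stage_seeds(master_seed: int) -> dict[str, int]:
    """Per-stage seeds from one master seed (kept below 2^31)."""
    ss = np.random.SeedSequence(int(master_seed))
    children = ss.spawn(2)
    return {
        "simulate": int(children[0].generate_state(1)[0] % (2**31)),
        "classify": int(children[1].generate_state(1)[0] % (2**31)),
    }


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_seeds: dict
    version: str
    stages: dict = field(default_factory=dict)
    epoch_counts: dict = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _stage(manifest: RunManifest, name: str, outputs: list[Path], t0: float) -> None:
    manifest.stages[name] = {
        "outputs": [str(p) for p in outputs],
        "seconds": round(time.perf_counter() - t0, 3),
    }


def run_pipeline(
    config: PipelineConfig | str | Path,
    out_dir: str | Path,
    *,
    seed: int | None = None,
    resume: bool = False,
) -> RunManifest:
    """Execute all stages under ``out_dir``; returns the run manifest.

    With ``resume=True`` a stage whose outputs already exist is skipped.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = derive_stage_seeds(config.seed)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seed=config.seed,
        stage_seeds=stage_seeds,
        version=__version__,
    )
    sim_cfg = config.simulation_config(stage_seeds["simulate"])

    # -- simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    sim_dir = out / "sim"
    sim_outputs = []
    subject_ids = sim_cfg.subject_ids()
    for i, sid in enumerate(subject_ids):
        stem = sim_dir / sid
        ev_path = sim_dir / f"{sid}_events.tsv"
        if resume and stem.with_suffix(".raw").exists() and ev_path.exists():
            sim_outputs += [stem.with_suffix(".raw"), ev_path]
            continue
        recording, events = simulate_subject(sim_cfg, i)
        sim_outputs.append(write_raw_recording(recording, stem))
        sim_outputs.append(write_events(events, ev_path))
    _stage(manifest, "simulate", sim_outputs, t0)

    # -- preprocess --------------------------------------------------------
    t0 = time.perf_counter()
    epochs_stem = out / "epochs" / "epochs"
    if resume and epochs_stem.with_suffix(".json").exists():
        epochs = load_epochs(epochs_stem)
    else:
        pieces, kept, dropped = [], 0, 0
        for sid in subject_ids:
            recording = read_raw_recording(sim_dir / sid, sim_cfg.montage)
            events = read_events(sim_dir / f"{sid}_events.tsv")
            ep, log = preprocess_recording(
                recording,
                events,
                low_hz=config.low_hz,
                high_hz=config.high_hz,
                ptp_threshold_uv=config.ptp_threshold_uv,
            )
            if log is not None:
                kept += log.n_kept
                dropped += log.n_dropped
            else:
                kept += ep.n_trials
            pieces.append(ep)
        epochs = EpochSet(
            np.concatenate([p.data for p in pieces]),
            pieces[0].time_ms,
            np.concatenate([p.labels for p in pieces]),
            np.concatenate([p.subject_ids for p in pieces]),
            pieces[0].montage,
            pieces[0].sampling_rate_hz,
            baseline_corrected=True,
        )
        manifest.epoch_counts = {
            "total": kept + dropped,
            "kept": kept,
            "rejected": dropped,
        }
        save_epochs(epochs, epochs_stem, provenance={"stage_seeds": stage_seeds})
    logger.info("epochs: %s", manifest.epoch_counts or "resumed")
    _stage(manifest, "preprocess", [epochs_stem.with_suffix(".raw")], t0)

    # -- features ----------------------------------------------------------
    t0 = time.perf_counter()
    feat_dir = out / "features"
    tables, feat_outputs = {}, []
    for ds in config.datasets:
        for comp in config.components:
            bands = [None] if ds == "1" else list(config.bands)
            for band in bands:
                key = (f"dataset{ds}", comp, band)
                table = assemble_dataset(epochs, ds, comp, band)
                tables[key] = table
                name = f"dataset{ds}_{comp}" + (f"_{band}" if band else "")
                feat_outputs.append(write_feature_tsv(table, feat_dir / f"{name}.tsv"))
    _stage(manifest, "features", feat_outputs, t0)

    # -- stats -------------------------------------------------------------
    t0 = time.perf_counter()
    stats_outputs = []
    if config.run_stats:
        battery = run_stat_battery(
            epochs,
            components=config.components,
            bands=config.bands,
            include_power="2" in config.datasets,
            include_coherence="3" in config.datasets,
        )
        path = out / "stats" / "paired_tests.tsv"
        path.parent.mkdir(parents=True, exist_ok=True)
        battery.to_csv(path, sep="\t", index=False, float_format="%.8g")
        stats_outputs.append(path)
    _stage(manifest, "stats", stats_outputs, t0)

    # -- classify ----------------------------------------------------------
    t0 = time.perf_counter()
    results = benchmark_all(
        {k: normalize_rows(t) for k, t in tables.items()},
        classifiers=config.classifiers,
        k=config.k_folds,
        seed=stage_seeds["classify"],
        modes=config.modes,
    )
    cls_dir = out / "classify"
    cls_dir.mkdir(parents=True, exist_ok=True)
    results_path = cls_dir / "results.tsv"
    results.to_csv(results_path, sep="\t", index=False, float_format="%.8g")
    _stage(manifest, "classify", [results_path], t0)

    manifest.save(out / "manifest.json")
    for name, info in manifest.stages.items():
        for p in info["outputs"]:
            assert Path(p).exists(), f"stage {name} lists missing output {p}"
    return manifest
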