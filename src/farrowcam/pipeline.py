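"""End-to-end orchestration: simulate -> beamform -> match -> metrics -> monitor.

A run is driven by one flat TOML config with per-stage sections ([sim],
[band], [detector], [match], [onset], [run]); the seed propagates to every
stochastic stage and every artefact carries a comment header echoing the
seed and stage, so identical configs reproduce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from . import __version__
from .annotation import EventLog, load_table, write_log
from .audio import write_wav
from .beamformer import CAMERA_BANDS, BandConfig, DetectorConfig
from .geometry import MicArray, PenGeometry, irregular_array, overhead_array
from .matcher import ConfusionCounts, MatchConfig, apply_location_policy, match
from .metrics import compute_metrics, metrics_report, write_report
from .onset import FarrowingReport, OnsetConfig, detect_onset, monitor_progress
from .scanner import scan_scene
from .scene_sim import SimConfig, simulate_scene, synthesize_mic_signals
from .beamformer import spots_to_log

log = logging.getLogger(__name__)

SCENE_PRESETS = ("full", "demo_30min", "quick")


def quick_sim_config(seed: int = 0) -> SimConfig:
    """A ~20 s toy scene with boosted event rates: enough activity for a
    fast demonstration of every pipeline stage."""
    cfg = SimConfig(
        seed=seed,
        pre_farrowing_s=8.0,
        post_farrowing_s=4.0,
        litter_size=2,
        first_birth_delay_s=2.0,
        birth_interval_mean_s=3.0,
        postnatal_tail_s=4.0,
    )
    cfg.event_rates = {
        "sow_vocal": {"before": 8.0, "during": 6.0, "after": 4.0},
        "trough": {"before": 3.0, "during": 1.0, "after": 1.0},
        "fence": {"before": 3.0, "during": 1.0, "after": 1.0},
        "neighbour": {"before": 3.0, "during": 3.0, "after": 3.0},
        "jute_rooting": {"before": 30.0, "during": 30.0, "after": 0.0},
        "piglet_move": {"before": 0.0, "during": 20.0, "after": 20.0},
    }
    return cfg


def sim_config_for_preset(preset: str, seed: int) -> SimConfig:
    if preset == "full":
        return SimConfig(seed=seed)
    if preset == "demo_30min":
        return SimConfig.demo_30min(seed=seed)
    if preset == "quick":
        return quick_sim_config(seed=seed)
    raise ValueError(f"unknown scene preset {preset!r}; choose from {SCENE_PRESETS}")


@dataclass
class RunConfig:
    """Aggregate configuration of a pipeline run."""

    sim: SimConfig = field(default_factory=lambda: quick_sim_config())
    band: BandConfig | None = None  # None: band around the simulated centre frequency
    detector: DetectorConfig = field(default_factory=lambda: DetectorConfig())
    match: MatchConfig = field(default_factory=lambda: MatchConfig(reference_mode="sound_or_behaviour"))
    onset: OnsetConfig = field(default_factory=OnsetConfig)
    geometry: PenGeometry = field(default_factory=PenGeometry)
    n_mics: int = 64
    out_dir: Path = Path("farrowcam_run")
    scene_preset: str = "quick"

    @property
    def array(self) -> MicArray:
        return irregular_array(self.geometry, n_mics=self.n_mics)


def _apply_section(obj, section: dict):
    known = {f.name for f in dataclasses.fields(obj)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown config key(s) for {type(obj).__name__}: {sorted(unknown)}")
    return replace(obj, **section) if dataclasses.fields(obj) else obj


def load_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a TOML file; CLI ``seed`` overrides the file."""
    doc: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    run_sec = doc.get("run", {})
    preset = run_sec.get("scene_preset", "quick")
    the_seed = seed if seed is not None else int(run_sec.get("seed", 0))
    cfg = RunConfig(scene_preset=preset)
    cfg.sim = sim_config_for_preset(preset, the_seed)
    for key, val in doc.get("sim", {}).items():
        if not hasattr(cfg.sim, key):
            raise ValueError(f"unknown [sim] key {key!r}")
        setattr(cfg.sim, key, val)
    cfg.sim.seed = the_seed
    if "band" in doc:
        b = doc["band"]
        if "camera" in b:
            cfg.band = BandConfig(*CAMERA_BANDS[b["camera"]])
        else:
            cfg.band = BandConfig(float(b["f_lo"]), float(b["f_hi"]))
    if "detector" in doc:
        cfg.detector = _apply_section(cfg.detector, doc["detector"])
    if "match" in doc:
        cfg.match = _apply_section(cfg.match, doc["match"])
    if "onset" in doc:
        cfg.onset = _apply_section(cfg.onset, doc["onset"])
    cfg.n_mics = int(run_sec.get("n_mics", 64))
    if "out_dir" in run_sec:
        cfg.out_dir = Path(run_sec["out_dir"])
    return cfg


def _header(stage: str, seed: int) -> str:
    return f"# farrowcam {__version__} | stage={stage} | seed={seed}\n"


def _write_log_with_header(log_: EventLog, path: Path, stage: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, seed))
    log_.entries.to_csv(path, mode="a", index=False, float_format="%.6f")


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute every stage and write the artefact directory:
    spots.csv, counts.json, metrics.csv, report.json, run.log."""
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.sim.seed
    stages = []

    def stage(name, fn):
        log.info("stage %s ...", name)
        try:
            res = fn()
        except Exception as exc:  # abort with the failing stage's name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stages.append(name)
        return res

    timeline, script, events, audible, behaviour = stage("simulate", lambda: simulate_scene(cfg.sim, cfg.geometry))
    _write_log_with_header(audible, out / "audible.csv", "simulate", seed)
    _write_log_with_header(behaviour, out / "behaviour.csv", "simulate", seed)

    spots = stage(
        "beamform",
        lambda: scan_scene(events, cfg.array, cfg.geometry, cfg.sim, cfg.detector, band=cfg.band,
                           t_stop=timeline.t_stop),
    )
    spot_log = spots_to_log(spots)
    _write_log_with_header(spot_log, out / "spots.csv", "beamform", seed)

    def do_match():
        mc = cfg.match
        res = match(
            spot_log, mc,
            audible=audible, behaviour=behaviour,
            sound_table=load_table("field1_sound"),
            behaviour_table=load_table("field2_behaviour"),
            window=(timeline.t_start, timeline.t_stop),
        )
        return res

    result = stage("match", do_match)
    counts_fn = result.counts("wrong_as_FN")
    counts_cp = result.counts("wrong_as_CP")
    with open(out / "counts.json", "w") as fh:
        json.dump(
            {
                "config": {"seed": seed, "reference_mode": cfg.match.reference_mode},
                "wrong_as_FN": counts_fn.as_dict(),
                "wrong_as_CP": counts_cp.as_dict(),
                "n_wrong_location": result.n_wrong_location,
            },
            fh,
            indent=2,
        )

    def do_metrics():
        df = metrics_report([
            (f"{cfg.match.reference_mode}/wrong_as_FN", counts_fn),
            (f"{cfg.match.reference_mode}/wrong_as_CP", counts_cp),
        ])
        with open(out / "metrics.csv", "w") as fh:
            fh.write(_header("metrics", seed))
        df.to_csv(out / "metrics.csv", mode="a", index=False, float_format="%.4f")
        return df

    stage("metrics", do_metrics)

    def do_monitor():
        report = detect_onset(spot_log, cfg.onset)
        if report.t_onset_est is not None:
            report = monitor_progress(spot_log, report, cfg.onset)
        doc = {
            "config": {"seed": seed, "window_s": cfg.onset.window_s},
            "t_onset_true": timeline.t_onset,
            "t_end_true": timeline.t_end_farrowing,
            "t_onset_est": report.t_onset_est,
            "t_end_est": report.t_end_est,
            "progress_intervals": report.progress_intervals,
            "alerts": [{"t": t, "kind": k} for t, k in report.alerts],
        }
        with open(out / "report.json", "w") as fh:
            json.dump(doc, fh, indent=2)
        return report

    stage("monitor", do_monitor)

    with open(out / "run.log", "w") as fh:
        fh.write(f"farrowcam {__version__}\n")
        fh.write(f"python {sys.version.split()[0]} numpy {np.__version__}\n")
        fh.write(f"seed {seed}\nscene_preset {cfg.scene_preset}\n")
        fh.write(f"stages {' '.join(stages)}\n")
    return out


def make_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the packaged reference fixtures and a small seeded demo scene:
    correspondence CSVs, the field-study counts JSON, a demo TOML config,
    the demo event logs and a short multichannel demo WAV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("field1_sound", "field2_sound", "field2_behaviour"):
        src = resources.files("farrowcam.data") / f"{name}.csv"
        dst = out / f"{name}.csv"
        dst.write_text(src.read_text())
        written.append(dst)
    src = resources.files("farrowcam.data") / "field1_counts.json"
    dst = out / "field1_counts.json"
    dst.write_text(src.read_text())
    written.append(dst)

    cfg_path = out / "demo_config.toml"
    cfg_path.write_text(
        "# farrowcam demo configuration\n"
        "[run]\n"
        f"seed = {seed}\n"
        'scene_preset = "quick"\n'
        "n_mics = 16\n\n"
        "[match]\n"
        'reference_mode = "sound_or_behaviour"\n'
    )
    written.append(cfg_path)

    sim = quick_sim_config(seed=seed)
    geometry = PenGeometry()
    timeline, script, events, audible, behaviour = simulate_scene(sim, geometry)
    write_log(audible, out / "demo_audible.csv")
    write_log(behaviour, out / "demo_behaviour.csv")
    written += [out / "demo_audible.csv", out / "demo_behaviour.csv"]

    array = irregular_array(geometry, n_mics=16)
    demo_events = [e for e in events if e.t < 4.0]
    sig = synthesize_mic_signals(demo_events, array, geometry, sim, t0=0.0, t1=4.0)
    write_wav(out / "demo_scene.wav", sig, sim.fs)
    written.append(out / "demo_scene.wav")
    return written
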