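"""File I/O, run manifest and end-to-end pipeline orchestration.

Stage order mirrors the experiment: simulate the cell pulse, render the
field-of-view video, track it, analyze the tracks into chromatography
metrics, and compare across runs.  Any contiguous subset of stages can run;
each stage records its inputs, outputs and seed in the run manifest so every
stochastic output is reproducible.

Tables are CSV with a leading ``# adchrom-schema: <name> v<major>`` comment
line; readers reject unknown major versions.  Summaries are JSON with a
``schema_version`` field.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chromatography import (
    PopulationSummary,
    records_from_tracks,
    records_from_transits,
    records_to_frame,
    summarize_population,
)
from .config import RunConfig, load_config, save_config
from .synthetic import (
    GroundTruthTransit,
    render_video,
    simulate_transits,
    transits_to_frame_table,
    write_tiff,
)
from .tracker import track_stack, track_summaries, tracks_to_table

__all__ = [
    "RunManifest",
    "write_table",
    "read_table",
    "run_pipeline",
    "SCHEMA_MAJOR",
]

logger = logging.getLogger(__name__)

SCHEMA_MAJOR = 1
_SCHEMA_PREFIX = "# adchrom-schema:"


class SchemaError(ValueError):
    """A table or summary carries an unsupported schema version."""


def write_table(frame: pd.DataFrame, path: str | Path, name: str) -> None:
    """Write a CSV table with its schema tag as the first line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_SCHEMA_PREFIX} {name} v{SCHEMA_MAJOR}\n")
        frame.to_csv(fh, index=False)


def read_table(path: str | Path, name: Optional[str] = None) -> pd.DataFrame:
    """Read a schema-tagged CSV, verifying the name and major version."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(_SCHEMA_PREFIX):
            raise SchemaError(f"{path}: missing '{_SCHEMA_PREFIX}' header line")
        tag = header[len(_SCHEMA_PREFIX):].strip()
        tag_name, _, version = tag.rpartition(" v")
        if name is not None and tag_name != name:
            raise SchemaError(f"{path}: expected schema '{name}', found '{tag_name}'")
        try:
            major = int(version.split(".")[0])
        except ValueError as exc:
            raise SchemaError(f"{path}: unparseable schema version '{version}'") from exc
        if major > SCHEMA_MAJOR:
            raise SchemaError(
                f"{path}: schema major version {major} is newer than supported "
                f"({SCHEMA_MAJOR})"
            )
        return pd.read_csv(fh)


@dataclass
class RunManifest:
    """Record of a pipeline run: config, seeds, artifacts, stage completion."""

    run_id: str
    seed: int
    config_path: Optional[str] = None
    software_version: str = __version__
    schema_version: int = SCHEMA_MAJOR
    seeds: Dict[str, int] = field(default_factory=dict)
    artifacts: Dict[str, str] = field(default_factory=dict)
    stages_completed: List[str] = field(default_factory=list)
    # video time of frame 0 relative to pulse injection (s); rendered videos
    # may be trimmed to start just before the first cell arrives
    time_origin_s: float = 0.0

    def record(self, stage: str, **artifacts: str) -> None:
        self.artifacts.update({k: str(v) for k, v in artifacts.items()})
        if stage not in self.stages_completed:
            self.stages_completed.append(stage)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        if int(data.get("schema_version", 0)) > SCHEMA_MAJOR:
            raise SchemaError(f"{path}: manifest schema newer than supported")
        return cls(**data)


def transits_to_frame(transits: Sequence[GroundTruthTransit]) -> pd.DataFrame:
    """Tabulate ground-truth transits (one row per cell)."""
    return pd.DataFrame(
        [
            (
                tr.cell_id, tr.t_offset_s, tr.t_elution_s, tr.true_binding_fraction,
                tr.v_roll_um_s, len(tr.intervals), tr.censored,
            )
            for tr in transits
        ],
        columns=[
            "cell_id", "t_offset_s", "t_elution_s", "true_binding_fraction",
            "v_roll_um_s", "n_intervals", "censored",
        ],
    )


_STAGES = ("simulate", "render", "track", "analyze")


def run_pipeline(
    config: RunConfig | str | Path,
    outdir: str | Path,
    stages: Sequence[str] = _STAGES,
    run_id: str = "run",
    seed: Optional[int] = None,
    video_duration_s: Optional[float] = None,
    lane_spacing: str = "uniform",
) -> RunManifest:
    """Execute a contiguous subset of pipeline stages, writing artifacts.

    ``seed`` overrides the seeds in the config's simulation/render sections
    (stage seeds are derived deterministically and recorded in the
    manifest).  ``video_duration_s`` caps the rendered video length so demo
    runs stay small.  Stages later in the chain require either an earlier
    stage in the same call or the corresponding artifact already on disk in
    ``outdir``.
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        config = load_config(config_path)
    else:
        config_path = None
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    order = [s for s in _STAGES if s in stages]
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    if order != list(stages):
        raise ValueError(f"stages must follow the order {_STAGES}")

    sim = config.simulation
    render_cfg = config.render
    if seed is not None:
        ss = np.random.SeedSequence(seed)
        sim_seed, render_seed = (int(s) % (2**31) for s in ss.generate_state(2))
        sim = dataclasses.replace(sim, seed=sim_seed)
        render_cfg = dataclasses.replace(render_cfg, seed=render_seed)
    manifest = RunManifest(
        run_id=run_id,
        seed=-1 if seed is None else seed,
        config_path=None if config_path is None else str(config_path),
        seeds={"simulate": sim.seed, "render": render_cfg.seed},
    )
    prior_manifest = outdir / "manifest.json"
    if "render" not in order and prior_manifest.exists():
        manifest.time_origin_s = RunManifest.load(prior_manifest).time_origin_s
    save_config(config, outdir / "config.yaml")
    manifest.record("config", config=outdir / "config.yaml")

    transits: Optional[List[GroundTruthTransit]] = None
    if "simulate" in order:
        logger.info("simulate: %d cells", sim.n_cells)
        transits = simulate_transits(
            sim, config.condition, config.geometry,
            acquisition_duration_s=config.analysis.acquisition_duration_s,
        )
        path = outdir / "transits.csv"
        write_table(transits_to_frame(transits), path, "transits")
        manifest.record("simulate", transits=path)

    stack = None
    frame_table = None
    if "render" in order:
        if transits is None:
            raise FileNotFoundError("render requires the simulate stage in this call")
        eluted = [tr.t_elution_s for tr in transits if not tr.censored]
        manifest.time_origin_s = max(min(eluted, default=0.0) - 2.0, 0.0)
        frame_table = transits_to_frame_table(
            transits, config.geometry, render_cfg, lane_spacing=lane_spacing,
            time_origin_s=manifest.time_origin_s,
        )
        if video_duration_s is not None:
            n_frames = int(round(video_duration_s * render_cfg.frame_rate_hz))
            frame_table = frame_table[frame_table["frame"] < n_frames]
        else:
            n_frames = None
        logger.info("render: %d frame rows", len(frame_table))
        stack = render_video(frame_table, render_cfg, n_frames=n_frames)
        video_path = outdir / "video.tif"
        write_tiff(stack, video_path)
        truth_path = outdir / "truth_tracks.csv"
        write_table(frame_table, truth_path, "truth-tracks")
        manifest.record("render", video=video_path, truth_tracks=truth_path)

    summaries = None
    if "track" in order:
        if stack is None:
            video_path = outdir / "video.tif"
            if not video_path.exists():
                raise FileNotFoundError(f"track stage needs {video_path}")
            import tifffile

            stack = tifffile.imread(video_path)
        tcfg = config.tracker.resolved(config.condition.v_free_flow_um_s)
        logger.info("track: %d frames", len(stack))
        tracks = track_stack(stack, tcfg)
        write_table(tracks_to_table(tracks, tcfg), outdir / "tracks.csv", "track-table")
        summaries = track_summaries(tracks, tcfg)
        write_table(summaries, outdir / "track_summaries.csv", "track-summaries")
        manifest.record(
            "track",
            tracks=outdir / "tracks.csv",
            track_summaries=outdir / "track_summaries.csv",
        )

    if "analyze" in order:
        acfg = config.analysis.resolved(
            config.render.pixel_size_um, config.render.frame_rate_hz
        )
        if summaries is not None:
            records = records_from_tracks(
                summaries, config.condition, config.geometry, acfg,
                time_origin_s=manifest.time_origin_s,
            )
            n_censored = 0
        elif transits is not None:
            records = records_from_transits(
                transits, config.condition, config.geometry, acfg
            )
            n_censored = sum(tr.censored for tr in transits)
        else:
            summary_path = outdir / "track_summaries.csv"
            if not summary_path.exists():
                raise FileNotFoundError(f"analyze stage needs {summary_path}")
            records = records_from_tracks(
                read_table(summary_path, "track-summaries"),
                config.condition, config.geometry, acfg,
                time_origin_s=manifest.time_origin_s,
            )
            n_censored = 0
        logger.info("analyze: %d cell records (%d censored)", len(records), n_censored)
        write_table(records_to_frame(records), outdir / "cell_records.csv", "cell-records")
        summary = summarize_population(records, acfg.residence_bin_width_s)
        (outdir / "population_summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2)
        )
        manifest.record(
            "analyze",
            cell_records=outdir / "cell_records.csv",
            population_summary=outdir / "population_summary.json",
        )

    manifest.save(outdir / "manifest.json")
    return manifest
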