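"""Adhesion chromatography metrics.

A pulse of cells perfused down a selectin-functionalized channel elutes into
the field of view after a transit time set by how persistently each cell
engages the substrate.  Two complementary speed readouts follow:

* **instantaneous velocity** ``V_inst`` — the frame-to-frame speed inside the
  field of view (a local, seconds-scale measurement), summarized per cell as
  the median step speed; and
* **average velocity** ``V_avg = L_channel / (t_elution − t_offset)`` — a
  whole-channel speed from the elution time corrected by the mean
  settling-feature dwell.

From a mass balance over a transit spent alternating between a bound phase at
``V_inst`` and free flow at ``v_free_flow``, the fraction of transit time a
cell spends adhesively engaged — the *percent binding time* — is

    %BT = [v_ff·(t_e − t_o) − L] / [(v_ff − V_inst)·(t_e − t_o)]

which is 0 for a pure free-flow transit (t_e − t_o = L/v_ff) and 1 for a
cell that rolled the entire channel (t_e − t_o = L/V_inst).

Cells are classified as *rolling* (0 < V_inst below the shear-dependent
threshold), *free-flow* (at or above it), or *arrested* (no measurable
motion); cells never reaching the field of view within the acquisition are
*censored* and excluded from elution-based metrics.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig, ChannelGeometry, FlowCondition
from .synthetic import BOUND, GroundTruthTransit

__all__ = [
    "CellRecord",
    "PopulationSummary",
    "ResidenceHistogram",
    "classify_adhesion",
    "average_velocity",
    "percent_binding_time",
    "estimate_offset_time",
    "residence_distribution",
    "summarize_population",
    "records_from_tracks",
    "records_from_transits",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

ROLLING = "rolling"
FREE_FLOW = "free_flow"
ARRESTED = "arrested"
CENSORED = "censored"


@dataclass
class CellRecord:
    """Per-cell analysis result."""

    cell_id: int
    t_elution_s: float
    v_inst_median_um_s: float
    adhesion_class: str
    v_avg_um_s: float = math.nan
    pct_binding_time: float = math.nan  # clamped to [0, 1] if enabled
    pct_binding_time_raw: float = math.nan
    v_ratio: float = math.nan  # v_avg / v_inst_median


@dataclass
class ResidenceHistogram:
    """Normalized elution-time histogram (the chromatogram)."""

    bin_edges_s: np.ndarray
    density: np.ndarray  # sums to 1 over eluted cells (empty input -> empty)
    n_eluted: int
    n_censored: int

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])


@dataclass
class PopulationSummary:
    """Per-run aggregate of cell records."""

    n_total: int
    n_rolling: int
    n_free_flow: int
    n_arrested: int
    n_censored: int
    pct_rolling: float
    median_v_inst_rolling_um_s: float
    mean_pct_binding_time: float
    sem_pct_binding_time: float
    mean_v_avg_um_s: float
    sem_v_avg_um_s: float
    mean_v_ratio_rolling: float
    mean_v_ratio_free: float
    residence_histogram: ResidenceHistogram

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "n_total": self.n_total,
            "n_rolling": self.n_rolling,
            "n_free_flow": self.n_free_flow,
            "n_arrested": self.n_arrested,
            "n_censored": self.n_censored,
            "pct_rolling": self.pct_rolling,
            "median_v_inst_rolling_um_s": self.median_v_inst_rolling_um_s,
            "mean_pct_binding_time": self.mean_pct_binding_time,
            "sem_pct_binding_time": self.sem_pct_binding_time,
            "mean_v_avg_um_s": self.mean_v_avg_um_s,
            "sem_v_avg_um_s": self.sem_v_avg_um_s,
            "mean_v_ratio_rolling": self.mean_v_ratio_rolling,
            "mean_v_ratio_free": self.mean_v_ratio_free,
            "residence_histogram": {
                "bin_edges_s": self.residence_histogram.bin_edges_s.tolist(),
                "density": self.residence_histogram.density.tolist(),
                "n_eluted": self.residence_histogram.n_eluted,
                "n_censored": self.residence_histogram.n_censored,
            },
        }


def classify_adhesion(
    v_inst_median_um_s: float,
    condition: FlowCondition,
    arrest_tolerance_um_s: float = 0.0,
) -> str:
    """Classify a cell from its median instantaneous velocity.

    Rolling means slow but nonzero forward motion below the shear-dependent
    threshold (125/250/375 μm/s at 0.5/1.0/1.5 dyn/cm²); at or above the
    threshold the cell is in free flow; no measurable motion (within
    ``arrest_tolerance_um_s``, e.g. one pixel per frame) is arrested.
    """
    v = v_inst_median_um_s
    if v < 0:
        raise ValueError(f"negative instantaneous velocity: {v}")
    if v <= arrest_tolerance_um_s:
        return ARRESTED
    if v < condition.v_roll_threshold_um_s:
        return ROLLING
    return FREE_FLOW


def average_velocity(t_elution_s: float, t_offset_s: float, l_channel_um: float) -> float:
    """Whole-channel average velocity: L_channel / (t_elution − t_offset).

    Raises ``ValueError`` when t_elution ≤ t_offset (a mis-calibrated offset)
    or the channel length is not positive.
    """
    if l_channel_um <= 0:
        raise ValueError("l_channel_um must be > 0")
    dt = t_elution_s - t_offset_s
    if dt <= 0:
        raise ValueError(
            f"t_elution ({t_elution_s} s) must exceed t_offset ({t_offset_s} s); "
            "check the offset calibration"
        )
    return l_channel_um / dt


def percent_binding_time(
    v_free_flow_um_s: float,
    t_elution_s: float,
    t_offset_s: float,
    l_channel_um: float,
    v_inst_um_s: float,
    clamp: bool = True,
) -> Tuple[float, float]:
    """Mass-balance percent binding time; returns ``(value, raw)``.

    raw = [v_ff·(t_e − t_o) − L] / [(v_ff − v_inst)·(t_e − t_o)].  The raw
    value is a time fraction by derivation; measurement noise can push it
    slightly outside [0, 1], so the returned ``value`` is clamped when
    ``clamp`` is true (the raw value is always returned alongside).
    """
    if v_inst_um_s >= v_free_flow_um_s:
        raise ValueError(
            f"v_inst ({v_inst_um_s} μm/s) must be below v_free_flow "
            f"({v_free_flow_um_s} μm/s): mass balance undefined"
        )
    dt = t_elution_s - t_offset_s
    if dt <= 0:
        raise ValueError("t_elution must exceed t_offset")
    raw = (v_free_flow_um_s * dt - l_channel_um) / ((v_free_flow_um_s - v_inst_um_s) * dt)
    if raw < -1e-6:
        logger.warning(
            "percent binding time %.4g < 0: elution faster than free flow "
            "(check v_free_flow / t_offset calibration)", raw,
        )
    value = min(max(raw, 0.0), 1.0) if clamp else raw
    return value, raw


def estimate_offset_time(
    blank_elution_times_s: Sequence[float],
    v_free_flow_um_s: float,
    l_channel_um: float,
) -> Tuple[float, float]:
    """Calibrate the settling-feature offset from a blank-channel run.

    In a non-functionalized channel cells spend the whole transit in free
    flow, so t_offset = mean(t_elution) − L/v_free_flow.  Returns the
    estimate (floored at 0) and its standard error sd/√n.  Requires ≥ 10
    blank elution times.
    """
    times = np.asarray(blank_elution_times_s, dtype=float)
    if times.size == 0:
        raise ValueError("no blank elution times supplied")
    if times.size < 10:
        raise ValueError(
            f"need at least 10 blank elution times for calibration, got {times.size}"
        )
    estimate = float(np.mean(times)) - l_channel_um / v_free_flow_um_s
    se = float(np.std(times, ddof=1) / math.sqrt(times.size))
    if estimate < -se:
        logger.warning(
            "offset estimate %.3g s is negative beyond its standard error: "
            "v_free_flow may be inconsistent with the blank run", estimate,
        )
    return max(estimate, 0.0), se


def residence_distribution(
    t_elutions_s: Sequence[float],
    bin_width_s: float,
    n_censored: int = 0,
    t_max_s: Optional[float] = None,
) -> ResidenceHistogram:
    """Bin elution times into a unit-mass residence-time distribution.

    Censored cells are carried as a separate count, never binned.  An empty
    input yields an empty histogram.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be > 0")
    times = np.asarray(t_elutions_s, dtype=float)
    if times.size == 0:
        return ResidenceHistogram(np.array([0.0]), np.empty(0), 0, n_censored)
    upper = t_max_s if t_max_s is not None else times.max()
    n_bins = max(int(math.ceil(upper / bin_width_s)), 1)
    edges = np.arange(n_bins + 1) * bin_width_s
    counts, edges = np.histogram(times, bins=edges)
    return ResidenceHistogram(edges, counts / times.size, int(times.size), n_censored)


def _mean_sem(values: np.ndarray) -> Tuple[float, float]:
    if values.size == 0:
        return math.nan, math.nan
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / math.sqrt(values.size)) if values.size > 1 else math.nan
    return mean, sem


def summarize_population(
    records: Sequence[CellRecord],
    bin_width_s: float = 10.0,
) -> PopulationSummary:
    """Aggregate per-cell records into the per-run population summary.

    ``pct_rolling`` is 100·n_rolling/n_classified with censored cells
    excluded from the denominator and arrested cells included; the median
    V_inst is taken over rolling cells only; percent-binding-time and V_avg
    means carry a cell-level SEM; the V_avg/V_inst ratio is summarized
    separately for rolling and free-flow cells.
    """
    if not records:
        raise ValueError("no cell records to summarize")
    classes = np.array([r.adhesion_class for r in records])
    n_censored = int(np.sum(classes == CENSORED))
    eluted = [r for r in records if r.adhesion_class != CENSORED]
    n_classified = len(eluted)
    n_rolling = sum(r.adhesion_class == ROLLING for r in eluted)
    n_free = sum(r.adhesion_class == FREE_FLOW for r in eluted)
    n_arrested = sum(r.adhesion_class == ARRESTED for r in eluted)
    pct_rolling = 100.0 * n_rolling / n_classified if n_classified else math.nan
    v_roll = np.array(
        [r.v_inst_median_um_s for r in eluted if r.adhesion_class == ROLLING]
    )
    bt = np.array([r.pct_binding_time for r in eluted if not math.isnan(r.pct_binding_time)])
    vavg = np.array([r.v_avg_um_s for r in eluted if not math.isnan(r.v_avg_um_s)])
    mean_bt, sem_bt = _mean_sem(bt)
    mean_va, sem_va = _mean_sem(vavg)
    ratio_roll = np.array(
        [r.v_ratio for r in eluted
         if r.adhesion_class == ROLLING and not math.isnan(r.v_ratio)]
    )
    ratio_free = np.array(
        [r.v_ratio for r in eluted
         if r.adhesion_class == FREE_FLOW and not math.isnan(r.v_ratio)]
    )
    hist = residence_distribution(
        [r.t_elution_s for r in eluted], bin_width_s, n_censored=n_censored
    )
    return PopulationSummary(
        n_total=len(records),
        n_rolling=n_rolling,
        n_free_flow=n_free,
        n_arrested=n_arrested,
        n_censored=n_censored,
        pct_rolling=pct_rolling,
        median_v_inst_rolling_um_s=float(np.median(v_roll)) if v_roll.size else math.nan,
        mean_pct_binding_time=mean_bt,
        sem_pct_binding_time=sem_bt,
        mean_v_avg_um_s=mean_va,
        sem_v_avg_um_s=sem_va,
        mean_v_ratio_rolling=float(np.mean(ratio_roll)) if ratio_roll.size else math.nan,
        mean_v_ratio_free=float(np.mean(ratio_free)) if ratio_free.size else math.nan,
        residence_histogram=hist,
    )


def _build_record(
    cell_id: int,
    t_elution_s: float,
    v_inst: float,
    condition: FlowCondition,
    l_channel_um: float,
    cfg: AnalysisConfig,
) -> CellRecord:
    cls = classify_adhesion(v_inst, condition, cfg.arrest_tolerance_um_s or 0.0)
    record = CellRecord(cell_id, t_elution_s, v_inst, cls)
    try:
        record.v_avg_um_s = average_velocity(t_elution_s, cfg.t_offset_s, l_channel_um)
    except ValueError:
        logger.warning(
            "cell %s: t_elution <= t_offset, skipping elution-based metrics", cell_id
        )
        return record
    if v_inst < condition.v_free_flow_um_s:
        record.pct_binding_time, record.pct_binding_time_raw = percent_binding_time(
            condition.v_free_flow_um_s, t_elution_s, cfg.t_offset_s,
            l_channel_um, v_inst, clamp=cfg.clamp_binding_time,
        )
    if v_inst > 0:
        record.v_ratio = record.v_avg_um_s / v_inst
    return record


def records_from_tracks(
    summaries: pd.DataFrame,
    condition: FlowCondition,
    geometry: ChannelGeometry,
    cfg: AnalysisConfig,
    time_origin_s: float = 0.0,
    min_detections: int = 2,
) -> List[CellRecord]:
    """Build cell records from the tracker's per-track summary table.

    A track's elution time is the video time of its first detection plus
    ``time_origin_s`` (use this when the video does not start at pulse
    injection).  Tracks with fewer than ``min_detections`` detections carry
    no velocity and are dropped.
    """
    cfg = cfg.resolved()
    records = []
    for row in summaries.itertuples(index=False):
        if row.n_detections < min_detections or math.isnan(row.v_inst_median_um_s):
            continue
        records.append(
            _build_record(
                int(row.track_id),
                float(row.t_first_s) + time_origin_s,
                float(row.v_inst_median_um_s),
                condition,
                geometry.channel_length_um,
                cfg,
            )
        )
    return records


def _fov_median_velocity(transit: GroundTruthTransit) -> float:
    """Time-weighted median of the velocities the cell holds inside the FOV
    (what a frame-sampled median step speed converges to)."""
    ivs = transit.fov_intervals
    if not ivs:
        return transit.intervals[-1].velocity_um_s
    v = np.array([iv.velocity_um_s for iv in ivs])
    w = np.array([iv.duration_s for iv in ivs])
    order = np.argsort(v)
    cum = np.cumsum(w[order])
    return float(v[order][np.searchsorted(cum, 0.5 * cum[-1])])


def records_from_transits(
    transits: Sequence[GroundTruthTransit],
    condition: FlowCondition,
    geometry: ChannelGeometry,
    cfg: AnalysisConfig,
    use_distance_to_fov: bool = True,
    use_true_offsets: bool = False,
    v_inst_mode: str = "fov_median",
) -> List[CellRecord]:
    """Build cell records directly from simulated ground-truth transits.

    ``use_distance_to_fov`` selects the exact transit distance (inlet → FOV)
    as the channel length in the velocity and binding-time formulas, making
    the mass-balance identity exact; set it false to use the nominal full
    channel length as a tracked-data analysis would.  ``use_true_offsets``
    substitutes each cell's simulated settling dwell for the population-mean
    ``cfg.t_offset_s``.  ``v_inst_mode`` is ``"fov_median"`` (the
    time-weighted median speed inside the field of view, what the tracker
    measures) or ``"v_roll"`` (the cell's ground-truth rolling speed — the
    two-velocity reading under which the mass balance is an identity).
    """
    if v_inst_mode not in ("fov_median", "v_roll"):
        raise ValueError(f"unknown v_inst_mode {v_inst_mode!r}")
    cfg = cfg.resolved()
    length = geometry.fov_position_um if use_distance_to_fov else geometry.channel_length_um
    records = []
    for tr in transits:
        if tr.censored:
            records.append(
                CellRecord(tr.cell_id, tr.t_elution_s, math.nan, CENSORED)
            )
            continue
        v_inst = (
            tr.v_roll_um_s if v_inst_mode == "v_roll" else _fov_median_velocity(tr)
        )
        local_cfg = (
            dataclasses.replace(cfg, t_offset_s=tr.t_offset_s)
            if use_true_offsets else cfg
        )
        records.append(
            _build_record(
                tr.cell_id, tr.t_elution_s, v_inst, condition, length, local_cfg,
            )
        )
    return records


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Tabulate cell records (one row per cell)."""
    return pd.DataFrame(
        [
            (
                r.cell_id, r.t_elution_s, r.v_inst_median_um_s, r.adhesion_class,
                r.v_avg_um_s, r.pct_binding_time, r.pct_binding_time_raw, r.v_ratio,
            )
            for r in records
        ],
        columns=[
            "cell_id", "t_elution_s", "v_inst_median_um_s", "adhesion_class",
            "v_avg_um_s", "pct_binding_time", "pct_binding_time_raw", "v_ratio",
        ],
    )
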