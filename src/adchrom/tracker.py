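"""Video post-processing: background subtraction, detection and linking.

The chain mirrors the flow-chamber tracking program it reimplements:

1. a running-average background, ``acc ← (1 − α)·acc + α·frame`` with
   α = 0.0005, giving an ≈80 s moving average at 25 fps;
2. both the frame and the background are blurred with a 13 px square kernel
   and their absolute difference thresholded at 15 counts;
3. connected components larger than 5 μm in equivalent diameter become
   detections with intensity-weighted centroids;
4. detections are linked frame-to-frame by overlap (large/slow objects) or
   by gated nearest-predicted-position assignment, with a look-ahead window
   before a track is closed.

Coordinates are 0-based pixels, x along the flow axis increasing downstream;
conversions to μm use ``pixel_size_um``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .config import TrackerConfig

__all__ = [
    "BackgroundModel",
    "Detection",
    "Track",
    "update_background",
    "detect_objects",
    "link_tracks",
    "track_speeds",
    "track_stack",
    "match_tracks_to_truth",
    "tracks_to_table",
    "track_summaries",
]

logger = logging.getLogger(__name__)


class BackgroundModel:
    """Exponentially weighted running-average background.

    With weight α and frame rate f, the e-folding time constant is 1/(α·f):
    the default α = 0.0005 at 25 fps averages over ≈80 s of video.
    """

    def __init__(self, first_frame: np.ndarray, alpha: float = 0.0005):
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        self.alpha = float(alpha)
        self.accumulator = np.asarray(first_frame, dtype=np.float64).copy()
        self.n_updates = 0

    def update(self, frame: np.ndarray) -> "BackgroundModel":
        if frame.shape != self.accumulator.shape:
            raise ValueError(
                f"frame shape {frame.shape} does not match accumulator "
                f"shape {self.accumulator.shape}"
            )
        self.accumulator *= 1.0 - self.alpha
        self.accumulator += self.alpha * np.asarray(frame, dtype=np.float64)
        self.n_updates += 1
        return self


def update_background(model: BackgroundModel, frame: np.ndarray) -> BackgroundModel:
    """Fold one frame into the running average (in place; returns the model)."""
    return model.update(frame)


@dataclass(frozen=True)
class Detection:
    """One segmented object in one frame."""

    frame_index: int
    x_px: float
    y_px: float
    equivalent_diameter_um: float
    area_px: int
    bbox: Tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)

    def position_um(self, pixel_size_um: float) -> Tuple[float, float]:
        return self.x_px * pixel_size_um, self.y_px * pixel_size_um


def _blur(img: np.ndarray, kernel_px: int) -> np.ndarray:
    return ndimage.uniform_filter(
        np.asarray(img, dtype=np.float64), size=kernel_px, mode="nearest"
    )


def detect_objects(
    frame: np.ndarray, model: BackgroundModel, cfg: TrackerConfig
) -> List[Detection]:
    """Segment moving objects in one frame against the background model.

    Foreground is ``|blur(frame) − blur(background)| ≥ intensity_threshold``;
    connected components with equivalent diameter ≤ ``min_diameter_um`` are
    discarded; centroids are weighted by the difference intensity.
    Requires at least one completed background update.
    """
    if model.n_updates < 1:
        raise ValueError("background model not initialized: no updates applied yet")
    diff = np.abs(_blur(frame, cfg.blur_kernel_px) - _blur(model.accumulator, cfg.blur_kernel_px))
    mask = diff >= cfg.intensity_threshold
    labels = measure.label(mask, connectivity=2)
    detections: List[Detection] = []
    frame_index = model.n_updates  # informational; caller may override
    for region in measure.regionprops(labels, intensity_image=diff):
        diameter_um = region.equivalent_diameter_area * cfg.pixel_size_um
        if diameter_um <= cfg.min_diameter_um:
            continue
        cy, cx = region.centroid_weighted
        detections.append(
            Detection(
                frame_index=frame_index,
                x_px=float(cx),
                y_px=float(cy),
                equivalent_diameter_um=float(diameter_um),
                area_px=int(region.area),
                bbox=tuple(region.bbox),
            )
        )
    return detections


@dataclass
class Track:
    """A linked sequence of detections for one object."""

    track_id: int
    detections: List[Detection] = field(default_factory=list)

    @property
    def entry_frame(self) -> int:
        return self.detections[0].frame_index

    @property
    def exit_frame(self) -> int:
        return self.detections[-1].frame_index

    @property
    def last(self) -> Detection:
        return self.detections[-1]

    def last_velocity_um_s(self, cfg: TrackerConfig) -> Tuple[float, float]:
        """Velocity over the most recent step (μm/s); zero for new tracks."""
        if len(self.detections) < 2:
            return (0.0, 0.0)
        a, b = self.detections[-2], self.detections[-1]
        dt = (b.frame_index - a.frame_index) / cfg.frame_rate_hz
        px = cfg.pixel_size_um
        return ((b.x_px - a.x_px) * px / dt, (b.y_px - a.y_px) * px / dt)


def _bboxes_overlap(a: Tuple[int, int, int, int], b: Tuple[int, int, int, int]) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def link_tracks(
    detections_by_frame: Dict[int, List[Detection]], cfg: TrackerConfig
) -> List[Track]:
    """Link per-frame detections into tracks.

    Greedy one-to-one assignment per frame: each detection may join the
    active track whose predicted position (last position + last step velocity
    × Δt; zero velocity for single-detection tracks) is nearest, provided the
    distance is ≤ ``max_link_distance_um`` and the upstream (−x) displacement
    is ≤ ``flow_axis_bias_um``.  A detection whose bounding box overlaps a
    slow track's previous boundary is linkable regardless of the distance
    gate (the "overlapping object boundary" rule, which serves large/slow
    objects).  Ties break by smallest distance, then earliest ``track_id``.
    Unmatched detections open new tracks; tracks unmatched for more than
    ``lookahead_frames`` frames are closed.
    """
    if cfg.max_link_distance_um is None:
        raise ValueError(
            "max_link_distance_um is unset; call TrackerConfig.resolved(v_free_flow)"
        )
    px = cfg.pixel_size_um
    overlap_speed_cutoff = cfg.flow_axis_bias_um * cfg.frame_rate_hz  # ~1 diameter/frame
    active: List[Track] = []
    finished: List[Track] = []
    next_id = 0
    for frame in sorted(detections_by_frame):
        still_active = []
        for tr in active:
            if frame - tr.exit_frame > cfg.lookahead_frames:
                finished.append(tr)
            else:
                still_active.append(tr)
        active = still_active
        dets = detections_by_frame[frame]
        candidates = []  # (distance_um, track_id, det_idx, track)
        for di, det in enumerate(dets):
            for tr in active:
                dt = (frame - tr.exit_frame) / cfg.frame_rate_hz
                vx, vy = tr.last_velocity_um_s(cfg)
                pred_x = tr.last.x_px * px + vx * dt
                pred_y = tr.last.y_px * px + vy * dt
                d = math.hypot(det.x_px * px - pred_x, det.y_px * px - pred_y)
                upstream = (tr.last.x_px - det.x_px) * px
                slow = math.hypot(vx, vy) <= overlap_speed_cutoff
                overlap_ok = slow and _bboxes_overlap(det.bbox, tr.last.bbox)
                gate_ok = d <= cfg.max_link_distance_um and upstream <= cfg.flow_axis_bias_um
                if overlap_ok or gate_ok:
                    candidates.append((d, tr.track_id, di, tr))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set = set()
        used_dets: set = set()
        for d, tid, di, tr in candidates:
            if tid in used_tracks or di in used_dets:
                continue
            det = dets[di]
            tr.detections.append(
                Detection(frame, det.x_px, det.y_px, det.equivalent_diameter_um,
                          det.area_px, det.bbox)
            )
            used_tracks.add(tid)
            used_dets.add(di)
        for di, det in enumerate(dets):
            if di in used_dets:
                continue
            track = Track(next_id, [Detection(frame, det.x_px, det.y_px,
                                              det.equivalent_diameter_um,
                                              det.area_px, det.bbox)])
            next_id += 1
            active.append(track)
        active.sort(key=lambda t: t.track_id)
    finished.extend(active)
    finished.sort(key=lambda t: t.track_id)
    return finished


def track_speeds(
    track: Track, cfg: TrackerConfig
) -> Tuple[np.ndarray, Optional[float]]:
    """Per-step speeds (μm/s) and the per-track median instantaneous velocity.

    Step speed is the Euclidean displacement in μm times the frame rate
    divided by the frame gap.  Single-detection tracks carry no velocity
    information: returns an empty array and ``None``.
    """
    if len(track.detections) < 2:
        return np.empty(0), None
    px = cfg.pixel_size_um
    pts = np.array([(d.frame_index, d.x_px, d.y_px) for d in track.detections])
    gaps = np.diff(pts[:, 0])
    disp = np.hypot(np.diff(pts[:, 1]), np.diff(pts[:, 2])) * px
    speeds = disp * cfg.frame_rate_hz / gaps
    return speeds, float(np.median(speeds))


def track_stack(stack: np.ndarray, cfg: TrackerConfig) -> List[Track]:
    """Run the full chain (background → detect → link) over an image stack.

    The background initializes from the first frame; detections are
    suppressed for the first ``warmup_frames`` frames while the average
    settles.  Per-frame detection counts are logged at debug level.
    """
    cfg.validate()
    if cfg.max_link_distance_um is None:
        raise ValueError(
            "max_link_distance_um is unset; call TrackerConfig.resolved(v_free_flow)"
        )
    model = BackgroundModel(stack[0], cfg.alpha)
    detections_by_frame: Dict[int, List[Detection]] = {}
    for i in range(len(stack)):
        model.update(stack[i])
        if i < cfg.warmup_frames:
            continue
        dets = detect_objects(stack[i], model, cfg)
        dets = [
            Detection(i, d.x_px, d.y_px, d.equivalent_diameter_um, d.area_px, d.bbox)
            for d in dets
        ]
        if dets:
            detections_by_frame[i] = dets
        logger.debug("frame %d: %d detections", i, len(dets))
    return link_tracks(detections_by_frame, cfg)


def tracks_to_table(tracks: Sequence[Track], cfg: TrackerConfig) -> pd.DataFrame:
    """Long-format track table: one row per detection with its step speed.

    Columns: ``track_id, frame, t_s, x_um, y_um, step_speed_um_s`` (speed of
    the step *into* each row; NaN for a track's first row).
    """
    rows = []
    for tr in tracks:
        speeds, _ = track_speeds(tr, cfg)
        for k, det in enumerate(tr.detections):
            rows.append(
                (
                    tr.track_id,
                    det.frame_index,
                    det.frame_index / cfg.frame_rate_hz,
                    det.x_px * cfg.pixel_size_um,
                    det.y_px * cfg.pixel_size_um,
                    float(speeds[k - 1]) if k >= 1 else np.nan,
                )
            )
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "t_s", "x_um", "y_um", "step_speed_um_s"]
    )


def match_tracks_to_truth(
    track_table: pd.DataFrame,
    truth_table: pd.DataFrame,
    max_distance_um: float = 20.0,
) -> pd.DataFrame:
    """Greedily match recovered tracks to ground-truth cells for validation.

    Both tables are long-format (``frame, x_um, y_um`` plus ``track_id`` /
    ``cell_id``).  For every (track, cell) pair sharing frames, the mean
    Euclidean distance over common frames is computed; pairs are accepted in
    ascending-distance order, one-to-one, while the mean distance is at most
    ``max_distance_um``.  Returns columns ``cell_id, track_id,
    mean_distance_um, n_common_frames``.
    """
    merged = truth_table.merge(
        track_table, on="frame", suffixes=("_true", "_trk")
    )
    if len(merged) == 0:
        return pd.DataFrame(
            columns=["cell_id", "track_id", "mean_distance_um", "n_common_frames"]
        )
    merged["dist"] = np.hypot(
        merged["x_um_true"] - merged["x_um_trk"],
        merged["y_um_true"] - merged["y_um_trk"],
    )
    pair = (
        merged.groupby(["cell_id", "track_id"])["dist"]
        .agg(["mean", "count"])
        .reset_index()
        .sort_values(["mean", "cell_id", "track_id"])
    )
    used_cells: set = set()
    used_tracks: set = set()
    rows = []
    for row in pair.itertuples(index=False):
        if row.mean > max_distance_um:
            break
        if row.cell_id in used_cells or row.track_id in used_tracks:
            continue
        rows.append((row.cell_id, row.track_id, row.mean, row.count))
        used_cells.add(row.cell_id)
        used_tracks.add(row.track_id)
    return pd.DataFrame(
        rows, columns=["cell_id", "track_id", "mean_distance_um", "n_common_frames"]
    )


def track_summaries(tracks: Sequence[Track], cfg: TrackerConfig) -> pd.DataFrame:
    """Per-track summary: entry/exit frames, first-seen time and median V_inst.

    ``v_inst_median_um_s`` is NaN for single-detection tracks (flagged via
    ``n_detections == 1``).
    """
    rows = []
    for tr in tracks:
        _, v_med = track_speeds(tr, cfg)
        rows.append(
            (
                tr.track_id,
                len(tr.detections),
                tr.entry_frame,
                tr.exit_frame,
                tr.entry_frame / cfg.frame_rate_hz,
                np.nan if v_med is None else v_med,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "n_detections",
            "entry_frame",
            "exit_frame",
            "t_first_s",
            "v_inst_median_um_s",
        ],
    )
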