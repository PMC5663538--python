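"""Ground-truth transit simulation and synthetic video rendering.

A pulse of cells enters the functionalized channel after a random dwell in the
upstream settling feature.  Each cell is an independent continuous-time
two-state Markov chain: in the *bound* state it rolls at its per-cell rolling
speed; in the *free* state it advects at the shear-dependent free-flow
velocity.  Exponential holding times with rates ``k_off`` (bound→free) and
``k_on`` (free→bound) govern switching.  The chain is advanced until the cell
reaches the imaging field of view (FOV); the time of arrival is the elution
time and the time-weighted bound fraction over the transit is the ground-truth
percent binding time.  Motion is simulated onward through the FOV so the cell
can be rendered and tracked.

Rendering draws each cell as a Gaussian spot on a uniform background with
additive Gaussian read noise, quantized to 8-bit — enough structure to
exercise the tracker's running-average background model, blur/threshold
segmentation and linker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .config import (
    ChannelGeometry,
    FlowCondition,
    RenderConfig,
    SimulationParams,
)

__all__ = [
    "Interval",
    "GroundTruthTransit",
    "simulate_transits",
    "fov_positions",
    "assign_lanes",
    "transits_to_frame_table",
    "render_video",
    "write_tiff",
]

BOUND = "bound"
FREE = "free"

_MAX_VROLL_REDRAWS = 100


@dataclass(frozen=True)
class Interval:
    """One constant-velocity leg of a transit."""

    state: str  # "bound" | "free"
    duration_s: float
    velocity_um_s: float


@dataclass
class GroundTruthTransit:
    """A simulated cell's path from channel inlet to the field of view.

    ``intervals`` covers inlet → FOV start and satisfies distance
    conservation (Σ duration·velocity = fov_position).  ``fov_intervals``
    continues the same chain through the FOV for rendering; it does not enter
    the elution time or binding fraction.  ``censored`` marks cells whose
    elution time exceeds the acquisition window.
    """

    cell_id: int
    intervals: List[Interval]
    fov_intervals: List[Interval]
    t_offset_s: float
    t_elution_s: float
    true_binding_fraction: float
    v_roll_um_s: float
    censored: bool = False

    @property
    def transit_time_s(self) -> float:
        return sum(iv.duration_s for iv in self.intervals)


def _lognormal_from_mean_cv(
    rng: np.random.Generator, mean: float, cv: float, size=None
):
    """Sample lognormal values with the given arithmetic mean and CV
    (degenerate to the constant ``mean`` when cv == 0)."""
    if cv == 0:
        return np.full(size, mean) if size is not None else mean
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def _draw_v_roll(
    rng: np.random.Generator, params: SimulationParams, v_free_flow: float
) -> float:
    for _ in range(_MAX_VROLL_REDRAWS):
        v = float(_lognormal_from_mean_cv(rng, params.v_roll_mean_um_s, params.v_roll_cv))
        if v < v_free_flow:
            return v
    raise ValueError(
        "could not draw a rolling speed below v_free_flow after "
        f"{_MAX_VROLL_REDRAWS} attempts; check v_roll_mean_um_s / v_roll_cv"
    )


def _advance(
    rng: np.random.Generator,
    start_state: str,
    distance_um: float,
    v_roll: float,
    v_free: float,
    k_on: float,
    k_off: float,
) -> Tuple[List[Interval], str]:
    """Run the two-state chain over a fixed distance; return the interval
    list and the state in force when the distance is reached."""
    intervals: List[Interval] = []
    state = start_state
    x = 0.0
    while x < distance_um - 1e-12:
        rate = k_off if state == BOUND else k_on
        v = v_roll if state == BOUND else v_free
        if v <= 0:
            raise ValueError("zero velocity with no escape: cell would never elute")
        dwell = math.inf if rate == 0 else rng.exponential(1.0 / rate)
        remaining = distance_um - x
        if v * dwell >= remaining or math.isinf(dwell):
            dwell = remaining / v
            intervals.append(Interval(state, dwell, v))
            x = distance_um
            break
        intervals.append(Interval(state, dwell, v))
        x += v * dwell
        state = FREE if state == BOUND else BOUND
    return intervals, state


def simulate_transits(
    params: SimulationParams,
    condition: FlowCondition,
    geometry: ChannelGeometry,
    acquisition_duration_s: float = 7_200.0,
) -> List[GroundTruthTransit]:
    """Simulate ``params.n_cells`` independent cell transits to the FOV.

    Returns one :class:`GroundTruthTransit` per cell, reproducible for a
    fixed ``params.seed``.  Cells eluting after ``acquisition_duration_s``
    are flagged censored (they would not be observed in the video).

    Raises
    ------
    ValueError
        If the FOV distance is zero, or a cell's rolling-speed draw cannot be
        placed below the free-flow velocity within a bounded number of
        redraws.
    """
    params.validate(condition)
    geometry.validate()
    if geometry.fov_position_um <= 0:
        raise ValueError("fov_position_um must be > 0: zero transit distance")
    rng = np.random.default_rng(params.seed)
    v_free = condition.v_free_flow_um_s
    fov_end = min(
        geometry.fov_position_um + geometry.fov_length_um, geometry.channel_length_um
    )
    transits: List[GroundTruthTransit] = []
    for cell_id in range(params.n_cells):
        v_roll = _draw_v_roll(rng, params, v_free)
        t_offset = float(
            _lognormal_from_mean_cv(rng, params.t_offset_mean_s, params.t_offset_cv)
        ) if params.t_offset_mean_s > 0 else 0.0
        start_state = BOUND if rng.random() < params.p_start_bound else FREE
        intervals, state_at_fov = _advance(
            rng, start_state, geometry.fov_position_um, v_roll, v_free,
            params.k_on_per_s, params.k_off_per_s,
        )
        fov_intervals, _ = _advance(
            rng, state_at_fov, fov_end - geometry.fov_position_um, v_roll, v_free,
            params.k_on_per_s, params.k_off_per_s,
        )
        t_transit = sum(iv.duration_s for iv in intervals)
        t_bound = sum(iv.duration_s for iv in intervals if iv.state == BOUND)
        t_elution = t_offset + t_transit
        transits.append(
            GroundTruthTransit(
                cell_id=cell_id,
                intervals=intervals,
                fov_intervals=fov_intervals,
                t_offset_s=t_offset,
                t_elution_s=t_elution,
                true_binding_fraction=t_bound / t_transit,
                v_roll_um_s=v_roll,
                censored=t_elution > acquisition_duration_s,
            )
        )
    return transits


def fov_positions(
    transit: GroundTruthTransit,
    geometry: ChannelGeometry,
    frame_rate_hz: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample the cell's along-flow position at frame cadence while in the FOV.

    Returns ``(t_s, x_um, state)`` arrays: times starting at the elution time
    and advancing by one frame interval, positions measured from the FOV's
    upstream edge (0 ≤ x < fov_length), and the state ("bound"/"free") in
    force at each sample.  A cell whose FOV dwell is shorter than one frame
    interval yields a single sample (at entry).
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    ivs = transit.fov_intervals
    if not ivs:
        return (np.empty(0), np.empty(0), np.empty(0, dtype=object))
    # Piecewise-linear position vs time through the FOV.
    t_knots = np.concatenate([[0.0], np.cumsum([iv.duration_s for iv in ivs])])
    x_knots = np.concatenate(
        [[0.0], np.cumsum([iv.duration_s * iv.velocity_um_s for iv in ivs])]
    )
    total = t_knots[-1]
    dt = 1.0 / frame_rate_hz
    n = int(math.floor(total / dt)) + 1
    t_rel = np.arange(n) * dt
    x = np.interp(t_rel, t_knots, x_knots)
    idx = np.clip(np.searchsorted(t_knots, t_rel, side="right") - 1, 0, len(ivs) - 1)
    states = np.array([ivs[i].state for i in idx], dtype=object)
    inside = x < geometry.fov_length_um + 1e-9
    return (transit.t_elution_s + t_rel[inside], x[inside], states[inside])


def assign_lanes(
    n_cells: int,
    cfg: RenderConfig,
    seed: Optional[int] = None,
    spacing: str = "uniform",
) -> np.ndarray:
    """Assign each cell a transverse (y) position in μm within the image.

    ``spacing="uniform"`` draws positions uniformly at random between margins
    (the default, emulating cells distributed across the channel width);
    ``"even"`` spreads cells on evenly spaced lanes with small jitter, which
    guarantees simultaneous cells stay separated — useful for tracking
    benchmarks.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    height_um = cfg.image_height_px * cfg.pixel_size_um
    margin = max(2.0 * cfg.cell_diameter_um, 4.0 * cfg.psf_sigma_px * cfg.pixel_size_um)
    lo, hi = margin, height_um - margin
    if hi <= lo:
        raise ValueError("image too small for the cell size margins")
    if spacing == "uniform":
        return rng.uniform(lo, hi, size=n_cells)
    if spacing == "even":
        lanes = np.linspace(lo, hi, n_cells)
        gap = (hi - lo) / max(n_cells - 1, 1)
        return lanes + rng.uniform(-0.1, 0.1, size=n_cells) * gap
    raise ValueError(f"unknown spacing {spacing!r}")


def transits_to_frame_table(
    transits: Sequence[GroundTruthTransit],
    geometry: ChannelGeometry,
    cfg: RenderConfig,
    y_um: Optional[np.ndarray] = None,
    lane_spacing: str = "uniform",
    time_origin_s: Optional[float] = None,
    lead_time_s: float = 2.0,
) -> pd.DataFrame:
    """Build the per-frame ground-truth position table for rendering.

    Columns: ``cell_id, frame, t_s, x_um, y_um, state`` with ``x_um``
    measured from the FOV's upstream edge and ``frame`` the global video
    frame index.  Frame 0 sits at ``time_origin_s``; by default that is
    ``lead_time_s`` before the earliest elution, so short test videos skip
    the dead time before any cell arrives yet still open with empty frames
    (as a real acquisition does, letting the tracker's background model warm
    up).  Censored transits are skipped.
    """
    live = [tr for tr in transits if not tr.censored]
    if y_um is None:
        y_um = assign_lanes(len(live), cfg, spacing=lane_spacing)
    rows = []
    samples = [fov_positions(tr, geometry, cfg.frame_rate_hz) for tr in live]
    if time_origin_s is None:
        time_origin_s = max(
            min((t[0] for t, _, _ in samples if len(t)), default=0.0)
            - lead_time_s,
            0.0,
        )
    for (t, x, states), tr, y in zip(samples, live, y_um):
        for ti, xi, si in zip(t, x, states):
            if ti < time_origin_s:
                continue
            rows.append(
                (
                    tr.cell_id,
                    int(round((ti - time_origin_s) * cfg.frame_rate_hz)),
                    ti,
                    xi,
                    float(y),
                    si,
                )
            )
    table = pd.DataFrame(
        rows, columns=["cell_id", "frame", "t_s", "x_um", "y_um", "state"]
    )
    return table.sort_values(["frame", "cell_id"], ignore_index=True)


def _add_spot(
    canvas: np.ndarray, x_px: float, y_px: float, amplitude: float, sigma: float
) -> None:
    """Add a Gaussian spot in-place, evaluated on a ±4σ window."""
    h, w = canvas.shape
    r = int(math.ceil(4.0 * sigma))
    x0, x1 = int(math.floor(x_px)) - r, int(math.floor(x_px)) + r + 1
    y0, y1 = int(math.floor(y_px)) - r, int(math.floor(y_px)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c) - x_px
    ys = np.arange(y0c, y1c) - y_px
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma * sigma))
    canvas[y0c:y1c, x0c:x1c] += amplitude * g


def render_video(
    frame_table: pd.DataFrame,
    cfg: RenderConfig,
    n_frames: Optional[int] = None,
) -> np.ndarray:
    """Render the per-frame position table as an 8-bit grayscale image stack.

    Each frame is ``background_level`` plus one Gaussian spot per in-view
    cell (amplitude ``cell_amplitude``, width ``psf_sigma_px``) plus additive
    Gaussian read noise, clipped to [0, 255].  Identical inputs and seed give
    a bit-identical stack.
    """
    cfg.validate()
    if cfg.pixel_size_um <= 0:  # defensive; validate() already enforces this
        raise ValueError("pixel_size_um must be > 0")
    if n_frames is None:
        n_frames = int(frame_table["frame"].max()) + 1 if len(frame_table) else 1
    h, w = cfg.image_height_px, cfg.image_width_px
    rng = np.random.default_rng(cfg.seed)
    stack = np.empty((n_frames, h, w), dtype=np.uint8)
    by_frame = dict(tuple(frame_table.groupby("frame"))) if len(frame_table) else {}
    for i in range(n_frames):
        canvas = np.full((h, w), float(cfg.background_level))
        group = by_frame.get(i)
        if group is not None:
            for x_um, y_um in zip(group["x_um"], group["y_um"]):
                _add_spot(
                    canvas,
                    x_um / cfg.pixel_size_um,
                    y_um / cfg.pixel_size_um,
                    cfg.cell_amplitude,
                    cfg.psf_sigma_px,
                )
        if cfg.noise_sigma > 0:
            canvas += rng.normal(0.0, cfg.noise_sigma, size=(h, w))
        stack[i] = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return stack


def write_tiff(stack: np.ndarray, path: str | Path) -> None:
    """Write an image stack as a multi-page 8-bit grayscale TIFF."""
    tifffile.imwrite(str(path), stack, photometric="minisblack")
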