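"""Typed run configuration for the adhesion chromatography pipeline.

All distances are micrometres, times seconds, velocities μm/s, wall shear
stress dyn/cm² and image intensities 8-bit counts unless a field name says
otherwise.  Each section is a plain dataclass with a ``validate`` method that
raises :class:`ConfigError` naming the offending field; ``load_config`` /
``save_config`` round-trip the whole bundle through YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "ConfigError",
    "ChannelGeometry",
    "FlowCondition",
    "SimulationParams",
    "RenderConfig",
    "TrackerConfig",
    "AnalysisConfig",
    "RunConfig",
    "rolling_threshold_for_shear",
    "free_flow_velocity_for_shear",
    "load_config",
    "save_config",
    "DEFAULT_PULSE_CELL_COUNT",
    "SHORT_CHANNEL_UM",
    "LONG_CHANNEL_UM",
]


class ConfigError(ValueError):
    """A configuration field violates its invariant."""


# Channel-length presets: the device comes in 1.3 cm and 14 cm variants.
SHORT_CHANNEL_UM = 13_000.0
LONG_CHANNEL_UM = 140_000.0

# A 50 μL pulse of 5×10^5 cells/mL = 2.5×10^4 cells.
DEFAULT_PULSE_VOLUME_UL = 50.0
DEFAULT_PULSE_CONC_CELLS_PER_ML = 5.0e5
DEFAULT_PULSE_CELL_COUNT = int(
    round(DEFAULT_PULSE_VOLUME_UL * 1e-3 * DEFAULT_PULSE_CONC_CELLS_PER_ML)
)

# Printed calibration: free-flow cell velocity and the rolling-classification
# threshold at each wall shear stress (dyn/cm² -> μm/s).
FREE_FLOW_TABLE = {0.5: 529.0, 1.0: 1059.0, 1.5: 1588.0}
ROLLING_THRESHOLD_TABLE = {0.5: 125.0, 1.0: 250.0, 1.5: 375.0}
# Linear extension of the threshold rule: 250 μm/s per dyn/cm².
ROLLING_THRESHOLD_SLOPE = 250.0


def rolling_threshold_for_shear(tau_wall: float) -> float:
    """Rolling-velocity threshold (μm/s) for a wall shear stress (dyn/cm²).

    The printed pairs (0.5, 125), (1.0, 250), (1.5, 375) are exact; any other
    positive shear uses the linear rule τ·250 μm/s per dyn/cm².
    """
    if tau_wall <= 0:
        raise ConfigError(f"tau_wall must be > 0, got {tau_wall}")
    if tau_wall in ROLLING_THRESHOLD_TABLE:
        return ROLLING_THRESHOLD_TABLE[tau_wall]
    return ROLLING_THRESHOLD_SLOPE * tau_wall


def free_flow_velocity_for_shear(tau_wall: float) -> float:
    """Approximate free-flow cell velocity (μm/s) at a wall shear stress.

    The printed triples 529/1059/1588 μm/s at 0.5/1.0/1.5 dyn/cm² are exact
    table entries (they are not exactly proportional to τ); other shears use
    piecewise-linear interpolation between, or extrapolation beyond, the
    printed points.
    """
    if tau_wall <= 0:
        raise ConfigError(f"tau_wall must be > 0, got {tau_wall}")
    if tau_wall in FREE_FLOW_TABLE:
        return FREE_FLOW_TABLE[tau_wall]
    taus = sorted(FREE_FLOW_TABLE)
    vs = [FREE_FLOW_TABLE[t] for t in taus]
    if tau_wall <= taus[0]:
        lo, hi = 0, 1
    elif tau_wall >= taus[-1]:
        lo, hi = len(taus) - 2, len(taus) - 1
    else:
        hi = next(i for i, t in enumerate(taus) if t >= tau_wall)
        lo = hi - 1
    slope = (vs[hi] - vs[lo]) / (taus[hi] - taus[lo])
    return vs[lo] + slope * (tau_wall - taus[lo])


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class ChannelGeometry:
    """Microchannel geometry.

    The device is a 2 mm wide, 100 μm deep channel of 1.3 or 14 cm, fed
    through a circular settling feature (inner/outer radii 10.5/11.75 mm)
    that lets cells contact the substrate before the functionalized channel.
    The imaging field of view (FOV) sits at the channel end by default.
    """

    channel_length_um: float = SHORT_CHANNEL_UM
    channel_width_um: float = 2_000.0
    channel_depth_um: float = 100.0
    settling_inner_radius_um: float = 10_500.0
    settling_outer_radius_um: float = 11_750.0
    fov_length_um: float = 650.0  # 500 px × 1.3 μm/px along the flow axis
    fov_position_um: Optional[float] = None  # distance of FOV start from inlet

    def __post_init__(self) -> None:
        if self.fov_position_um is None:
            self.fov_position_um = self.channel_length_um - self.fov_length_um
        self.validate()

    def validate(self) -> None:
        for name in (
            "channel_length_um",
            "channel_width_um",
            "channel_depth_um",
            "settling_inner_radius_um",
            "settling_outer_radius_um",
            "fov_length_um",
        ):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.fov_position_um >= 0, "fov_position_um must be >= 0")
        _require(
            self.fov_position_um + self.fov_length_um <= self.channel_length_um + 1e-9,
            "fov_position_um + fov_length_um must not exceed channel_length_um",
        )


@dataclass
class FlowCondition:
    """Wall shear stress with its derived velocities plus substrate metadata.

    ``v_free_flow_um_s`` and ``v_roll_threshold_um_s`` default to the
    shear-stress rules when left ``None``.
    """

    tau_wall_dyn_cm2: float = 1.0
    v_free_flow_um_s: Optional[float] = None
    v_roll_threshold_um_s: Optional[float] = None
    selectin: str = "P"  # one of P | E | L | none
    selectin_conc_ug_ml: float = 25.0
    heparin_dose_u_ml: float = 0.0

    def __post_init__(self) -> None:
        if self.v_free_flow_um_s is None:
            self.v_free_flow_um_s = free_flow_velocity_for_shear(self.tau_wall_dyn_cm2)
        if self.v_roll_threshold_um_s is None:
            self.v_roll_threshold_um_s = rolling_threshold_for_shear(
                self.tau_wall_dyn_cm2
            )
        self.validate()

    def validate(self) -> None:
        _require(self.tau_wall_dyn_cm2 > 0, "tau_wall_dyn_cm2 must be > 0")
        _require(
            0 < self.v_roll_threshold_um_s < self.v_free_flow_um_s,
            "require 0 < v_roll_threshold_um_s < v_free_flow_um_s",
        )
        _require(
            self.selectin in ("P", "E", "L", "none"),
            "selectin must be one of P, E, L, none",
        )
        _require(self.selectin_conc_ug_ml >= 0, "selectin_conc_ug_ml must be >= 0")
        _require(self.heparin_dose_u_ml >= 0, "heparin_dose_u_ml must be >= 0")


@dataclass
class SimulationParams:
    """Two-state transit-model parameters.

    Cells alternate between a bound (rolling) state and free flow as a
    continuous-time Markov chain: ``k_on`` is the free→bound capture rate and
    ``k_off`` the bound→free release rate.  Each cell draws one rolling speed
    (lognormal, mean ``v_roll_mean_um_s``, coefficient of variation
    ``v_roll_cv``) and one settling-feature dwell (``t_offset``).
    """

    n_cells: int = DEFAULT_PULSE_CELL_COUNT
    k_on_per_s: float = 0.2
    k_off_per_s: float = 0.1
    v_roll_mean_um_s: float = 60.0
    v_roll_cv: float = 0.5
    p_start_bound: float = 0.5
    t_offset_mean_s: float = 30.0
    t_offset_cv: float = 0.2
    seed: int = 0

    def validate(self, condition: Optional[FlowCondition] = None) -> None:
        _require(self.n_cells >= 1, "n_cells must be >= 1")
        _require(self.k_on_per_s >= 0, "k_on_per_s must be >= 0")
        _require(self.k_off_per_s >= 0, "k_off_per_s must be >= 0")
        _require(self.v_roll_mean_um_s > 0, "v_roll_mean_um_s must be > 0")
        _require(self.v_roll_cv >= 0, "v_roll_cv must be >= 0")
        _require(0 <= self.p_start_bound <= 1, "p_start_bound must be in [0, 1]")
        _require(self.t_offset_mean_s >= 0, "t_offset_mean_s must be >= 0")
        _require(self.t_offset_cv >= 0, "t_offset_cv must be >= 0")
        if condition is not None:
            _require(
                self.v_roll_mean_um_s < condition.v_free_flow_um_s,
                "v_roll_mean_um_s must be below the condition's v_free_flow_um_s",
            )


@dataclass
class RenderConfig:
    """Synthetic video rendering settings, matching the acquisition described
    for the experiment: 25 fps, 500×376 px, 10× objective with 2×2 binning
    (pixel size is never printed; 1.3 μm/px is a plausible default and fully
    configurable)."""

    pixel_size_um: float = 1.3
    image_width_px: int = 500
    image_height_px: int = 376
    frame_rate_hz: float = 25.0
    cell_diameter_um: float = 12.0
    psf_sigma_px: float = 4.0
    background_level: float = 20.0
    cell_amplitude: float = 90.0
    noise_sigma: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.pixel_size_um > 0, "pixel_size_um must be > 0")
        _require(self.frame_rate_hz > 0, "frame_rate_hz must be > 0")
        _require(self.image_width_px > 0, "image_width_px must be > 0")
        _require(self.image_height_px > 0, "image_height_px must be > 0")
        _require(
            0 <= self.background_level <= 255, "background_level must be in [0, 255]"
        )
        _require(0 <= self.cell_amplitude <= 255, "cell_amplitude must be in [0, 255]")
        _require(self.noise_sigma >= 0, "noise_sigma must be >= 0")
        _require(self.psf_sigma_px > 0, "psf_sigma_px must be > 0")
        _require(self.cell_diameter_um > 0, "cell_diameter_um must be > 0")


@dataclass
class TrackerConfig:
    """Video post-processing parameters.

    Defaults follow the described processing chain: running-average background
    with weight 0.0005 (an ~80 s moving average at 25 fps), a 13 px blur, an
    absolute difference threshold of 15 counts, and a 5 μm minimum contour
    diameter.  ``max_link_distance_um`` defaults to 1.2× the expected
    free-flow displacement per frame so free-flowing cells remain linkable.
    """

    alpha: float = 0.0005
    blur_kernel_px: int = 13
    intensity_threshold: float = 15.0
    min_diameter_um: float = 5.0
    pixel_size_um: float = 1.3
    frame_rate_hz: float = 25.0
    lookahead_frames: int = 3
    max_link_distance_um: Optional[float] = None
    flow_axis_bias_um: float = 12.0  # allowed upstream displacement, one cell diameter
    warmup_frames: int = 25

    def resolved(self, v_free_flow_um_s: float) -> "TrackerConfig":
        """Return a copy with ``max_link_distance_um`` filled from the
        free-flow velocity if unset."""
        cfg = dataclasses.replace(self)
        if cfg.max_link_distance_um is None:
            cfg.max_link_distance_um = 1.2 * v_free_flow_um_s / cfg.frame_rate_hz
        cfg.validate()
        return cfg

    def validate(self) -> None:
        _require(0 < self.alpha <= 1, "alpha must be in (0, 1]")
        _require(
            self.blur_kernel_px >= 1 and self.blur_kernel_px % 2 == 1,
            "blur_kernel_px must be odd and >= 1",
        )
        _require(self.intensity_threshold > 0, "intensity_threshold must be > 0")
        _require(self.min_diameter_um > 0, "min_diameter_um must be > 0")
        _require(self.pixel_size_um > 0, "pixel_size_um must be > 0")
        _require(self.frame_rate_hz > 0, "frame_rate_hz must be > 0")
        _require(self.lookahead_frames >= 1, "lookahead_frames must be >= 1")
        if self.max_link_distance_um is not None:
            _require(self.max_link_distance_um > 0, "max_link_distance_um must be > 0")
        _require(self.flow_axis_bias_um >= 0, "flow_axis_bias_um must be >= 0")
        _require(self.warmup_frames >= 0, "warmup_frames must be >= 0")

    @property
    def background_time_constant_s(self) -> float:
        """e-folding time of the running-average background, 1/(α·frame rate)."""
        return 1.0 / (self.alpha * self.frame_rate_hz)


@dataclass
class AnalysisConfig:
    """Chromatography analysis settings.

    ``t_offset_s`` is the population-mean settling-feature dwell subtracted
    from elution times; calibrate it from a blank (non-functionalized) run
    with :func:`adchrom.chromatography.estimate_offset_time`.
    ``arrest_tolerance_um_s`` is the zero-motion tolerance below which a cell
    counts as arrested rather than rolling (default: one pixel per frame).
    """

    t_offset_s: float = 0.0
    acquisition_duration_s: float = 7_200.0
    clamp_binding_time: bool = True
    arrest_tolerance_um_s: Optional[float] = None
    residence_bin_width_s: float = 10.0

    def resolved(self, pixel_size_um: float = 1.3, frame_rate_hz: float = 25.0
                 ) -> "AnalysisConfig":
        cfg = dataclasses.replace(self)
        if cfg.arrest_tolerance_um_s is None:
            cfg.arrest_tolerance_um_s = pixel_size_um * frame_rate_hz
        cfg.validate()
        return cfg

    def validate(self) -> None:
        _require(self.t_offset_s >= 0, "t_offset_s must be >= 0")
        _require(self.acquisition_duration_s > 0, "acquisition_duration_s must be > 0")
        if self.arrest_tolerance_um_s is not None:
            _require(
                self.arrest_tolerance_um_s >= 0, "arrest_tolerance_um_s must be >= 0"
            )
        _require(self.residence_bin_width_s > 0, "residence_bin_width_s must be > 0")


@dataclass
class RunConfig:
    """Bundle of every configuration section for one pipeline run."""

    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    condition: FlowCondition = field(default_factory=FlowCondition)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    render: RenderConfig = field(default_factory=RenderConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self) -> None:
        self.geometry.validate()
        self.condition.validate()
        self.simulation.validate(self.condition)
        self.render.validate()
        self.tracker.validate()
        self.analysis.validate()

    def to_dict(self) -> dict:
        return {
            name: dataclasses.asdict(getattr(self, name))
            for name in ("geometry", "condition", "simulation", "render",
                         "tracker", "analysis")
        }


_SECTION_TYPES = {
    "geometry": ChannelGeometry,
    "condition": FlowCondition,
    "simulation": SimulationParams,
    "render": RenderConfig,
    "tracker": TrackerConfig,
    "analysis": AnalysisConfig,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown field(s) {sorted(unknown)} in config section '{section}'"
        )
    try:
        return cls(**data)
    except ConfigError as exc:
        raise ConfigError(f"section '{section}': {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Missing sections and fields take their documented defaults (e.g. a bare
    ``condition: {tau_wall_dyn_cm2: 1.0}`` fills v_free_flow = 1059 μm/s and
    the 250 μm/s rolling threshold).  Invariant violations raise
    :class:`ConfigError` naming the field.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - set(_SECTION_TYPES)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    sections = {
        name: _build_section(cls, data.get(name, {}) or {}, name)
        for name, cls in _SECTION_TYPES.items()
    }
    cfg = RunConfig(**sections)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a RunConfig as YAML or JSON (by extension); round-trips with
    :func:`load_config`."""
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
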