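import numpy as np
import pytest

from adchrom import (
    AnalysisConfig,
    ChannelGeometry,
    FlowCondition,
    RenderConfig,
    SimulationParams,
    TrackerConfig,
)


@pytest.fixture
def geometry():
    """Default short (1.3 cm) channel with the FOV at the channel end."""
    return ChannelGeometry()


@pytest.fixture
def condition():
    """1.0 dyn/cm² on P-selectin: v_free = 1059 μm/s, threshold 250 μm/s."""
    return FlowCondition(tau_wall_dyn_cm2=1.0)


@pytest.fixture
def render_cfg():
    return RenderConfig(seed=11)


@pytest.fixture
def tracker_cfg(condition):
    return TrackerConfig().resolved(condition.v_free_flow_um_s)


@pytest.fixture
def analysis_cfg():
    return AnalysisConfig().resolved()


@pytest.fixture
def rendered_five_cell_run(geometry, condition, render_cfg):
    """Small rendered stack with ground truth for round-trip tests."""
    from adchrom import simulate_transits, render_video, transits_to_frame_table

    params = SimulationParams(
        n_cells=5, seed=21, t_offset_mean_s=5.0, t_offset_cv=0.5
    )
    transits = simulate_transits(params, condition, geometry)
    table = transits_to_frame_table(
        transits, geometry, render_cfg, lane_spacing="even"
    )
    stack = render_video(table, render_cfg)
    return transits, table, stack
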