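import numpy as np
import pytest

import colomap as cm
from colomap.phantom import Breathing


def make_config(**overrides) -> cm.PhantomConfig:
    """Small, fast phantom session used across the suite."""
    kw = dict(
        duration_s=300.0,
        frame_interval_s=1.0,
        pixel_spacing_mm=1.5,
        image_shape=(80, 300),
        baseline_diameter_mm=20.0,
        occlusion_floor_mm=1.0,
        seed=7,
    )
    kw.update(overrides)
    return cm.PhantomConfig(**kw)


def make_corridor(config: cm.PhantomConfig, wall_offset_mm: float = 13.0,
                  margin_mm: float = 10.0) -> cm.WallCorridor:
    return cm.phantom.wall_corridor(config, offset_mm=wall_offset_mm, margin_mm=margin_mm)


@pytest.fixture(scope="session")
def single_wave_config() -> cm.PhantomConfig:
    return make_config(
        hapc_events=[cm.WaveSpec(onset_time_s=60.0, origin_mm=0.0, velocity_mm_s=10.0,
                                 amplitude_fraction=0.8, half_width_mm=20.0)],
    )


@pytest.fixture(scope="session")
def single_wave_truth(single_wave_config) -> cm.PhantomGroundTruth:
    return cm.simulate_diameter_field(single_wave_config)


@pytest.fixture(scope="session")
def single_wave_frames(single_wave_config, single_wave_truth) -> cm.ImageSeries:
    return cm.render_frames(single_wave_truth, single_wave_config)


@pytest.fixture(scope="session")
def single_wave_diameters(single_wave_config, single_wave_frames) -> cm.DiameterProfileSeries:
    curve = cm.MidlineCurve(points_mm=single_wave_config.midline_points_mm)
    corridor = make_corridor(single_wave_config)
    return cm.measure_diameters(single_wave_frames, curve, corridor, spacing_mm=2.0)


@pytest.fixture(scope="session")
def single_wave_rmap(single_wave_diameters) -> cm.ResidualMap:
    return cm.residual_map(single_wave_diameters)


@pytest.fixture(scope="session")
def noisy_breathing_config() -> cm.PhantomConfig:
    return make_config(
        hapc_events=[cm.WaveSpec(onset_time_s=60.0, origin_mm=0.0, velocity_mm_s=10.0,
                                 amplitude_fraction=0.8, half_width_mm=20.0)],
        breathing=Breathing(amplitude_mm=3.0, period_s=4.0),
        noise_sd=0.05,
    )
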