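import numpy as np
import pytest

import gaitstab as g


@pytest.fixture(scope="session")
def truth300():
    """Default-parameter step table, 300 strides, seed 42."""
    return g.simulate_step_table(g.SyntheticGaitConfig(n_strides=300, seed=42))


@pytest.fixture(scope="session")
def gait60():
    """Rendered default gait (60 strides, seed 7) with detected events."""
    cfg = g.SyntheticGaitConfig(n_strides=60, seed=7)
    truth = g.simulate_step_table(cfg)
    ts = g.render_continuous(truth, cfg)
    events = g.compute_sampling_instants(g.detect_heelstrikes(ts))
    return cfg, truth, ts, events


@pytest.fixture(scope="session")
def noise_free_cfg():
    """Deterministic gait: no stride-time, CoM or placement variability."""
    return g.SyntheticGaitConfig(
        n_strides=45, seed=0, stride_time_sd=0.0, com_sway_sd=0.0,
        com_vel_sd=0.0, sigma_eps=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_gait(noise_free_cfg):
    truth = g.simulate_step_table(noise_free_cfg)
    ts = g.render_continuous(truth, noise_free_cfg)
    return truth, ts


def com_velocity(ts):
    """ML CoM-proxy velocity as the divergence analysis defines it."""
    from gaitstab.events import lowpass

    smoothed = lowpass(ts.axis("thorax", "ml"), ts.sample_rate, 10.0)
    return np.gradient(smoothed, ts.time)


def gait_lde(cfg, params=None):
    """Full chain: render, detect, normalize, divergence exponent."""
    truth = g.simulate_step_table(cfg)
    ts = g.render_continuous(truth, cfg)
    ev = g.detect_heelstrikes(ts)
    return g.compute_lde(
        com_velocity(ts), ts.time, g.reference_heelstrikes(ev),
        params or g.LdeParams(),
    )
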