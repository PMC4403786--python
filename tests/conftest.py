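"""Shared fixtures.

Expensive PDE runs are session-scoped and shared through a trace cache:
the capsule-thickness sweep at test resolution also serves the
calibration-recovery and biphasic-shape tests.
"""

import numpy as np
import pytest

from isletsim.observables import cached_base_trace, capsule_sweep
from isletsim.params import Config, DomainSettings, load_config
from isletsim.protocol import protocol_from_settings

#: cell size used for full-protocol runs in tests [m]
TEST_RESOLUTION = 25e-6
#: the published capsule-thickness sweep values [m]
SWEEP_LCAPS = [0.0, 50e-6, 100e-6, 150e-6, 200e-6, 250e-6, 300e-6, 350e-6]


@pytest.fixture()
def config() -> Config:
    return load_config()


@pytest.fixture(scope="session")
def session_config() -> Config:
    return load_config()


@pytest.fixture(scope="session")
def trace_cache() -> dict:
    return {}


@pytest.fixture(scope="session")
def sweep_table(session_config, trace_cache):
    """Capsule sweep 0..350 um at test resolution (8 simulations, shared)."""
    return capsule_sweep(
        SWEEP_LCAPS, session_config, resolution=TEST_RESOLUTION,
        trace_cache=trace_cache,
    )


@pytest.fixture(scope="session")
def free_trace(session_config, trace_cache):
    """Free-islet reference trace at the configured IEQ, from the cache."""
    from isletsim.simulate import config_with

    cfg = config_with(session_config, l_caps=0.0)
    proto = protocol_from_settings(cfg.protocol)
    base = cached_base_trace(cfg, proto, None, TEST_RESOLUTION, trace_cache)
    from isletsim.observables import PerifusionTrace

    return PerifusionTrace(
        times=base.times.copy(),
        insulin_out=base.insulin_out * cfg.observables.ieq,
        gluc_inlet=base.gluc_inlet.copy(),
        metadata={**base.metadata, "ieq": cfg.observables.ieq},
    )


def single_islet_settings(
    diameter=150e-6, length=2.0e-3, height=0.8e-3, l_caps=0.0
) -> DomainSettings:
    """Small one-islet chamber for fast solver-convergence tests."""
    return DomainSettings(
        channel_length=length,
        channel_height=height,
        l_caps=l_caps,
        islet_diameters=(diameter,),
        vertical_offset=0.0,
    )


def kinetics_off(cfg: Config) -> Config:
    """Copy of cfg with every reaction rate amplitude set to zero."""
    import copy

    out = copy.deepcopy(cfg)
    k = out.kinetics
    k.oxy_consumption.r_max = 0.0
    k.gluc_consumption.r_max = 0.0
    k.ins_phase1.r_max = 0.0
    k.ins_phase2.r_max = 0.0
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
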