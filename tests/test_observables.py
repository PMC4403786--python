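"""Experiment-scale observables: IEQ scaling, phase metrics, sweeps."""

import numpy as np
import pytest

from conftest import SWEEP_LCAPS, TEST_RESOLUTION
from isletsim.observables import (
    PerifusionTrace,
    phase_metrics,
    scale_to_ieq,
)
from isletsim.params import iequiv_volume
from isletsim.protocol import gsir_protocol


ISLET_AREA = np.pi * (50e-6) ** 2 + np.pi * (75e-6) ** 2
FLOW = 100e-9 / 60.0


def make_trace(times, conc, gluc=None):
    times = np.asarray(times, float)
    return PerifusionTrace(
        times=times,
        insulin_out=np.asarray(conc, float),
        gluc_inlet=np.asarray(gluc, float) if gluc is not None
        else np.full(times.shape, 3.0),
    )


class TestScaleToIeq:
    def test_effective_depth_definition(self):
        tr = scale_to_ieq([0, 60], [1e-12, 2e-12], ISLET_AREA, 50.0, FLOW)
        h_expected = iequiv_volume(50) / ISLET_AREA
        assert tr.metadata["effective_depth"] == pytest.approx(h_expected, rel=1e-12)
        assert tr.insulin_out[0] == pytest.approx(1e-12 * h_expected / FLOW, rel=1e-12)

    def test_linear_in_ieq(self):
        t1 = scale_to_ieq([0, 60], [1e-12, 2e-12], ISLET_AREA, 50.0, FLOW)
        t2 = scale_to_ieq([0, 60], [1e-12, 2e-12], ISLET_AREA, 100.0, FLOW)
        assert np.allclose(t2.insulin_out, 2 * t1.insulin_out, rtol=1e-12)

    def test_linear_in_flux(self):
        t1 = scale_to_ieq([0, 60], [1e-12, 2e-12], ISLET_AREA, 50.0, FLOW)
        t2 = scale_to_ieq([0, 60], [3e-12, 6e-12], ISLET_AREA, 50.0, FLOW)
        assert np.allclose(t2.insulin_out, 3 * t1.insulin_out, rtol=1e-12)

    def test_zero_flux(self):
        tr = scale_to_ieq([0, 60], [0.0, 0.0], ISLET_AREA, 50.0, FLOW)
        assert np.all(tr.insulin_out == 0.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            scale_to_ieq([0, 60], [0, 0], 0.0, 50.0, FLOW)
        with pytest.raises(ValueError):
            scale_to_ieq([0, 60], [0, 0], ISLET_AREA, 0.0, FLOW)

    def test_display_units(self):
        tr = make_trace([0, 60], [6e-9, 12e-9])
        # 1 uU/mL == 6e-9 mol/m^3 at 1 U = 6 nmol
        assert tr.insulin_uU_per_mL()[0] == pytest.approx(1.0)


class TestPhaseMetrics:
    def synthetic_biphasic(self):
        """Hand-built trace on the reference protocol: basal 1, ramp to a
        5.0 peak at t = 480 s, decay to a 2.0 plateau."""
        t = np.arange(0, 2460, 60.0)
        c = np.full(t.shape, 1.0)
        c[(t >= 360) & (t < 480)] = [3.0, 4.0]
        c[t == 480] = 5.0
        c[(t > 480) & (t <= 900)] = [4.0, 3.0, 2.5, 2.2, 2.1, 2.05, 2.0]
        c[(t > 900) & (t <= 1500)] = 2.0
        c[t > 1500] = 1.0
        return make_trace(t, c)

    def test_hand_built_metrics(self):
        m = phase_metrics(self.synthetic_biphasic(), gsir_protocol())
        assert m.basal == pytest.approx(1.0)
        assert m.peak == pytest.approx(5.0)
        assert m.time_to_peak == pytest.approx(180.0)  # 480 s - 300 s onset
        assert m.plateau == pytest.approx(2.0)
        # half rise = 1 + 2 = 3.0, first reached at t = 360 -> delay 60 s
        assert m.delay == pytest.approx(60.0)
        assert m.reliable

    def test_constant_trace_flagged(self):
        t = np.arange(0, 2460, 60.0)
        m = phase_metrics(make_trace(t, np.ones_like(t)), gsir_protocol())
        assert not m.reliable
        assert np.isnan(m.delay)
        assert m.peak == m.plateau == m.basal == pytest.approx(1.0)

    def test_trace_must_span_high_segment(self):
        with pytest.raises(ValueError):
            phase_metrics(make_trace([0, 60], [1, 1]), gsir_protocol())


class TestCapsuleSweep:
    def test_peak_height_nonincreasing(self, sweep_table):
        peaks = sweep_table["peak"].to_numpy()
        assert np.all(np.diff(peaks) <= 1e-9 * peaks[0])

    def test_time_to_peak_nondecreasing(self, sweep_table):
        ttp = sweep_table["time_to_peak"].to_numpy()
        assert np.all(np.diff(ttp) >= -1e-9)

    def test_encapsulation_blunts_and_delays(self, sweep_table):
        """Thick capsules blunt the first phase and delay its arrival."""
        row0 = sweep_table.iloc[0]
        row_thick = sweep_table.iloc[-1]
        assert row_thick["peak"] < row0["peak"]
        assert row_thick["delay"] >= row0["delay"]

    def test_sweep_covers_requested_thicknesses(self, sweep_table):
        assert sweep_table["l_caps"].tolist() == SWEEP_LCAPS

    def test_singleton_sweep_matches_direct_run(self, session_config, trace_cache):
        from isletsim.observables import capsule_sweep, simulate_trace
        from isletsim.simulate import config_with

        table = capsule_sweep(
            [0.0], session_config, resolution=TEST_RESOLUTION,
            trace_cache=trace_cache,
        )
        cfg = config_with(session_config, l_caps=0.0)
        direct = simulate_trace(cfg, resolution=TEST_RESOLUTION)
        assert table.iloc[0]["total_insulin"] == pytest.approx(
            direct.total_insulin(), rel=1e-9
        )

    def test_biphasic_shape_free_islets(self, free_trace, session_config):
        """Distinct first-phase peak within 10 min of the step, then a
        lower sustained plateau."""
        from isletsim.protocol import protocol_from_settings

        proto = protocol_from_settings(session_config.protocol)
        m = phase_metrics(free_trace, proto)
        assert m.reliable
        assert 0.0 < m.time_to_peak <= 600.0
        assert m.peak > 1.2 * m.plateau
        assert m.plateau > m.basal

    def test_k_insl_governs_first_phase_sharpness(
        self, session_config, trace_cache, free_trace
    ):
        """Slower local release (human 0.003 vs murine 0.006 s^-1) lowers
        and delays the first-phase peak."""
        import copy

        from isletsim.observables import cached_base_trace
        from isletsim.protocol import protocol_from_settings
        from isletsim.simulate import config_with

        cfg = config_with(session_config, l_caps=0.0)
        cfg = copy.deepcopy(cfg)
        cfg.kinetics.k_insl = 0.003
        proto = protocol_from_settings(cfg.protocol)
        slow_base = cached_base_trace(cfg, proto, None, TEST_RESOLUTION, trace_cache)
        slow = PerifusionTrace(
            times=slow_base.times,
            insulin_out=slow_base.insulin_out * cfg.observables.ieq,
            gluc_inlet=slow_base.gluc_inlet,
        )
        m_fast = phase_metrics(free_trace, proto)
        m_slow = phase_metrics(slow, proto)
        assert m_slow.peak < m_fast.peak
        assert m_slow.time_to_peak >= m_fast.time_to_peak


class TestHypoxiaRatioIdentity:
    def test_identical_oxygen_gives_unity(self):
        """Running the same protocol twice on one chamber is deterministic,
        so the secretion ratio of two identical-oxygen runs is exactly 1."""
        from conftest import single_islet_settings
        from isletsim.params import load_config
        from isletsim.simulate import PerifusionSimulator
        from isletsim.protocol import Segment, StimulationProtocol

        cfg = load_config()
        cfg.domain = single_islet_settings()
        cfg.solver.resolution = 25e-6
        sim = PerifusionSimulator.from_config(cfg)
        proto = StimulationProtocol(
            segments=[Segment(60.0, 3.0, 0.2), Segment(240.0, 11.0, 0.2)],
            sampling_interval=60.0,
        )
        tot = []
        for _ in range(2):
            res = sim.run(proto)
            tot.append(np.trapezoid(res.insulin_outflux, res.times))
        assert tot[0] == tot[1]
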