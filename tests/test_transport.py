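"""Coupled transport solver: conservation, convergence, analytic limits."""

import copy

import numpy as np
import pytest

from conftest import kinetics_off, single_islet_settings
from isletsim.geometry import ISLET, DomainSpec, build_mesh
from isletsim.params import load_config
from isletsim.protocol import Segment, StimulationProtocol
from isletsim.simulate import PerifusionSimulator
from isletsim.transport import TransportSolver
from isletsim.flow import solve_flow


def small_config(l_caps=0.0, resolution=25e-6, **solver_kw):
    cfg = load_config()
    cfg.domain = single_islet_settings(l_caps=l_caps)
    cfg.solver.resolution = resolution
    for k, v in solver_kw.items():
        setattr(cfg.solver, k, v)
    return cfg


def short_protocol(tau=60.0, sampling=60.0):
    return StimulationProtocol(
        segments=[Segment(120.0, 3.0, 0.2), Segment(480.0, 11.0, 0.2),
                  Segment(120.0, 3.0, 0.2)],
        sampling_interval=sampling,
        smoothing_tau=tau,
    )


@pytest.fixture(scope="module")
def single_islet_sim():
    return PerifusionSimulator.from_config(small_config())


class TestTrivialAndBounds:
    def test_uniform_state_is_steady_without_kinetics(self):
        cfg = kinetics_off(small_config())
        cfg.domain.islet_diameters = ()
        sim = PerifusionSimulator.from_config(cfg)
        st = sim.solver.steady_state(3.0, 0.2)
        assert np.allclose(st.c_gluc, 3.0, rtol=1e-9)
        assert np.allclose(st.c_oxy, 0.2, rtol=1e-9)
        st2 = sim.solver.step(st, 3.0, 0.2)
        assert np.allclose(st2.c_gluc, st.c_gluc, rtol=1e-9, atol=1e-12)

    def test_outlet_step_respects_transit_delay(self):
        """With advection only, the outlet cannot see the new inlet level
        before the fastest streamline has crossed the channel."""
        cfg = kinetics_off(small_config(resolution=20e-6))
        cfg.domain.islet_diameters = ()
        sim = PerifusionSimulator.from_config(cfg, dt=0.5)
        u_max = sim.velocity.max_speed()
        proto = StimulationProtocol(
            segments=[Segment(30.0, 3.0, 0.2), Segment(170.0, 11.0, 0.2)],
            sampling_interval=2.0,
            smoothing_tau=0.0,
        )
        res = sim.run(proto)
        delay = cfg.domain.channel_length / u_max
        gluc = res.outflow_conc["gluc"]
        t = res.times
        # the foot of the front (numerically smeared) stays low well before
        # the fastest streamline can arrive ...
        assert gluc[t <= 30.0 + 0.8 * delay].max() < 3.0 + 0.05 * 8.0
        # ... and the half-rise arrives no earlier than the transit bound
        t_half = t[gluc >= 7.0][0]
        assert t_half >= 30.0 + delay
        assert gluc[-1] == pytest.approx(11.0, rel=0.01)

    def test_protocol_must_tile_dt(self, single_islet_sim):
        bad = StimulationProtocol(segments=[Segment(10.5, 3.0, 0.2)])
        with pytest.raises(ValueError):
            single_islet_sim.run(bad)


class TestSteadyOxygen:
    def test_no_consumption_uniform(self):
        cfg = kinetics_off(small_config())
        sim = PerifusionSimulator.from_config(cfg)
        fld, frac = sim.solver.steady_oxygen(0.2, 3.0)
        assert np.allclose(fld, 0.2, rtol=1e-9)
        assert frac == 0.0

    def test_core_below_surface(self, single_islet_sim):
        sim = single_islet_sim
        fld, _ = sim.solver.steady_oxygen(0.2, 11.0)
        mesh = sim.mesh
        islet = fld[mesh.islet_cells]
        X, Y = mesh.cell_centers()
        xc = X.ravel()[mesh.islet_cells]
        yc = Y.ravel()[mesh.islet_cells]
        isl = mesh.spec.islets[0]
        r = np.hypot(xc - isl.cx, yc - isl.cy)
        core = islet[r < 0.3 * isl.radius].mean()
        rim = islet[r > 0.8 * isl.radius].mean()
        assert core < rim < 0.2

    def test_encapsulation_deepens_hypoxia(self):
        mins = {}
        for l_caps in (0.0, 150e-6):
            sim = PerifusionSimulator.from_config(small_config(l_caps=l_caps))
            fld, _ = sim.solver.steady_oxygen(0.2, 11.0)
            mins[l_caps] = fld[sim.mesh.islet_cells].min()
        assert mins[150e-6] < mins[0.0]

    def test_zeroth_order_limit_matches_closed_form(self):
        """Constant-rate consumption in a disk: c(r) = c0 + R r^2 / (4D)."""
        cfg = small_config(resolution=5e-6)
        cfg.domain.channel_length = 1.0e-3
        cfg.domain.channel_height = 0.6e-3
        cfg.flow.mean_speed = 0.0  # quiescent medium
        k = cfg.kinetics
        k.oxy_consumption.c_half = 1e-9  # zeroth-order limit
        k.oxy_metabolic_modulation.r_max = 0.0
        k.c_cr_oxy = 0.0  # no hypoxic cutoff
        sim = PerifusionSimulator.from_config(cfg)
        fld, _ = sim.solver.steady_oxygen(0.2, 3.0)
        mesh = sim.mesh
        isl = mesh.spec.islets[0]
        X, Y = mesh.cell_centers()
        r = np.hypot(X.ravel() - isl.cx, Y.ravel() - isl.cy)[mesh.islet_cells]
        vals = fld[mesh.islet_cells]
        center = vals[r < 1.5 * mesh.h].mean()
        ring_sel = np.abs(r - 0.8 * isl.radius) < mesh.h
        ring = vals[ring_sel].mean()
        R0 = 0.034
        D = cfg.materials["tissue"].d_oxy
        expected = R0 * (0.8 * isl.radius) ** 2 / (4 * D)
        assert ring - center == pytest.approx(expected, rel=0.05)


class TestConservation:
    def test_mass_balance_without_kinetics(self):
        cfg = kinetics_off(small_config(time_order=1))
        sim = PerifusionSimulator.from_config(cfg)
        st0 = sim.solver.steady_state(3.0, 0.2)
        a = sim.solver.a
        content0 = a * st0.c_gluc.sum()
        proto = StimulationProtocol(
            segments=[Segment(60.0, 3.0, 0.2), Segment(240.0, 11.0, 0.2)],
            sampling_interval=60.0, smoothing_tau=0.0,
        )
        res = sim.run(proto, track_balance=True, initial_state=st0)
        dt = sim.solver.dt
        net_in = sum(b.inflow["gluc"] - b.outflow["gluc"] for b in res.balances) * dt
        d_content = res.balances[-1].content["gluc"] - content0
        assert net_in == pytest.approx(d_content, rel=5e-3)

    def test_insulin_release_accounting(self, single_islet_sim):
        """Released insulin = outflow + domain content change (implicit
        Euler makes the discrete budget exact; tolerance is loose)."""
        cfg = small_config(time_order=1)
        sim = PerifusionSimulator.from_config(cfg)
        st0 = sim.solver.steady_state(3.0, 0.2)
        a = sim.solver.a
        content0 = a * st0.c_ins.sum()
        proto = short_protocol()
        res = sim.run(proto, track_balance=True, initial_state=st0)
        dt = sim.solver.dt
        released = sum(b.reaction["ins"] for b in res.balances) * dt
        outflow = sum(b.outflow["ins"] for b in res.balances) * dt
        d_content = res.balances[-1].content["ins"] - content0
        assert released == pytest.approx(outflow + d_content, rel=0.01)

    def test_nonnegativity_throughout(self, single_islet_sim):
        res = single_islet_sim.run(short_protocol())
        st = res.final_state
        for arr in (st.c_gluc, st.c_oxy, st.c_ins, st.c_insl):
            assert arr.min() >= 0.0
        for f, series in res.outflow_conc.items():
            assert series.min() >= 0.0


class TestConvergence:
    def test_time_step_halving(self):
        traces = {}
        for dt in (1.0, 0.5):
            sim = PerifusionSimulator.from_config(small_config(), dt=dt)
            res = sim.run(short_protocol())
            traces[dt] = res.insulin_outflux
        diff = np.linalg.norm(traces[1.0] - traces[0.5])
        ref = np.linalg.norm(traces[0.5])
        assert diff / ref < 0.01

    def test_mesh_refinement(self):
        traces = {}
        for h in (25e-6, 12.5e-6):
            sim = PerifusionSimulator.from_config(small_config(resolution=h))
            res = sim.run(short_protocol())
            traces[h] = res.insulin_outflux
        diff = np.linalg.norm(traces[25e-6] - traces[12.5e-6])
        ref = np.linalg.norm(traces[12.5e-6])
        assert diff / ref < 0.02

    def test_biphasic_response_in_small_chamber(self, single_islet_sim):
        """Glucose step-up produces a transient first-phase overshoot."""
        res = single_islet_sim.run(short_protocol())
        c = res.outflow_conc["ins"]
        t = res.times
        onset, end = 120.0, 600.0
        sel = (t >= onset) & (t <= end)
        peak = c[sel].max()
        late = c[(t > end - 120) & (t <= end)].mean()
        assert peak > 1.2 * late
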