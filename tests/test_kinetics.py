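"""Point-wise Hill kinetics: identities, published values, oracle checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import isletsim.kinetics as kin
from isletsim.kinetics import LocalState
from isletsim.params import HillParams, KineticParams


def state(c_gluc=3.0, c_oxy=0.2, c_ins=0.0, c_insl=0.0, c_t=0.0):
    return LocalState(
        c_gluc=np.asarray(c_gluc, float),
        c_oxy=np.asarray(c_oxy, float),
        c_ins=np.asarray(c_ins, float),
        c_insl=np.asarray(c_insl, float),
        c_t=np.asarray(c_t, float),
    )


class TestHill:
    def test_half_max_exact(self):
        p = HillParams(r_max=3e-5, c_half=7.0, n=2.5)
        assert kin.hill(7.0, p) == pytest.approx(1.5e-5, rel=1e-14)

    def test_zero(self):
        assert kin.hill(0.0, HillParams(1.0, 7.0, 2.5)) == 0.0

    def test_saturation_limit(self):
        p = HillParams(r_max=2.0, c_half=7.0, n=2.5)
        assert kin.hill(7e6, p) == pytest.approx(2.0, rel=1e-9)

    def test_high_precision_value(self):
        # independently computed with 50-digit arithmetic (mpmath):
        # 11^2.5 / (11^2.5 + 7^2.5) = 0.75583203562818616...
        assert kin.hill_fraction(11.0, 7.0, 2.5) == pytest.approx(
            0.75583203562818616, abs=1e-14
        )

    def test_negative_clamped(self):
        assert kin.hill(-1.0, HillParams(1.0, 7.0, 2.5)) == 0.0

    @given(
        c1=st.floats(0, 100),
        c2=st.floats(0, 100),
        n=st.floats(0.5, 5),
        ch=st.floats(1e-3, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_nondecreasing(self, c1, c2, n, ch):
        p = HillParams(r_max=1.0, c_half=ch, n=n)
        lo, hi = sorted((c1, c2))
        assert kin.hill(lo, p) <= kin.hill(hi, p) + 1e-15


class TestOxygenConsumption:
    def test_negative_under_normoxia(self, config):
        r = kin.oxygen_consumption(state(c_gluc=3.0, c_oxy=0.2), config.kinetics)
        # direct composition of the published factors
        k = config.kinetics
        expected = (
            -0.034
            * kin.hill_fraction(0.2, 1e-3, 1.0)
            * (1.0 + k.oxy_metabolic_modulation.r_max * kin.hill_fraction(3.0, 7.0, 2.5))
        )
        assert r == pytest.approx(expected, rel=1e-12)
        assert r < 0

    def test_cut_to_zero_below_critical(self, config):
        k = config.kinetics
        r = kin.oxygen_consumption(state(c_oxy=0.5 * k.c_cr_oxy), k)
        assert r == 0.0

    def test_metabolic_demand_increases_with_glucose(self, config):
        k = config.kinetics
        r3 = kin.oxygen_consumption(state(c_gluc=3.0, c_oxy=0.1), k)
        r11 = kin.oxygen_consumption(state(c_gluc=11.0, c_oxy=0.1), k)
        assert abs(r11) > abs(r3)

    def test_ramp_continuity(self, config):
        k = config.kinetics
        lo, hi = k.c_cr_oxy, k.cutoff_ramp_factor * k.c_cr_oxy
        for edge in (lo, hi):
            below = kin.oxygen_consumption(state(c_oxy=edge * (1 - 1e-9)), k)
            above = kin.oxygen_consumption(state(c_oxy=edge * (1 + 1e-9)), k)
            # continuous with finite slope: the jump vanishes with epsilon
            assert below == pytest.approx(above, abs=1e-10)


class TestGlucoseConsumption:
    def test_half_max(self, config):
        r = kin.glucose_consumption(state(c_gluc=1e-2), config.kinetics)
        assert r == pytest.approx(-0.014, rel=1e-12)

    def test_zero(self, config):
        assert kin.glucose_consumption(state(c_gluc=0.0), config.kinetics) == 0.0

    def test_physiological_value(self, config):
        r = kin.glucose_consumption(state(c_gluc=11.0), config.kinetics)
        assert r == pytest.approx(-0.028 * 11.0 / 11.01, rel=1e-12)


class TestInsulinSecretion:
    def test_pure_second_phase_half_max(self, config):
        r = kin.insulin_secretion(state(c_gluc=7.0, c_oxy=0.2, c_t=0.0),
                                  config.kinetics)
        assert r == pytest.approx(1.5e-5, rel=1e-3)  # oxygen fraction ~ 1

    def test_falling_glucose_equals_no_gradient(self, config):
        r0 = kin.insulin_secretion(state(c_t=0.0), config.kinetics)
        rneg = kin.insulin_secretion(state(c_t=-0.05), config.kinetics)
        assert rneg == r0

    def test_anoxia_stops_secretion(self, config):
        r = kin.insulin_secretion(state(c_gluc=11.0, c_oxy=0.0, c_t=1.0),
                                  config.kinetics)
        assert r == 0.0

    def test_continuous_at_gradient_switch(self, config):
        r0 = kin.insulin_secretion(state(c_t=0.0), config.kinetics)
        reps = kin.insulin_secretion(state(c_t=1e-9), config.kinetics)
        assert reps == pytest.approx(r0, abs=1e-15)

    def test_phase1_window_peaks_near_5mM(self, config):
        w = config.kinetics.phase1_window
        grid = np.linspace(0.0, 40.0, 16001)
        vals = kin.phase1_window(grid, w)
        assert vals.max() == pytest.approx(1.0, abs=1e-12)
        assert 4.0 < grid[np.argmax(vals)] < 7.5  # maximum near normoglycemia
        # suppressed at extremes
        assert kin.phase1_window(0.5, w) < 0.05
        assert kin.phase1_window(35.0, w) < 0.5


class TestLocalInsulinPool:
    def test_equilibrium(self, config):
        d, src = kin.local_insulin_rhs(state(c_ins=1.0, c_insl=1.0), 0.0,
                                       config.kinetics)
        assert d == 0.0 and src == 0.0

    def test_closed_system_conservation(self, config):
        # d(c_insL + c_ins)/dt = R_ins exactly, for arbitrary states
        s = state(c_ins=0.3, c_insl=1.7)
        r_ins = 2.5e-5
        d_insl, src = kin.local_insulin_rhs(s, r_ins, config.kinetics)
        assert d_insl + src == pytest.approx(r_ins, rel=1e-12)

    @pytest.mark.parametrize("k_insl", [0.003, 0.006])
    def test_relaxation_time_constant(self, config, k_insl):
        """0D pool relaxes toward R/k + c_ins with time constant 1/k."""
        config.kinetics.k_insl = k_insl
        r_ins, c_ins = 3e-5, 0.0

        def rhs(t, y):
            d, _ = kin.local_insulin_rhs(state(c_ins=c_ins, c_insl=y[0]),
                                         r_ins, config.kinetics)
            return [float(d)]

        sol = solve_ivp(rhs, (0, 1 / k_insl), [0.0], rtol=1e-10, atol=1e-14)
        expected = (r_ins / k_insl) * (1 - np.exp(-1.0))  # analytic solution
        assert sol.y[0, -1] == pytest.approx(expected, rel=1e-6)


class TestComposedRatesOracle:
    def test_sign_invariants_random_states(self, config, rng):
        n = 1000
        s = state(
            c_gluc=rng.uniform(0, 30, n),
            c_oxy=rng.uniform(0, 0.3, n),
            c_ins=rng.uniform(0, 1e-3, n),
            c_insl=rng.uniform(0, 1e-2, n),
            c_t=rng.uniform(-0.2, 0.2, n),
        )
        rates = kin.reaction_rates(s, config.kinetics)
        assert np.all(rates.r_gluc <= 0)
        assert np.all(rates.r_oxy <= 0)
        assert np.all(rates.r_ins >= 0)

    def test_matches_high_precision_reevaluation(self, config, rng):
        """Composed rates agree with an independent mpmath recomputation."""
        import mpmath as mp

        mp.mp.dps = 40
        k = config.kinetics
        n = 1000
        cg = rng.uniform(0, 30, n)
        co = rng.uniform(0, 0.3, n)
        ct = rng.uniform(-0.1, 0.2, n)
        s = state(c_gluc=cg, c_oxy=co, c_t=ct)
        rates = kin.reaction_rates(s, k)

        def f_H(c, ch, nn):
            c, ch, nn = mp.mpf(c), mp.mpf(ch), mp.mpf(nn)
            if c <= 0:
                return mp.mpf(0)
            return c**nn / (c**nn + ch**nn)

        # window normalization constant, recomputed coarsely but precisely
        wgrid = np.linspace(0, 40, 16001)
        wpeak = max(
            float(f_H(g, k.phase1_window.rise_c_half, k.phase1_window.rise_n)
                  * (1 - f_H(g, k.phase1_window.fall_c_half, k.phase1_window.fall_n)))
            for g in wgrid[np.argsort(-kin.phase1_window(wgrid, k.phase1_window))[:5]]
        )

        idx = rng.choice(n, size=50, replace=False)  # 50 spot checks at dps=40
        for i in idx:
            ramp = min(max((co[i] - k.c_cr_oxy) /
                           (k.c_cr_oxy * (k.cutoff_ramp_factor - 1)), 0.0), 1.0)
            r_oxy = (
                mp.mpf(k.oxy_consumption.r_max)
                * f_H(co[i], k.oxy_consumption.c_half, 1)
                * (1 + mp.mpf(k.oxy_metabolic_modulation.r_max)
                   * f_H(cg[i], 7, 2.5))
                * ramp
            )
            assert float(r_oxy) == pytest.approx(rates.r_oxy[i], rel=1e-12, abs=1e-25)

            r_gluc = mp.mpf(k.gluc_consumption.r_max) * f_H(cg[i], mp.mpf("0.01"), 1)
            assert float(r_gluc) == pytest.approx(rates.r_gluc[i], rel=1e-12, abs=1e-25)

            ph2 = mp.mpf(k.ins_phase2.r_max) * f_H(cg[i], 7, mp.mpf("2.5"))
            ph1 = mp.mpf(0)
            if ct[i] > 0:
                w = (f_H(cg[i], k.phase1_window.rise_c_half, k.phase1_window.rise_n)
                     * (1 - f_H(cg[i], k.phase1_window.fall_c_half,
                                k.phase1_window.fall_n)) / mp.mpf(wpeak))
                ph1 = mp.mpf(k.ins_phase1.r_max) * f_H(ct[i], mp.mpf("0.03"), 2) * w
            r_ins = (ph2 + ph1) * f_H(co[i], mp.mpf("0.003"), 3)
            assert float(r_ins) == pytest.approx(rates.r_ins[i], rel=1e-11, abs=1e-25)
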