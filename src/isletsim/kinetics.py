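"""Cellular-level reaction kinetics of glucose-stimulated insulin release.

Pure, point-wise (0D) functions; every rate is a Hill law or a product of
Hill laws of the *local* concentrations. They vectorize over numpy arrays
and are used unchanged by the PDE solver inside islet cells and by the 0D
tests.

Model summary (all rates in mol·m⁻³·s⁻¹ of islet tissue):

* oxygen consumption: ``R_oxy = R_max,oxy · f_H(c_oxy; 1 μM, 1) ·
  φ_o,g(c_gluc) · ramp(c_oxy)`` — Michaelis–Menten in oxygen, amplified at
  high glucose by the metabolic-demand factor φ_o,g, and ramped to zero
  below the critical oxygen concentration;
* glucose consumption: Michaelis–Menten, ``R_max,gluc · f_H(c_gluc; 10 μM, 1)``;
* insulin secretion: second phase follows local glucose
  (``f_H(c_gluc; 7 mM, 2.5)``), first phase follows the *rise rate* of local
  glucose (``f_H(∂c_gluc/∂t; 0.03 mM s⁻¹, 2)``, zero when glucose falls)
  gated by a glucose window peaking near 5 mM; the sum is throttled by the
  oxygen fraction ``f_H(c_oxy; 3 μM, 3)``;
* local insulin pool: insulin is secreted into an intra-islet compartment
  ``c_insL`` and released to the medium with first-order rate ``k_insL``:
  ``dc_insL/dt = R_ins − k_insL (c_insL − c_ins)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .params import HillParams, KineticParams, Phase1Window

log = logging.getLogger(__name__)

__all__ = [
    "LocalState",
    "ReactionRates",
    "hill",
    "hill_fraction",
    "oxygen_consumption",
    "glucose_consumption",
    "insulin_secretion",
    "local_insulin_rhs",
    "phase1_window",
    "hypoxia_ramp",
    "reaction_rates",
]


@dataclass
class LocalState:
    """Concentrations at one point (or arrays of points).

    ``c_t`` is the local glucose time-gradient ∂c_gluc/∂t; it may have any
    sign. Concentrations are clamped to 0 before rate evaluation.
    """

    c_gluc: np.ndarray
    c_oxy: np.ndarray
    c_ins: np.ndarray
    c_insl: np.ndarray
    c_t: np.ndarray


@dataclass
class ReactionRates:
    """Signed volumetric rates: consumption ≤ 0, secretion ≥ 0."""

    r_gluc: np.ndarray
    r_oxy: np.ndarray
    r_ins: np.ndarray
    dc_insl_dt: np.ndarray


def _clamped(c):
    """Clamp negative concentrations (discretization undershoot) to zero."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        log.debug("clamped %d negative concentration value(s)", int(np.sum(c < 0)))
        c = np.maximum(c, 0.0)
    return c


def hill(c, p: HillParams):
    """Hill rate ``R_max · cⁿ / (cⁿ + C_Hfⁿ)``.

    With ``R_max = 1`` this is the dimensionless saturation fraction.
    Negative ``c`` is clamped to 0 (where the rate vanishes).
    """
    c = _clamped(c)
    cn = np.power(c, p.n)
    return p.r_max * cn / (cn + p.c_half**p.n)


def hill_fraction(c, c_half: float, n: float):
    """Dimensionless Hill fraction ``cⁿ/(cⁿ + c_halfⁿ)``."""
    return hill(c, HillParams(r_max=1.0, c_half=c_half, n=n))


def hypoxia_ramp(c_oxy, k: KineticParams):
    """Consumption cutoff factor: 1 above ``ramp_factor·C_cr``, 0 below C_cr.

    A linear ramp replaces the published hard cutoff for solver stability;
    the width is configurable via ``cutoff_ramp_factor``.
    """
    c_oxy = np.asarray(c_oxy, dtype=float)
    lo = k.c_cr_oxy
    hi = k.cutoff_ramp_factor * k.c_cr_oxy
    if hi <= lo:  # c_cr_oxy == 0: no cutoff
        return np.ones_like(c_oxy)
    return np.clip((c_oxy - lo) / (hi - lo), 0.0, 1.0)


def metabolic_demand(c_gluc, k: KineticParams):
    """φ_o,g(c_gluc) = 1 + a · f_H(c_gluc): oxygen demand rises with glucose,
    paralleling second-phase secretion."""
    p = k.oxy_metabolic_modulation
    return 1.0 + p.r_max * hill_fraction(c_gluc, p.c_half, p.n)


def oxygen_consumption(s: LocalState, k: KineticParams):
    """R_oxy ≤ 0; cut to zero below the critical oxygen concentration."""
    base = hill(s.c_oxy, k.oxy_consumption)
    return base * metabolic_demand(s.c_gluc, k) * hypoxia_ramp(s.c_oxy, k)


def glucose_consumption(s: LocalState, k: KineticParams):
    """R_gluc ≤ 0 (Michaelis–Menten; no oxygen feedback)."""
    return hill(s.c_gluc, k.gluc_consumption)


def phase1_window(c_gluc, w: Phase1Window):
    """Glucose gate for first-phase secretion, normalized to peak 1 (~5 mM)."""
    c_gluc = _clamped(c_gluc)
    raw = hill_fraction(c_gluc, w.rise_c_half, w.rise_n) * (
        1.0 - hill_fraction(c_gluc, w.fall_c_half, w.fall_n)
    )
    return raw / _window_peak(w)


def _window_peak(w: Phase1Window) -> float:
    key = (w.rise_c_half, w.rise_n, w.fall_c_half, w.fall_n)
    peak = _WINDOW_PEAK_CACHE.get(key)
    if peak is None:
        grid = np.linspace(0.0, 40.0, 16001)
        raw = hill_fraction(grid, w.rise_c_half, w.rise_n) * (
            1.0 - hill_fraction(grid, w.fall_c_half, w.fall_n)
        )
        peak = float(raw.max())
        _WINDOW_PEAK_CACHE[key] = peak
    return peak


_WINDOW_PEAK_CACHE: dict = {}


def insulin_secretion(s: LocalState, k: KineticParams):
    """R_ins ≥ 0: (second phase + gated first phase) × oxygen fraction.

    The first-phase Hill term acts on the glucose time-gradient and is
    non-zero only while local glucose increases (c_t > 0); since the Hill
    fraction itself vanishes as c_t → 0⁺, the switch is continuous.
    """
    c_t = np.asarray(s.c_t, dtype=float)
    second = hill(s.c_gluc, k.ins_phase2)
    first = np.where(
        c_t > 0.0,
        hill(np.maximum(c_t, 0.0), k.ins_phase1),
        0.0,
    ) * phase1_window(s.c_gluc, k.phase1_window)
    oxy = hill_fraction(s.c_oxy, k.ins_oxy_modulation.c_half, k.ins_oxy_modulation.n)
    return (second + first) * oxy


def local_insulin_rhs(s: LocalState, r_ins, k: KineticParams):
    """Right-hand sides of the local-insulin exchange.

    Returns ``(dc_insL/dt, source)`` where ``source = k_insL (c_insL −
    c_ins)`` is the volumetric release entering the transported insulin
    field inside islets (so that d(c_insL + c_ins)/dt = R_ins in a closed
    system).
    """
    exchange = k.k_insl * (np.asarray(s.c_insl, float) - np.asarray(s.c_ins, float))
    return np.asarray(r_ins, float) - exchange, exchange


def reaction_rates(s: LocalState, k: KineticParams) -> ReactionRates:
    """All composed rates at once."""
    r_ins = insulin_secretion(s, k)
    dc_insl, _ = local_insulin_rhs(s, r_ins, k)
    return ReactionRates(
        r_gluc=glucose_consumption(s, k),
        r_oxy=oxygen_consumption(s, k),
        r_ins=r_ins,
        dc_insl_dt=dc_insl,
    )
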