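"""Experiment-comparable observables from simulation output.

The solver works in a 2D channel cross-section and yields insulin outflow
per unit depth. To compare with perifusion measurements the 2D flux is
converted to a 3D outflow concentration by assigning the chamber an
effective depth such that the modeled islet cross-sections carry the
experiment's total islet volume (in islet equivalents, IEQ):

    h_eff = V_IEQ(target_ieq) / Σ islet areas,
    c_out = Φ_2D · h_eff / Q,

with Φ_2D the 2D outflow flux [mol s⁻¹ m⁻¹] and Q the perifusate flow
rate. The module also computes first/second-phase summary metrics,
capsule-thickness sweeps, and the low-oxygen secretion ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import Config, iequiv_volume
from .protocol import StimulationProtocol, gsir_protocol, protocol_from_settings
from .simulate import PerifusionSimulator, config_with

#: duration of the window after glucose step-up searched for the
#: first-phase peak [s]
PHASE1_WINDOW = 600.0
#: plateau = mean over this trailing part of the high-glucose segment [s]
PLATEAU_WINDOW = 300.0


@dataclass
class PerifusionTrace:
    """Outflow insulin time series with protocol annotations."""

    times: np.ndarray  # [s], strictly increasing
    insulin_out: np.ndarray  # [mol m^-3]
    gluc_inlet: np.ndarray  # [mol m^-3] annotation per sample
    metadata: dict = field(default_factory=dict)

    def validate(self):
        t = np.asarray(self.times, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if np.any(np.asarray(self.insulin_out) < 0):
            raise ValueError("outflow concentrations must be >= 0")

    def insulin_uU_per_mL(self, nmol_per_unit: float = 6.0) -> np.ndarray:
        """Display units: μU/mL (1 U = ``nmol_per_unit`` nmol insulin)."""
        return self.insulin_out / (nmol_per_unit * 1e-9)

    def total_insulin(self) -> float:
        """Time integral of outflow concentration [mol·s·m⁻³]."""
        return float(np.trapezoid(self.insulin_out, self.times))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times / 60.0,
                "insulin_out": self.insulin_out,
                "gluc_in_mM": self.gluc_inlet,
            }
        )

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata=None) -> "PerifusionTrace":
        df = pd.read_csv(path)
        required = {"time_min", "insulin_out"}
        if not required.issubset(df.columns):
            raise ValueError(f"trace CSV needs columns {sorted(required)}")
        gluc = df["gluc_in_mM"].to_numpy() if "gluc_in_mM" in df else np.full(len(df), np.nan)
        tr = cls(
            times=df["time_min"].to_numpy() * 60.0,
            insulin_out=df["insulin_out"].to_numpy(),
            gluc_inlet=gluc,
            metadata=metadata or {},
        )
        tr.validate()
        return tr


@dataclass
class PhaseMetrics:
    """First/second-phase summary of a biphasic GSIR trace."""

    basal: float
    peak: float  # first-phase peak outflow concentration
    time_to_peak: float  # from high-glucose onset [s]
    auc_phase1: float  # area of the first-phase excursion above basal
    plateau: float  # late second-phase level
    delay: float  # time to half of (peak - basal) above basal [s]
    reliable: bool = True

    def stimulation_index(self) -> float:
        return self.peak / self.basal if self.basal > 0 else math.inf


def scale_to_ieq(
    times,
    raw_2d_outflux,
    islet_area: float,
    target_ieq: float,
    flow_rate: float,
    gluc_inlet=None,
    metadata=None,
) -> PerifusionTrace:
    """Convert a per-unit-depth outflow flux series to concentrations.

    ``islet_area`` is the total modeled islet cross-section [m²]; the
    effective chamber depth is chosen so the islets carry ``target_ieq``
    islet equivalents of tissue. Linear in both the flux and the IEQ
    target.
    """
    if target_ieq <= 0:
        raise ValueError("target_ieq must be > 0")
    if islet_area <= 0:
        raise ValueError("modeled islet area must be > 0")
    if flow_rate <= 0:
        raise ValueError("flow_rate must be > 0")
    h_eff = iequiv_volume(target_ieq) / islet_area
    conc = np.asarray(raw_2d_outflux, float) * h_eff / flow_rate
    times = np.asarray(times, float)
    meta = dict(metadata or {})
    meta.update({"ieq": target_ieq, "effective_depth": h_eff, "flow_rate": flow_rate})
    trace = PerifusionTrace(
        times=times,
        insulin_out=conc,
        gluc_inlet=(
            np.asarray(gluc_inlet, float)
            if gluc_inlet is not None
            else np.full(times.shape, np.nan)
        ),
        metadata=meta,
    )
    trace.validate()
    return trace


def trace_from_result(result, mesh, config: Config, protocol=None) -> PerifusionTrace:
    """Scale a solver result to the configured IEQ count."""
    meta = {
        "l_caps": mesh.spec.l_caps,
        "oxygen_mode": config.protocol.oxygen_mode,
    }
    return scale_to_ieq(
        result.times,
        result.insulin_outflux,
        mesh.analytic_areas["islet"],
        config.observables.ieq,
        config.flow.flow_rate,
        gluc_inlet=result.gluc_inlet,
        metadata=meta,
    )


def simulate_trace(
    config: Config,
    protocol: StimulationProtocol | None = None,
    dt: float | None = None,
    resolution: float | None = None,
    simulator: PerifusionSimulator | None = None,
) -> PerifusionTrace:
    """Run one full perifusion simulation and return the scaled trace."""
    sim = simulator or PerifusionSimulator.from_config(
        config, dt=dt, resolution=resolution
    )
    proto = protocol if protocol is not None else protocol_from_settings(
        config.protocol
    )
    result = sim.run(proto)
    return trace_from_result(result, sim.mesh, config, proto)


def phase_metrics(trace: PerifusionTrace, protocol: StimulationProtocol) -> PhaseMetrics:
    """Summarize the biphasic response to the high-glucose step.

    Peak is searched within the first 10 min after the step-up; the
    plateau is the mean over the last 5 min of the high segment; the delay
    is the first time the outflow exceeds basal + (peak − basal)/2. A trace
    without a genuine interior peak is flagged unreliable rather than
    raising.
    """
    window = protocol.stimulation_window()
    if window is None:
        raise ValueError("protocol has no high-glucose segment")
    onset, seg_end = window
    t = np.asarray(trace.times, float)
    c = np.asarray(trace.insulin_out, float)
    if t[-1] < seg_end:
        raise ValueError("trace does not span the high-glucose segment")

    basal = float(np.mean(c[t <= onset])) if np.any(t <= onset) else float(c[0])
    sel = (t >= onset) & (t <= min(onset + PHASE1_WINDOW, seg_end))
    i_peak = int(np.argmax(c[sel]))
    t_sel = t[sel]
    peak = float(c[sel][i_peak])
    time_to_peak = float(t_sel[i_peak] - onset)

    plateau_sel = (t >= seg_end - PLATEAU_WINDOW) & (t <= seg_end)
    plateau = float(np.mean(c[plateau_sel]))

    rise = peak - basal
    reliable = True
    if rise <= max(1e-12, 1e-6 * max(peak, 1e-300)):
        # flat trace: peak == plateau == basal, delay undefined
        delay = float("nan")
        reliable = False
    else:
        above = t_sel[c[sel] >= basal + 0.5 * rise]
        delay = float(above[0] - onset) if above.size else float("nan")
        if i_peak == len(t_sel) - 1 and t_sel[-1] < seg_end - 1e-9:
            reliable = False  # peak at window edge: not a genuine transient
    auc = float(
        np.trapezoid(np.maximum(c[sel] - basal, 0.0), t_sel)
    )
    return PhaseMetrics(
        basal=basal,
        peak=peak,
        time_to_peak=time_to_peak,
        auc_phase1=auc,
        plateau=plateau,
        delay=delay,
        reliable=reliable,
    )


def capsule_sweep(
    l_caps_list,
    config: Config,
    protocol: StimulationProtocol | None = None,
    dt: float | None = None,
    resolution: float | None = None,
    trace_cache: dict | None = None,
) -> pd.DataFrame:
    """One full simulation per capsule thickness, identical protocol.

    Returns a table of phase metrics and total secreted insulin per
    thickness. ``trace_cache`` (fingerprint → PerifusionTrace) lets a
    calibration grid reuse sweep runs.
    """
    l_caps_list = list(l_caps_list)
    if not l_caps_list:
        raise ValueError("l_caps list must be non-empty")
    rows = []
    for l_caps in l_caps_list:
        cfg = config_with(config, l_caps=float(l_caps))
        proto = protocol if protocol is not None else protocol_from_settings(
            cfg.protocol
        )
        trace = _cached_trace(cfg, proto, dt, resolution, trace_cache)
        m = phase_metrics(trace, proto)
        rows.append(
            {
                "l_caps": float(l_caps),
                "peak": m.peak,
                "time_to_peak": m.time_to_peak,
                "delay": m.delay,
                "plateau": m.plateau,
                "basal": m.basal,
                "auc_phase1": m.auc_phase1,
                "total_insulin": trace.total_insulin(),
            }
        )
    return pd.DataFrame(rows)


def cached_base_trace(cfg, proto, dt=None, resolution=None, cache=None) -> PerifusionTrace:
    """Trace at IEQ = 1, memoized on the full configuration fingerprint.

    Outflow concentration is linear in the IEQ scale, so all consumers
    (sweeps, calibration grids) share simulations through this cache and
    rescale afterwards.
    """
    import copy as _copy

    from .simulate import config_fingerprint

    base_cfg = _copy.deepcopy(cfg)
    base_cfg.observables.ieq = 1.0
    if cache is None:
        return simulate_trace(base_cfg, proto, dt=dt, resolution=resolution)
    key = config_fingerprint(base_cfg, proto, dt, resolution)
    if key not in cache:
        cache[key] = simulate_trace(base_cfg, proto, dt=dt, resolution=resolution)
    return cache[key]


def _cached_trace(cfg, proto, dt, resolution, cache):
    base = cached_base_trace(cfg, proto, dt, resolution, cache)
    scale = cfg.observables.ieq
    return PerifusionTrace(
        times=base.times.copy(),
        insulin_out=base.insulin_out * scale,
        gluc_inlet=base.gluc_inlet.copy(),
        metadata={**base.metadata, "ieq": scale},
    )


def hypoxia_ratio(
    config: Config,
    dt: float | None = None,
    resolution: float | None = None,
    return_traces: bool = False,
):
    """Integrated-secretion ratio at tissue vs normoxic inlet oxygen.

    Runs the reference stimulation protocol twice on the same chamber —
    inlet oxygen 0.200 mol·m⁻³ (atmospheric equilibrium) and 0.060 mol·m⁻³
    (tissue-like) — and returns ∫insulin(tissue) / ∫insulin(normoxic).
    Mesh, flow and factorizations are shared between the two runs.
    """
    sim = PerifusionSimulator.from_config(config, dt=dt, resolution=resolution)
    ps = config.protocol
    traces = {}
    for mode in ("normoxic", "tissue"):
        proto = gsir_protocol(
            mode, ps.sampling_interval, ps.smoothing_tau
        )
        result = sim.run(proto)
        traces[mode] = scale_to_ieq(
            result.times,
            result.insulin_outflux,
            sim.mesh.analytic_areas["islet"],
            config.observables.ieq,
            config.flow.flow_rate,
            gluc_inlet=result.gluc_inlet,
            metadata={"l_caps": sim.mesh.spec.l_caps, "oxygen_mode": mode},
        )
    ratio = traces["tissue"].total_insulin() / traces["normoxic"].total_insulin()
    if return_traces:
        return ratio, traces
    return ratio
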