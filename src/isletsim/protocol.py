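"""Piecewise-constant inlet stimulation protocols.

The reference GSIR perifusion sequence is a low → high → low glucose step
(3 mM for 5 min, 11 mM for 20 min, 3 mM for 15 min) with outflow sampling
every minute. The KCl-depolarization segment of the wet-lab protocol has no
counterpart in the secretion model and is replaced by continued low
glucose; inlet oxygen is constant at either the atmospheric-equilibrium
value (0.200 mol·m⁻³ ≈ 140 mmHg) or a tissue-like value
(0.060 mol·m⁻³ ≈ 40 mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ConfigError, ProtocolSettings

#: inlet oxygen concentration by mode [mol m^-3]
OXYGEN_LEVELS = {"normoxic": 0.200, "tissue": 0.060}

GLUCOSE_LOW = 3.0  # [mol m^-3]
GLUCOSE_HIGH = 11.0


@dataclass
class Segment:
    """One constant-inlet interval."""

    duration: float  # [s]
    c_gluc: float  # [mol m^-3]
    c_oxy: float  # [mol m^-3]

    def validate(self):
        if self.duration <= 0:
            raise ConfigError("segment durations must be > 0")
        if self.c_gluc < 0 or self.c_oxy < 0:
            raise ConfigError("inlet concentrations must be >= 0")


@dataclass
class StimulationProtocol:
    """Ordered inlet segments plus the outflow sampling interval."""

    segments: list
    sampling_interval: float = 60.0
    #: first-order inlet dispersion constant [s] applied by the solver,
    #: modeling tubing/bead-bed dead volume (0 = perfectly sharp steps)
    smoothing_tau: float = 60.0

    def validate(self):
        if not self.segments:
            raise ConfigError("protocol needs at least one segment")
        for s in self.segments:
            s.validate()
        if self.sampling_interval <= 0:
            raise ConfigError("sampling_interval must be > 0")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def switch_times(self) -> np.ndarray:
        return np.cumsum([s.duration for s in self.segments])

    def inlet_at(self, t: float):
        """(c_gluc, c_oxy) at time ``t`` ∈ [0, total duration].

        Exact piecewise-constant lookup (no interpolation); at a switch
        time the value of the segment *beginning* there applies. The
        optional inlet-dispersion constant ``smoothing_tau`` is applied by
        the transport solver, not here.
        """
        total = self.total_duration
        if t < 0 or t > total:
            raise ValueError(f"t={t} outside protocol span [0, {total}]")
        edges = np.concatenate([[0.0], self.switch_times()])
        # segment index such that edges[k] <= t < edges[k+1] (last closed)
        k = int(np.searchsorted(edges, t, side="right") - 1)
        k = min(k, len(self.segments) - 1)
        seg = self.segments[k]
        return seg.c_gluc, seg.c_oxy

    def sample_times(self) -> np.ndarray:
        """Outflow sampling grid (first sample one interval after t = 0)."""
        n = int(np.floor(self.total_duration / self.sampling_interval + 1e-9))
        return np.arange(1, n + 1) * self.sampling_interval

    def stimulation_window(self):
        """(start, end) of the first high-glucose segment, for metrics."""
        t = 0.0
        base = self.segments[0].c_gluc
        for seg in self.segments:
            if seg.c_gluc > base:
                return t, t + seg.duration
            t += seg.duration
        return None


def gsir_protocol(
    oxygen_mode: str = "normoxic",
    sampling_interval: float = 60.0,
    smoothing_tau: float = 60.0,
) -> StimulationProtocol:
    """The reference low/high/low glucose step protocol.

    G3 (5 min) → G11 (20 min) → G3 (15 min); oxygen constant by mode.
    """
    if oxygen_mode not in OXYGEN_LEVELS:
        raise ConfigError(f"unknown oxygen_mode {oxygen_mode!r}")
    c_oxy = OXYGEN_LEVELS[oxygen_mode]
    proto = StimulationProtocol(
        segments=[
            Segment(300.0, GLUCOSE_LOW, c_oxy),
            Segment(1200.0, GLUCOSE_HIGH, c_oxy),
            Segment(900.0, GLUCOSE_LOW, c_oxy),
        ],
        sampling_interval=sampling_interval,
        smoothing_tau=smoothing_tau,
    )
    proto.validate()
    return proto


def protocol_from_settings(ps: ProtocolSettings) -> StimulationProtocol:
    """Build a protocol from config: explicit segments override the preset."""
    if ps.segments is not None:
        segs = []
        for item in ps.segments:
            if isinstance(item, dict):
                segs.append(
                    Segment(
                        duration=float(item["duration"]),
                        c_gluc=float(item["c_gluc"]),
                        c_oxy=float(item["c_oxy"]),
                    )
                )
            else:
                d, g, o = item
                segs.append(Segment(float(d), float(g), float(o)))
        proto = StimulationProtocol(
            segments=segs,
            sampling_interval=ps.sampling_interval,
            smoothing_tau=ps.smoothing_tau,
        )
        proto.validate()
        return proto
    if ps.preset != "gsir":
        raise ConfigError(f"unknown protocol preset {ps.preset!r}")
    return gsir_protocol(ps.oxygen_mode, ps.sampling_interval, ps.smoothing_tau)
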