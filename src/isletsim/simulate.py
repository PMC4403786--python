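"""High-level simulation pipeline: config → mesh → flow → transport.

A :class:`PerifusionSimulator` binds the expensive, geometry-dependent
pieces (labeled mesh, steady velocity field, transport factorizations) and
can then run any number of stimulation protocols — e.g. the same chamber
under normoxic and tissue-oxygen inlets — at marginal cost.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass

from .flow import mean_speed_from_flow_rate, solve_flow
from .geometry import build_mesh, domain_from_settings
from .params import Config, dump_config
from .protocol import StimulationProtocol, protocol_from_settings
from .transport import TransportResult, TransportSolver


@dataclass
class PerifusionSimulator:
    """One perifusion chamber, meshed and factorized, ready to run."""

    config: Config
    mesh: object
    velocity: object
    solver: TransportSolver

    @classmethod
    def from_config(
        cls,
        config: Config,
        dt: float | None = None,
        resolution: float | None = None,
        time_order: int | None = None,
    ) -> "PerifusionSimulator":
        spec = domain_from_settings(config.domain)
        res = resolution if resolution is not None else config.solver.resolution
        mesh = build_mesh(spec, res)
        fs = config.flow
        mean_speed = (
            fs.mean_speed
            if fs.mean_speed is not None
            else mean_speed_from_flow_rate(fs.flow_rate, fs.column_diameter)
        )
        velocity = solve_flow(
            mesh,
            config.fluid,
            mean_speed,
            model=fs.model,
            capsule_flow=fs.capsule_flow,
            capsule_permeability=fs.capsule_permeability,
        )
        solver = TransportSolver(mesh, velocity, config, dt=dt, time_order=time_order)
        return cls(config=config, mesh=mesh, velocity=velocity, solver=solver)

    def run(self, protocol: StimulationProtocol | None = None, **kw) -> TransportResult:
        proto = protocol if protocol is not None else protocol_from_settings(
            self.config.protocol
        )
        return self.solver.run(proto, **kw)


def config_with(config: Config, **domain_updates) -> Config:
    """Copy of ``config`` with domain fields replaced (e.g. l_caps)."""
    cfg = copy.deepcopy(config)
    for key, val in domain_updates.items():
        if not hasattr(cfg.domain, key):
            raise AttributeError(f"unknown domain field {key!r}")
        setattr(cfg.domain, key, val)
    cfg.validate()
    return cfg


def config_fingerprint(
    config: Config,
    protocol: StimulationProtocol,
    dt: float | None = None,
    resolution: float | None = None,
) -> str:
    """Stable hash of everything a raw simulation depends on."""
    key = "|".join(
        [
            dump_config(config),
            repr([(s.duration, s.c_gluc, s.c_oxy) for s in protocol.segments]),
            repr((protocol.sampling_interval, protocol.smoothing_tau)),
            repr((dt, resolution)),
        ]
    )
    return hashlib.sha256(key.encode()).hexdigest()
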