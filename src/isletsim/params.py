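"""Model parameters: Hill kinetics constants, material and fluid properties.

Every constant of the insulin-secretion / nutrient-consumption model lives
here, with defaults equal to the published parameterization of the
local-concentration GSIR model (murine calibration, ``k_insL = 0.006 s⁻¹``).
Configurations are plain YAML; unspecified keys keep their defaults, unknown
keys are hard errors.

Units are strict SI internally (m, s, mol·m⁻³); config files may use unit
suffixes (``"150 um"``, ``"3 mM"``, ``"100 uL/min"``, ``"40 mmHg"``) which
are converted on load (see :mod:`isletsim.units`).
"""

from __future__ import annotations

import copy
import io
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .units import parse_quantity

#: Diameter of one islet equivalent (IEQ) [m].
IEQ_DIAMETER = 150e-6


class ConfigError(ValueError):
    """Invalid, unknown, or non-physical configuration input."""


# ---------------------------------------------------------------------------
# dataclasses


@dataclass
class HillParams:
    """Parameters of a Hill (generalized Michaelis–Menten) rate law.

    ``r_max`` is signed: negative for consumption, positive for secretion,
    and equal to 1 for dimensionless modulation fractions. ``c_half`` is the
    half-maximal concentration (same units as the argument of the rate law)
    and ``n`` the Hill slope.
    """

    r_max: float
    c_half: float
    n: float

    def validate(self) -> None:
        if not (self.c_half > 0):
            raise ConfigError(f"Hill c_half must be > 0, got {self.c_half}")
        if not (self.n > 0):
            raise ConfigError(f"Hill exponent n must be > 0, got {self.n}")


@dataclass
class Phase1Window:
    """Glucose window modulating first-phase secretion.

    The window is the product of a rising Hill fraction (half-max
    ``rise_c_half``, slope ``rise_n``) and a falling one
    (``1 - f_H(c; fall_c_half, fall_n)``), normalized so its maximum is 1
    (which falls near 5 mM with the defaults): first-phase release is most
    sensitive around normoglycemia and suppressed at very low or very high
    glucose.
    """

    rise_c_half: float = 3.0
    rise_n: float = 4.0
    fall_c_half: float = 16.0
    fall_n: float = 4.0

    def validate(self) -> None:
        for nm in ("rise_c_half", "rise_n", "fall_c_half", "fall_n"):
            if not (getattr(self, nm) > 0):
                raise ConfigError(f"phase1_window.{nm} must be > 0")


@dataclass
class KineticParams:
    """All cellular-level rate parameters of the GSIR model (SI units)."""

    #: Oxygen consumption, base Michaelis–Menten term (R_max < 0).
    oxy_consumption: HillParams = field(
        default_factory=lambda: HillParams(r_max=-0.034, c_half=1e-3, n=1.0)
    )
    #: Glucose-dependence of oxygen consumption (metabolic demand);
    #: r_max is the dimensionless amplitude a of phi = 1 + a * f_H(c_gluc).
    #: The default 1.0 doubles consumption from basal to saturating glucose,
    #: matching measured islet respiration increases under stimulation.
    oxy_metabolic_modulation: HillParams = field(
        default_factory=lambda: HillParams(r_max=1.0, c_half=7.0, n=2.5)
    )
    #: Glucose consumption (R_max < 0).
    gluc_consumption: HillParams = field(
        default_factory=lambda: HillParams(r_max=-0.028, c_half=1e-2, n=1.0)
    )
    #: Second-phase insulin secretion vs local glucose.
    ins_phase2: HillParams = field(
        default_factory=lambda: HillParams(r_max=3e-5, c_half=7.0, n=2.5)
    )
    #: First-phase insulin secretion vs glucose time-gradient dc/dt
    #: [mol·m⁻³·s⁻¹]; active only while the local glucose rises.
    ins_phase1: HillParams = field(
        default_factory=lambda: HillParams(r_max=21e-5, c_half=0.03, n=2.0)
    )
    #: Oxygen-dependence of insulin secretion (dimensionless fraction).
    ins_oxy_modulation: HillParams = field(
        default_factory=lambda: HillParams(r_max=1.0, c_half=3e-3, n=3.0)
    )
    #: First-order release rate from the local insulin compartment [s⁻¹]
    #: (0.006 murine; 0.003 in the original human calibration).
    k_insl: float = 0.006
    #: Critical oxygen concentration [mol·m⁻³]: consumption is ramped to
    #: zero below it (hypoxic shutdown).
    c_cr_oxy: float = 1e-4
    #: Consumption ramps linearly from full at ``ramp_factor * c_cr_oxy``
    #: to zero at ``c_cr_oxy`` (a smoothed cutoff for solver stability).
    cutoff_ramp_factor: float = 2.0
    phase1_window: Phase1Window = field(default_factory=Phase1Window)

    def validate(self) -> None:
        for nm in (
            "oxy_consumption",
            "oxy_metabolic_modulation",
            "gluc_consumption",
            "ins_phase2",
            "ins_phase1",
            "ins_oxy_modulation",
        ):
            getattr(self, nm).validate()
        if not (self.k_insl > 0):
            raise ConfigError(f"k_insl must be > 0, got {self.k_insl}")
        if not (self.c_cr_oxy >= 0):
            raise ConfigError("c_cr_oxy must be >= 0")
        if not (self.cutoff_ramp_factor > 1):
            raise ConfigError("cutoff_ramp_factor must be > 1")
        if self.oxy_consumption.r_max > 0 or self.gluc_consumption.r_max > 0:
            raise ConfigError("consumption r_max must be <= 0 (signed rates)")
        self.phase1_window.validate()


@dataclass
class MaterialProps:
    """Diffusion coefficients of one material [m²·s⁻¹]."""

    material: str
    d_oxy: float
    d_gluc: float
    d_ins: float

    def validate(self) -> None:
        if self.material not in ("water", "tissue", "alginate"):
            raise ConfigError(f"unknown material {self.material!r}")
        for nm in ("d_oxy", "d_gluc", "d_ins"):
            if not (getattr(self, nm) > 0):
                raise ConfigError(f"{self.material}.{nm} must be > 0")


def default_materials() -> dict:
    """Literature-consensus diffusivities for water, islet tissue, alginate."""
    return {
        "water": MaterialProps("water", d_oxy=3.0e-9, d_gluc=0.9e-9, d_ins=0.15e-9),
        "tissue": MaterialProps("tissue", d_oxy=2.0e-9, d_gluc=0.3e-9, d_ins=0.05e-9),
        "alginate": MaterialProps("alginate", d_oxy=2.5e-9, d_gluc=0.6e-9, d_ins=0.1e-9),
    }


@dataclass
class FluidProps:
    """Newtonian perifusion medium, defaults for water at 37 °C."""

    rho: float = 993.0  # [kg m^-3]
    eta: float = 6.9e-4  # [Pa s]

    def validate(self) -> None:
        if not (self.rho > 0 and self.eta > 0):
            raise ConfigError("fluid rho and eta must be > 0")


@dataclass
class DomainSettings:
    """Perifusion-chamber geometry knobs (the 2D channel cross-section)."""

    channel_length: float = 4.0e-3
    channel_height: float = 1.0e-3
    #: Capsule thickness; 0 means free (unencapsulated) islets.
    l_caps: float = 0.0
    #: Islet diameters, upstream to downstream.
    islet_diameters: tuple = (100e-6, 150e-6)
    #: Spacing between islet centers along the flow axis.
    islet_spacing: float = 1.0e-3
    #: Vertical stagger of islet centers about the centerline (+ then -).
    vertical_offset: float = 0.15e-3
    #: Minimum clearance between capsule surface and channel wall; the
    #: stagger shrinks automatically for thick capsules to preserve it.
    wall_margin: float = 25e-6
    #: Offset of the islet center from the capsule center (x-direction).
    capsule_offset: float = 0.0

    def validate(self) -> None:
        if self.channel_length <= 0 or self.channel_height <= 0:
            raise ConfigError("channel dimensions must be > 0")
        if self.l_caps < 0:
            raise ConfigError("l_caps must be >= 0")
        if any(d <= 0 for d in self.islet_diameters):
            raise ConfigError("islet diameters must be > 0")


@dataclass
class FlowSettings:
    """Inlet flow specification."""

    flow_rate: float = 100e-9 / 60.0  # 100 uL/min [m^3 s^-1]
    #: Perifusion column bore [m]; the multi-channel microcolumns used for
    #: dynamic GSIR have ~0.4 mL chambers of about 4 mm internal diameter,
    #: giving a superficial speed of ~0.13 mm/s at 100 uL/min.
    column_diameter: float = 4.0e-3
    #: If set, overrides the mean speed derived from flow_rate/column.
    mean_speed: Optional[float] = None
    #: "stokes" (default; creeping flow) or "navier-stokes".
    model: str = "stokes"
    #: Allow seepage through the capsule (Brinkman term) instead of
    #: treating it as impermeable. Exploratory; off by default.
    capsule_flow: bool = False
    #: Brinkman permeability of the capsule [m^2] when capsule_flow is on.
    capsule_permeability: float = 1e-14

    def validate(self) -> None:
        if self.flow_rate < 0:
            raise ConfigError("flow_rate must be >= 0")
        if self.column_diameter <= 0:
            raise ConfigError("column_diameter must be > 0")
        if self.model not in ("stokes", "navier-stokes"):
            raise ConfigError(f"unknown flow model {self.model!r}")


@dataclass
class SolverSettings:
    """Space/time discretization controls."""

    resolution: float = 10e-6  # target square-cell size [m]
    dt: float = 1.0  # time step [s]
    time_order: int = 2  # 1 = backward Euler, 2 = BDF2
    picard_tol: float = 1e-9
    picard_maxiter: int = 200

    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.resolution <= 0:
            raise ConfigError("resolution must be > 0")
        if self.time_order not in (1, 2):
            raise ConfigError("time_order must be 1 or 2")
        if self.picard_tol <= 0 or self.picard_maxiter < 1:
            raise ConfigError("invalid nonlinear-iteration settings")


@dataclass
class ObservableSettings:
    """2D→3D scaling and display units."""

    ieq: float = 50.0  # IEQ count the outflow is scaled to
    #: Insulin unit conversion, nmol per insulin Unit (display only).
    nmol_per_unit: float = 6.0

    def validate(self) -> None:
        if self.ieq <= 0:
            raise ConfigError("ieq must be > 0")
        if self.nmol_per_unit <= 0:
            raise ConfigError("nmol_per_unit must be > 0")


@dataclass
class ProtocolSettings:
    """Inlet stimulation protocol selection."""

    preset: str = "gsir"
    oxygen_mode: str = "normoxic"  # or "tissue"
    sampling_interval: float = 60.0  # [s]
    #: First-order inlet dispersion time constant [s], modeling the dead
    #: volume between the switching valve and the chamber; 0 = sharp steps.
    smoothing_tau: float = 60.0
    #: Explicit segment list [(duration, c_gluc, c_oxy)] overrides the preset.
    segments: Optional[list] = None

    def validate(self) -> None:
        if self.oxygen_mode not in ("normoxic", "tissue"):
            raise ConfigError(f"unknown oxygen_mode {self.oxygen_mode!r}")
        if self.sampling_interval <= 0:
            raise ConfigError("sampling_interval must be > 0")
        if self.smoothing_tau < 0:
            raise ConfigError("smoothing_tau must be >= 0")


@dataclass
class Config:
    """Full resolved parameter bundle."""

    kinetics: KineticParams = field(default_factory=KineticParams)
    materials: dict = field(default_factory=default_materials)
    fluid: FluidProps = field(default_factory=FluidProps)
    domain: DomainSettings = field(default_factory=DomainSettings)
    flow: FlowSettings = field(default_factory=FlowSettings)
    solver: SolverSettings = field(default_factory=SolverSettings)
    observables: ObservableSettings = field(default_factory=ObservableSettings)
    protocol: ProtocolSettings = field(default_factory=ProtocolSettings)

    def validate(self) -> None:
        self.kinetics.validate()
        for m in self.materials.values():
            m.validate()
        self.fluid.validate()
        self.domain.validate()
        self.flow.validate()
        self.solver.validate()
        self.observables.validate()
        self.protocol.validate()


# ---------------------------------------------------------------------------
# config file parsing

# field -> physical dimension, for unit-suffix parsing
_DIMENSIONS = {
    "r_max": "rate",
    "c_half": None,  # concentration for most laws, rate for ins_phase1
    "n": None,
    "k_insl": "inverse_time",
    "c_cr_oxy": "concentration",
    "cutoff_ramp_factor": None,
    "rise_c_half": "concentration",
    "fall_c_half": "concentration",
    "rise_n": None,
    "fall_n": None,
    "d_oxy": "diffusivity",
    "d_gluc": "diffusivity",
    "d_ins": "diffusivity",
    "rho": "density",
    "eta": "viscosity",
    "channel_length": "length",
    "channel_height": "length",
    "l_caps": "length",
    "islet_spacing": "length",
    "vertical_offset": "length",
    "wall_margin": "length",
    "capsule_offset": "length",
    "flow_rate": "flow",
    "column_diameter": "length",
    "mean_speed": "speed",
    "capsule_permeability": None,
    "resolution": "length",
    "dt": "time",
    "sampling_interval": "time",
    "smoothing_tau": "time",
}


def _coerce(section: str, key: str, value, target):
    """Parse one scalar config entry with unit handling."""
    if value is None or isinstance(value, (bool, list, tuple)):
        if key in ("islet_diameters",) and isinstance(value, (list, tuple)):
            return tuple(parse_quantity(v, "length") for v in value)
        return value
    dim = _DIMENSIONS.get(key)
    if key == "c_half":
        dim = "rate" if section == "ins_phase1" else "concentration"
    if dim is None:
        # dimensionless / non-quantity field
        if isinstance(value, str):
            try:
                return float(value)
            except ValueError:
                return value
        return value
    return parse_quantity(value, dim)


def _apply_overrides(obj, overrides: dict, path: str) -> None:
    """Recursively apply a nested override dict onto a dataclass tree."""
    for key, value in overrides.items():
        if not hasattr(obj, key):
            raise ConfigError(f"unknown configuration key {path}{key!r}")
        current = getattr(obj, key)
        if isinstance(
            current, (HillParams, Phase1Window, MaterialProps, FluidProps)
        ) or (hasattr(current, "__dataclass_fields__") and isinstance(value, dict)):
            if not isinstance(value, dict):
                raise ConfigError(f"section {path}{key} must be a mapping")
            _apply_overrides(current, value, f"{path}{key}.")
        elif isinstance(current, dict):
            if not isinstance(value, dict):
                raise ConfigError(f"section {path}{key} must be a mapping")
            for sub, subval in value.items():
                if sub not in current:
                    raise ConfigError(
                        f"unknown configuration key {path}{key}.{sub!r}"
                    )
                _apply_overrides(current[sub], subval, f"{path}{key}.{sub}.")
        else:
            leaf = key.rsplit(".", 1)[-1]
            section = path.rstrip(".").rsplit(".", 1)[-1] if path else ""
            if isinstance(value, (list, tuple)) and leaf == "islet_diameters":
                value = tuple(parse_quantity(v, "length") for v in value)
            elif isinstance(value, (list, tuple)) and leaf == "segments":
                pass
            else:
                value = _coerce(section, leaf, value, current)
            setattr(obj, key, value)


def load_config(path=None) -> Config:
    """Build the full parameter bundle.

    With ``path=None`` every value takes its default. Otherwise the YAML
    file is parsed, unknown keys raise :class:`ConfigError` naming the key,
    and non-physical values raise on validation.
    """
    cfg = Config()
    if path is not None:
        if isinstance(path, dict):
            data = path
        else:
            with open(path, "r", encoding="utf-8") as fh:
                data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("top-level config must be a mapping")
        _apply_overrides(cfg, data, "")
    cfg.validate()
    return cfg


def config_to_dict(cfg: Config) -> dict:
    """Plain-SI nested dict representation (round-trips through YAML)."""
    d = asdict(cfg)
    d["domain"]["islet_diameters"] = list(cfg.domain.islet_diameters)
    return d


def dump_config(cfg: Config, stream=None) -> str:
    """Serialize a config to YAML (all values SI)."""
    out = io.StringIO()
    yaml.safe_dump(config_to_dict(cfg), out, sort_keys=True)
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def config_from_dict(data: dict) -> Config:
    """Inverse of :func:`config_to_dict`."""
    return load_config(copy.deepcopy(data))


# ---------------------------------------------------------------------------
# islet-equivalent geometry


def iequiv_volume(n_ieq: float) -> float:
    """Volume [m³] of ``n_ieq`` islet equivalents.

    One IEQ is the volume of a 150 μm diameter sphere,
    (π/6)·d³ ≈ 1.767 × 10⁻¹² m³.
    """
    if n_ieq < 0:
        raise ValueError(f"IEQ count must be >= 0, got {n_ieq}")
    return n_ieq * (math.pi / 6.0) * IEQ_DIAMETER**3


def sphere_equivalent_diameter(volume: float) -> float:
    """Diameter [m] of the sphere with the given volume (> 0)."""
    if not (volume > 0):
        raise ValueError(f"volume must be > 0, got {volume}")
    return (6.0 * volume / math.pi) ** (1.0 / 3.0)
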