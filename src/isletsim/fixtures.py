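"""Synthetic measured-trace generation for calibration testing.

Runs the simulator at known ground-truth parameters and adds seeded
Gaussian noise with standard deviation proportional to the trace maximum
(ELISA replicate error is roughly proportional to signal near the peak).
The resulting CSV is schema-identical to real perifusion data, enabling
parameter-recovery tests without wet-lab traces.
"""

from __future__ import annotations

import numpy as np

from .observables import PerifusionTrace, simulate_trace
from .params import Config
from .protocol import StimulationProtocol
from .simulate import config_with


def make_synthetic_trace(
    config: Config,
    true_l_caps: float,
    true_ieq: float,
    true_k_insl: float,
    noise_sd_fraction: float = 0.02,
    seed: int = 0,
    path=None,
    protocol: StimulationProtocol | None = None,
    dt: float | None = None,
    resolution: float | None = None,
) -> PerifusionTrace:
    """Simulate at ground truth, add proportional Gaussian noise, write CSV.

    Noise sd = ``noise_sd_fraction`` × max(trace); independent per sample,
    generated from ``numpy.random.default_rng(seed)``; noisy values are
    clipped at zero (concentrations cannot be negative). With zero noise
    the output is bitwise identical to the simulation for any seed.
    """
    if noise_sd_fraction < 0:
        raise ValueError("noise_sd_fraction must be >= 0")
    cfg = config_with(config, l_caps=float(true_l_caps))
    cfg.kinetics.k_insl = float(true_k_insl)
    cfg.observables.ieq = float(true_ieq)
    cfg.validate()
    trace = simulate_trace(cfg, protocol, dt=dt, resolution=resolution)
    noisy = trace.insulin_out.copy()
    if noise_sd_fraction > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sd_fraction * float(np.max(noisy))
        noisy = np.clip(noisy + rng.normal(0.0, sd, size=noisy.shape), 0.0, None)
    out = PerifusionTrace(
        times=trace.times.copy(),
        insulin_out=noisy,
        gluc_inlet=trace.gluc_inlet.copy(),
        metadata={
            **trace.metadata,
            "synthetic": True,
            "true_l_caps": float(true_l_caps),
            "true_ieq": float(true_ieq),
            "true_k_insl": float(true_k_insl),
            "noise_sd_fraction": float(noise_sd_fraction),
            "seed": int(seed),
        },
    )
    out.validate()
    if path is not None:
        out.to_csv(path)
    return out
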