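# isletsim

Multiphysics simulation of dynamic glucose-stimulated insulin release
(GSIR) from pancreatic islets in a perifusion chamber — free islets or
islets microencapsulated in alginate — with calibration utilities for
measured outflow traces.

**Who it is for.** Researchers studying islet transplantation and
bioartificial-pancreas encapsulation who need a quantitative, local
concentration-based account of how capsule thickness and oxygen
availability shape the insulin secretion time-profile, and a way to fit
that model to perifusion measurements.

## The model

Glucose, oxygen and released insulin are transported through a 2D
perifusion chamber by convection and diffusion,

∂c/∂t + ∇·(−D∇c) = R − **u**·∇c,

with the steady velocity field **u** from the incompressible
momentum/continuity equations (no-slip islets, capsules and walls;
parabolic inlet; Re ≪ 10). Every cellular rate R is a Hill law,
R = R_max·cⁿ/(cⁿ + C_Hfⁿ), of the *local* concentrations inside islet
tissue: Michaelis–Menten oxygen and glucose consumption (oxygen demand
rising with glucose and shut off below a critical pO₂), and biphasic
insulin secretion — a second-phase term driven by local glucose
(C_Hf = 7 mM, n = 2.5) plus a first-phase term driven by the glucose
*rise rate* ∂c_gluc/∂t (C_Hf = 0.03 mM/s, n = 2, active only while
glucose rises), both throttled by local oxygen (C_Hf = 3 μM, n = 3).
Secreted insulin enters an intra-islet pool released with first-order
rate k_insL (0.006 s⁻¹ murine, 0.003 s⁻¹ human):

dc_insL/dt = R_ins − k_insL (c_insL − c_ins).

The 2D outflow flux is converted to measured concentrations by scaling
the modeled islet cross-sections to a target islet-equivalent (IEQ)
count. See `docs/methods.md` for the full parameter table, numerical
scheme (finite volumes + BDF2 with exactly-solved implicit kinetics) and
design choices.

## Worked example

```python
from isletsim import load_config, simulate_trace, phase_metrics
from isletsim.protocol import protocol_from_settings

cfg = load_config()                              # all published defaults
trace = simulate_trace(cfg, resolution=25e-6)    # coarse demo mesh
m = phase_metrics(trace, protocol_from_settings(cfg.protocol))
print(f"basal   {trace.insulin_uU_per_mL()[0]:8.1f} uU/mL")
print(f"peak    {m.peak/6e-9:8.1f} uU/mL at {m.time_to_peak/60:.0f} min after the G11 step")
print(f"plateau {m.plateau/6e-9:8.1f} uU/mL")
print(f"delay   {m.delay/60:8.1f} min to half-rise")
```

prints

```
basal       26.5 uU/mL
peak       625.3 uU/mL at 3 min after the G11 step
plateau    205.5 uU/mL
delay        2.0 min to half-rise
```

i.e. the classic biphasic response to the 3 → 11 mM glucose step: a low
basal outflow, a sharp first-phase spike about 3 minutes after the step
(the islets sense the local glucose *rise*), and a sustained second-phase
plateau about a third of the peak while glucose stays high. Repeating the
run with `cfg = config_with(cfg, l_caps=150e-6)` (islets inside 150 μm
alginate capsules) gives a visibly delayed and blunted first phase — the
central encapsulation effect the package quantifies.

The same pipeline is scriptable from the shell:

```bash
isletsim simulate --lcaps 150um --ieq 50 --out trace.csv
isletsim sweep --lcaps 0,50um,100um,150um,200um,250um,300um,350um --out sweep.csv
isletsim make-fixture --lcaps 150um --ieq 50 --noise 0.02 --seed 1 --out fixture.csv
isletsim fit --data fixture.csv --out fit.json
isletsim dump-defaults > config.yaml
```

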