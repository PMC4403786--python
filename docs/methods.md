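# Methods

`isletsim` simulates dynamic glucose-stimulated insulin release (GSIR) from
pancreatic islets — free or embedded in alginate microcapsules — during a
perifusion experiment, and calibrates the model against measured outflow
traces. This note documents the model, its numerical treatment, the
parameters that matter, and the limits of what the test suite demonstrates.

## Model

### Transport

Four concentrations are tracked: glucose, oxygen, released insulin
(`c_gluc`, `c_oxy`, `c_ins`; all transported) and a non-diffusing
intra-islet insulin pool (`c_insL`). Each transported species obeys the
convection–diffusion–reaction equation in nonconservative form for an
incompressible medium,

    ∂c/∂t + ∇·(−D∇c) = R − u·∇c,

on a 2D cross-section of the perifusion chamber: a rectangular channel
(default 4 × 1 mm) containing two circular islet sections (d = 100 and
150 μm, staggered ±0.15 mm about the axis, 1 mm apart) with optional
concentric capsule annuli of thickness `l_caps`. Diffusivities are
material-wise constants (m²/s ×10⁻⁹):

| species  | medium | islet tissue | alginate |
|----------|-------:|-------------:|---------:|
| oxygen   | 3.0    | 2.0          | 2.5      |
| glucose  | 0.9    | 0.3          | 0.6      |
| insulin  | 0.15   | 0.05         | 0.10     |

Boundary conditions: Dirichlet inlet at the protocol values, purely
convective outlet, zero-flux walls.

### Flow

The steady velocity field solves incompressible momentum balance +
continuity with no-slip walls, a fully developed parabolic inlet profile
and a zero-normal-stress outlet. At perifusion conditions Re ≈ 0.1–3, so
the transient and (by default) inertial terms are dropped and the flow is
solved once per geometry (Stokes); a Picard-iterated Navier–Stokes variant
exists and agrees with Stokes to < 0.5 % (checked in the suite). Islet and
capsule interiors are impermeable (velocity unknowns eliminated); an
exploratory mode instead assigns the capsule a finite Brinkman
permeability so medium can seep through it. That mode is off by default
and not used by any quantitative check.

The mean inlet speed comes from the experimental flow rate, 100 μL/min,
through the perifusion-column bore. The bore is a design choice (no value
is printed with the experiment): multi-channel perifusion microcolumns
have ≈ 0.4 mL chambers of about 4 mm internal diameter, so the default is
4.0 mm, giving U ≈ 0.133 mm/s. This matters: at 16× faster speeds (a 1 mm
bore) the oxygen boundary layers around the islets become so thin that
tissue-level inlet oxygen (0.060 mol/m³) causes almost no secretion loss,
contradicting the hypoxia behavior the model is meant to capture.

### Kinetics

All cellular rates are Hill laws `R_max·cⁿ/(cⁿ + C_Hfⁿ)` of *local*
concentrations, active only in islet tissue:

* **Oxygen consumption** — Michaelis–Menten in oxygen (R_max = −0.034
  mol·m⁻³ s⁻¹, C_Hf = 1 μM), multiplied by a metabolic-demand factor
  φ_o,g(c_gluc) = 1 + a·f_H(c_gluc; 7 mM, 2.5) and ramped linearly to zero
  between 2·C_cr and the critical oxygen concentration C_cr (default
  0.1 μM; the ramp replaces a hard cutoff for solver stability). The
  amplitude `a` is not printed in the source material; the default a = 1
  doubles consumption from basal to saturating glucose, consistent with
  measured islet respiration increases under stimulation, and is required
  to reproduce the published low-oxygen secretion losses (with a = 0.5 the
  islets stay essentially normoxic at 0.060 mol/m³ inlet).
* **Glucose consumption** — Michaelis–Menten (R_max = −0.028 mol·m⁻³ s⁻¹,
  C_Hf = 10 μM); negligible feedback on the results.
* **Insulin secretion** — sum of a second-phase term driven by local
  glucose (R_max = 3×10⁻⁵ mol·m⁻³ s⁻¹, C_Hf = 7 mM, n = 2.5) and a
  first-phase term driven by the local glucose *rise rate*
  (R_max = 21×10⁻⁵, C_Hf = 0.03 mM/s, n = 2), active only while glucose
  increases, gated by a glucose window w(c_gluc) (product of a rising Hill
  at 3 mM, n = 4 and a falling Hill at 16 mM, n = 4, normalized to peak 1;
  the maximum sits near 5–7 mM so first-phase release is suppressed at
  very low and very high glucose). The sum is throttled by the oxygen
  fraction f_H(c_oxy; 3 μM, 3).
* **Local insulin pool** — insulin first enters an intra-islet compartment
  and is released with first-order rate k_insL:
  dc_insL/dt = R_ins − k_insL(c_insL − c_ins). Default k_insL = 0.006 s⁻¹
  (murine calibration); 0.003 s⁻¹ reproduces the slower human profile.
  Halving k_insL lowers and delays the first-phase outflow peak.

### Inlet protocol and dispersion

The reference protocol is G3 (5 min) → G11 (20 min) → G3 (15 min) with
minute sampling; inlet oxygen is constant at 0.200 mol/m³ ("normoxic",
≈140 mmHg) or 0.060 mol/m³ ("tissue", ≈40 mmHg). The KCl-depolarization
segment of the wet-lab protocol has no secretion mechanism in this model
and is replaced by continued G3. Protocol lookup is exact
(piecewise-constant); a first-order inlet-dispersion filter with time
constant τ = 60 s (default) is applied inside the solver, representing the
~100–300 μL of valve-to-chamber dead volume at 100 μL/min. This filter is
load-bearing for the first-phase morphology: with perfectly sharp steps
the local glucose rise lasts only ~10–20 s, the first-phase bolus stays
below the overshoot threshold (R_max,ph1·Δt ≲ (R_ph2,ss − R_basal)/k_insL)
and the outflow rises monotonically with no distinct peak. The biphasic
shape is robust for τ in 30–120 s (peak/plateau 2.6–3.0, peak 2–3 min
after the step).

## Numerics

* **Space** — uniform square-cell finite volumes (default h = 10 μm),
  harmonic-mean diffusive conductances at material interfaces, first-order
  upwind advection (cell Péclet numbers reach ~10, so upwinding provides
  the necessary stabilization; the associated numerical dispersion is
  small against the 60 s sampling). Circles are rasterized
  area-preservingly: boundary cells are ranked by coverage and the labeled
  count chosen to match the analytic area (error ≤ half a cell, ~0.3 % at
  default resolution).
* **Flow** — staggered (MAC) grid sharing the transport cells; the
  velocity/pressure saddle-point system is solved directly (sparse LU with
  residual-checked iterative refinement). Discrete continuity holds to
  machine precision, which the transport discretization inherits.
* **Time** — BDF2 with fixed dt = 1 s (backward Euler selectable), history
  duplicated at restarts. Reactions are solved *implicitly and exactly* at
  each step: because the nonlinear sources act only on islet cells, the
  implicit system is closed by a dense Schur-type reduction onto those
  cells (the constant transport operator is factorized once; its inverse
  columns over islet cells are precomputed). The reduced few-hundred-
  dimensional nonlinear system is solved per step by damped Newton with a
  diagonal (pointwise) reaction Jacobian. This avoids operator-splitting
  bias — important because oxygen consumption would traverse the hypoxic
  cutoff within a single 1 s substep.
* **Initial state** — a steady pre-solve at the first segment's inlet
  values stands in for the experimental 45–60 min stabilization wash.
* **Degenerate inputs** — negative concentrations from discretization are
  clamped to zero and counted; a flat trace yields phase metrics flagged
  `reliable=False` instead of an exception; zero-variance measured traces
  make r² undefined and raise.
* **Tolerances** — reduced Newton: 10⁻⁹ relative (accepting 10³× looser
  after 200 iterations with a debug log); linear solves are direct.

## Observables and calibration

The 2D solver yields insulin outflow per unit depth; multiplying by an
effective depth h_eff = V_IEQ(target)/Σ(islet areas) and dividing by the
flow rate converts to outflow concentration scaled to a chosen islet
equivalent (IEQ) count (default 50, as in the experiments). One IEQ is the
volume of a 150 μm sphere, 1.767×10⁻¹² m³ (the geometric value; a printed
value of 1.77×10⁻¹³ m³ elsewhere appears to carry a power-of-ten slip).
Insulin display units use 1 U = 6 nmol (configurable).

Phase metrics: basal = pre-step mean; first-phase peak = maximum within
10 min of the step-up; plateau = mean over the last 5 min of the high
segment; delay = first time the outflow exceeds basal + (peak − basal)/2.

Calibration is a deterministic grid search over capsule thickness
(default {0, 50, …, 350 μm}) and optionally k_insL, with the IEQ scale
obtained in closed form per candidate (the trace is linear in it); fit
quality is SSE and r² about the measured mean. Simulations are memoized on
a full-configuration fingerprint, so sweeps and fits share runs. The
low-oxygen comparison reports the ratio of *time-integrated* secretion
over the whole protocol (tissue / normoxic inlet oxygen); the published
"% of normal rate" phrasing is not time-resolved, and the integral is the
reproducible summary.

## Synthetic data

`make_synthetic_trace` runs the simulator at known ground truth and adds
independent Gaussian noise with sd proportional to the trace maximum
(ELISA replicate error grows with signal), clipped at zero, from a single
seeded generator. It emulates sampling cadence, amplitude scale, and noise
level of real perifusion data but none of its systematic artifacts —
baseline drift, carry-over between fractions, plate effects, or the
KCl-normalization rescaling done upstream of real data files. Passing
recovery tests therefore demonstrate identifiability of (l_caps, IEQ,
k_insL) under well-behaved noise, not robustness to real-data systematics.

## Problem sizes used by the checks

Default runs use the 4 × 1 mm chamber at h = 10 μm (40 000 cells,
~256 islet cells) and dt = 1 s over the 40 min protocol. The test suite
exercises full protocols at h = 25 μm and convergence/benchmark cases on
smaller single-islet chambers (h = 5–25 μm), chosen so the whole suite
runs in tens of minutes on one core while staying in the
asymptotic-convergence regime demonstrated by the dt- and mesh-halving
checks (< 1 % and < 2 % trace changes respectively).

## Known limitations

* 2D plane geometry; the 2D→3D conversion assumes the whole islet volume
  experiences the cross-section's microenvironment.
* Homogeneous islets: no α/β-cell structure, no granule-pool dynamics, no
  KCl-depolarization pathway.
* The capsule is a uniform diffusive shell; alginate-concentration effects
  enter only through its diffusivities, and the capsule-seepage (Brinkman)
  mode is untested against data.
* The φ_o,g amplitude, the first-phase glucose window shape, the critical
  oxygen concentration, the column bore and the inlet-dispersion constant
  are reconstructed or estimated, not published values; all are
  configurable, and the headline hypoxia predictions depend mainly on the
  first, fourth and the inlet oxygen levels.
* The free-islet low-oxygen ratio computed at defaults (≈80 %) sits a few
  points above the 70–75 % reference range targeted by the acceptance
  checks; the encapsulated ratio (≈51 %) reproduces the ≈50 % reference.
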