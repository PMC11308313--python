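# Methods

`infusim` predicts the transient dose rates that reach a patient when
several syringe pumps share one vascular access point, and attributes
the deviation from the prescribed rates to three mechanisms: push-out
of the dead volume, laminar (Poiseuille) smearing of composition
fronts, and charging/discharging of mechanical compliance. This note
documents the model, its assumptions, the defaults, and what the
shipped scenarios do and do not demonstrate.

## Hydraulic network model

Each pump branch is lumped into an ideal volumetric flow source
`Q_set,i(t)` (the pump drive, a piecewise-constant schedule) feeding a
single compliance `C_i` (mL/mbar — dominated by the air-filled rubber
plunger tip of the syringe, plus any other compressible elements of the
branch) behind the branch-line resistance `R_i`. All branches meet at a
zero-volume junction that drains through the catheter resistance
`R_cath` to a constant venous back-pressure `P_ven`:

    C_i dP_i/dt = Q_set,i(t) − (P_i − P_j)/R_i            (branch i)
    Σ_i (P_i − P_j)/R_i = (P_j − P_ven)/R_cath            (junction)

The junction pressure `P_j` is algebraic, so branch inflows sum to the
catheter outflow identically — conservation holds to linear-solver
precision at every step (tested to <1e−10 mL/h). A branch with
`C_i = 0` is rigid: it delivers its set flow exactly and enters the
junction balance as a fixed source. Branch flows may be negative: a
pressure surge from one pump can press mixed fluid back up another
pump's line. That is the counter-intuitive regime of thin catheters:
with `R ∝ d⁻⁴`, a 1 Fr lumen (~0.3 mm bore) has >1500× the resistance
of a 7 Fr one (~1.6 mm), so re-establishing a higher total flow
requires a large junction-pressure excursion, and every syringe
plunger stores `C·ΔP` of fluid on the way.

Resistances come from the Hagen–Poiseuille law for developed laminar
flow, `R = 128 µL/(π d⁴)`, converted once (in `units.py`) to the
clinical unit system used throughout the public interface: mL, hours,
mbar, mm, mPa·s. Reynolds numbers at clinical flows (mL/h through
sub-millimetre lumens) are ≪ 1, so the laminar assumption is safe.

**Integrator.** Backward Euler on the linear pressure ODE, solving the
small (N ≤ pumps) coupled system each step with the junction eliminated
analytically. The scheme is unconditionally stable, which matters
because a small compliance (µL/mbar) against a large catheter
resistance gives time constants `τ = C(R_branch + R_cath)` of seconds
while runs span hours. It is first-order accurate: the single-branch
step response matches `1 − exp(−t/τ)` to 1.4e−4 relative at
`dt = τ/2000` (tested). Networks are initialized at the steady state of
the t = 0 set flows, matching a running infusion; a cold start can be
requested by passing an explicit initial pressure state.

## Transport model

The shared mixed segment (manifold dead volume + catheter lumen) is a
**shift register of volume slices**, each carrying per-drug volume
fractions. Per step, the junction mixture is pushed onto the proximal
end and an equal volume is emitted distally. Push-then-emit plug
advection is exact for any step volume (the emitted composition is the
average over the step's throughput and cumulative volumes telescope),
so no sub-stepping is needed; the slice volume (default: shared
volume/200, floor 1e−5 mL) instead sets the default time step via
`Q_max·dt ≤ slice volume`, which resolves a push-out front to half a
percent of the dead volume. Adjacent slices with identical composition
coalesce, keeping steady phases O(1) slices.

**Backflow.** When a branch flow is negative, the junction mixture
entering that line is stored in a per-branch LIFO buffer (plug
reversal — laminar flow at these Reynolds numbers is kinematically
reversible) and returns ahead of fresh stock when the branch recovers.
Buffered volume beyond the line's internal volume is tolerated with a
warning (physically it displaces fluid toward the syringe). Net
aspiration at the access point (negative catheter outflow) is outside
the supported regime and raises an error rather than silently
mis-transporting.

**Laminar washout kernel.** A parabolic velocity profile with no
radial mixing turns a sharp front into the classical washout curve:
with mean transit `τ = V/Q`, the effluent contains no new fluid before
`τ/2` (the centerline moves at exactly twice the mean velocity) and a
fraction `1 − (τ/2t)²` afterwards. The kernel is applied to the plug
effluent in **cumulative-volume coordinates**, which generalizes the
curve to time-varying flow under the quasi-static assumption that the
parabolic profile rescales instantly with the flow. In volume
coordinates the lag density relative to the plug front is
`k(u) = V²/(2(u+V)³)` on `u ∈ [−V/2, ∞)` with survival
`S(u) = V²/(4(u+V)²)`; its mean is zero, so plug and laminar transport
share the mean residence volume `V` (mean residence time `V/Q`). The
implementation treats the plug series as piecewise-constant in volume
and convolves it exactly against `S`, extending the series by its
first/last composition outside the simulated span. It conserves a
constant composition to machine precision, reproduces the closed-form
breakthrough curve exactly for an on-grid step, and agrees with a
brute-force radial-annuli integration (4×10⁶ annuli, equal-area
sampling) to better than 1e−6. The kernel is applied once over the
shared segment; branch lines upstream of the junction use plug
transport (their content is uniform stock except for the backflow
buffer). Molecular diffusion and Taylor–Aris dispersion are neglected,
which overstates the sharpness of the washout tail for small molecules
on long timescales.

## Error decomposition

The dosing error of drug d is `delivered_d(t) − set_d(t)`, where
`delivered_d = (effluent fraction of d) × catheter outflow`. The
three-way split runs three nested simulations on one grid:

  (a) rigid syringes (C = 0), plug transport      → push-out alone
  (b) rigid syringes, laminar kernel              → + Poiseuille
  (c) full model                                  → + compliance

with `push_out = dev(a)`, `poiseuille = dev(b) − dev(a)`,
`compliance = dev(c) − dev(b)`. The components sum to the full-model
deviation exactly by construction. The split depends on the ablation
order (transport first, compliance last); this order isolates the
purely kinematic push-out — which has the closed form
`V_shared (f_old − f_new)` per drug for an instantaneous flow change —
as the base layer. Integrated errors are reported as signed mL plus
separate overdose/underdose magnitudes (trapezoidal quadrature).

## Defaults and their rationale

| parameter | default | why |
|---|---|---|
| viscosity | 1.0 mPa·s | water-like infusates; per-branch override |
| syringe compliance (50 mL) | 2e−3 mL/mbar | order-of-magnitude estimate for an air-cushioned rubber plunger; manufacturers do not publish it. Only the compliance-dominant (1 Fr) vs compliance-negligible (7 Fr) contrast is load-bearing |
| 7 Fr catheter | 16 cm, 1.6 mm ID | typical adult CVC; ID is an engineering estimate |
| 1 Fr catheter | 30 cm, 0.3 mm ID | typical neonatal PICC; ID is an estimate |
| manifold dead volume | 0.5 mL | 3-gang manifold + connector, estimate |
| branch tubing | 1 m, 1.0 mm ID | standard extension line |
| venous pressure | 0 mbar gauge | patient-side dynamics not modelled |
| scenario flows (cases 2–4) | A: 10→20 or 20→10, B: 1 mL/h | an "A much faster than B" regime; illustrative and configurable |
| grid (cases 2–4) | dt 2.5e−4 h, 1 h span | dt ≪ the 1 Fr time constant (~31 s) and one step moves ≈ one slice |

Every default is overridable via the YAML catalog and scenario files.

## What the scenarios and fixtures do and do not show

The built-in cases and the randomized fixture generator exercise
piecewise-constant schedules on 1–4 pumps with physically valid
parameters; rigid fixtures verify the push-out closed form across 50
seeds within one slice volume. They emulate set-flow changes on an
established infusion. They do **not** emulate: pump start-up and
syringe-exchange pressure transients, hydrostatic height changes,
pump stepper ripple, drug incompatibility chemistry, non-Newtonian
infusates, or patient-side venous pressure variation. Passing tests
therefore validate the hydraulic/transport model under its stated
assumptions, not the full clinical variability of infusion therapy.

## Numerical choices and degenerate inputs

- Backward Euler samples set flows at the end of each step, so an
  event at t\* first acts on the step landing at t\*; schedule events
  should lie on grid points (the built-ins do).
- Zero-resistance branches are floored at 1e−9 mbar·h/mL to avoid a
  singular junction balance; an all-infinite-resistance network raises
  a singular-network error.
- A zero-volume laminar segment degenerates to the identity kernel; a
  zero-volume tube has first arrival 0.
- Problem sizes: the shipped cases use 4 000 steps (cases 2–4; three
  nested ablations each) and 1 500 steps (case 1); the full test suite
  runs in well under a minute on one CPU.

## Known limitations

- The compliance is lumped per branch; distributed line compliance and
  tubing visco-elasticity are not represented.
- The laminar kernel assumes quasi-static profile adjustment; during
  very fast flow reversals this underestimates dispersion, and net
  aspiration is rejected rather than modelled.
- Dose is reported as mL/h of stock solution; mass rates require the
  user to supply concentrations.
- Catalog inner diameters and compliances are estimates, not
  manufacturer data; quantitative predictions for a specific setup
  require measured component parameters.
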