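# infusim

Transient dosing-error prediction for multi-pump intravenous infusion.

When several syringe pumps share one vascular access point, changing
the set flow on *one* pump transiently changes what *every* pump
delivers to the patient. Clinicians — and intuition — routinely get
these transients wrong, and for critical medication at neonatal flow
rates the errors matter. `infusim` is a bedside-style prediction tool:
given the physical parameters of the setup (syringe compliance, line
and catheter geometry, manifold dead volume) and the pump schedules, it
predicts each drug's actual dose rate entering the patient over time
and splits the deviation into its three mechanisms:

1. **Push-out** — the dead volume between mixing point and catheter tip
   still holds the *old* mixing ratio but is expelled at the *new*
   total flow rate; per drug the excess volume is
   `V_dead (f_old − f_new)`.
2. **Poiseuille flow profile** — laminar flow in a cylindrical tube has
   a parabolic velocity profile (centerline = 2× mean velocity) and no
   radial mixing, so a front arrives after *half* the mean transit time
   `V/Q` and washes out with a `1 − (τ/2t)²` tail.
3. **Mechanical compliance** — compressible syringe plungers store
   `C·ΔP` of fluid while pressures re-equilibrate. With a thin catheter
   (`R ∝ d⁻⁴`: a 1 Fr lumen resists >1500× more than a 7 Fr one) the
   pressure surge after a flow increase even presses mixed fluid
   *backwards* up the other pump's line, producing a biphasic
   overdose-then-underdose of the critical drug.

The model is a lumped compliance–resistance network,
`C_i dP_i/dt = Q_set,i − (P_i − P_j)/R_i` with an algebraic junction
balance, integrated by backward Euler, feeding a shift-register
slice-chain model of the catheter contents with a laminar washout
kernel. See [docs/methods.md](docs/methods.md) for the full account.

## Worked example

Four built-in cases cover the canonical teaching situations. Case 4 is
the counter-intuitive one: pump A steps 10 → 20 mL/h against pump B's
1 mL/h of critical medication through a 1 Fr neonatal catheter.

```bash
$ infusim run-case 4 --outdir out/case4
wrote out/case4/summary.json
  drug A: signed error -0.1084 mL (overdose 0.0438, underdose 0.1522), biphasic=True
  drug B: signed error -0.0615 mL (overdose 0.0072, underdose 0.0687), biphasic=True
```

Drug B is first **overdosed** (0.0072 mL — the old, B-richer dead
volume pushed out at the new total flow) and then **underdosed**
(0.0687 mL — B's syringe plunger compresses and mixed fluid is pressed
back up B's line while the junction pressure climbs by
`R_cath·ΔQ ≈ 42 mbar`). The compliance mechanism contributes more
integrated error (0.084 mL) than the push-out (0.023 mL), which is why
panels of clinicians reliably mispredict this case. On a 7 Fr catheter
(case 2) the same flow step gives a pure push-out overdose and the
compliance contribution is negligible.

Case 1 is the syringe-exchange question — a 3 mL line at 6 mL/h:

```bash
$ infusim run-case 1 --outdir out/case1
  ...
  first arrival: 15.0 min (mean transit 30.0 min)
```

The first bit of new medicine arrives after 15 minutes, not the 30 the
mean transit suggests, because the laminar centerline runs twice as
fast as the average.

Each run writes tidy CSV time series (`flows.csv`, `doses.csv`,
`decomposition.csv`), a `summary.json` with integrated
overdose/underdose per drug, and a parameter-echo `run.log`. Custom
setups are YAML scenario files (`infusim run my_scenario.yaml`); the
component catalog (`infusim list-components`) ships documented defaults
for the common syringes, manifolds and catheters, all overridable.

The same machinery is available as a library:

```python
from infusim import builtin_case, decompose

sc = builtin_case(4)
deco = decompose(sc.network, sc.grid)
print(deco.integrated["drug B"]["compliance_abs_ml"])   # 0.0841...
print(deco.integrated["drug B"]["push_out_abs_ml"])     # 0.0226...
```

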