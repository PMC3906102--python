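# glycosuria

Modeling renal glucose handling after an intravenous glucose load:
does the kidney excrete glucose through a hard concentration threshold,
or through progressive, saturable reabsorption along the tubule?

This package implements and compares the two descriptions on
IVGTT-style experiments (0.33 g/kg IV glucose bolus, ~15 plasma glucose
samples in the first hour, urine collected every 5 minutes through a
catheter):

- a **two-compartment glycemia model** providing the continuous plasma
  glucose input `C(t)`:

      dQ1/dt = -(k_x1 + k_21) Q1 + k_12 Q2 + k_g,     C = Q1 / V_p
      dQ2/dt =  k_21 Q1 - k_12 Q2

  with the pre-bolus equilibrium fixing `k_12 = k_21 G_b V_p / Q_20`
  and `k_g = k_x1 G_b V_p` (solved in closed form; a linear interpolant
  of measured glycemias is the model-free alternative);

- the **progressive tubular reabsorption (PTR) model**: filtered glucose
  (at rate `rho C(t)`, `rho` = GFR) advects along an idealized aggregate
  tubule of length `L = 1.5 cm` at velocity `phi`, discretized into
  `N = 10` serial segments, while a saturable Hill-type transporter
  removes up to `T^max = k_T rho` mmol/min in total at rate
  `(T^max/N) c^nu / (G_half^nu + c^nu)` per segment; the cross-section
  tapers exponentially (180 L/day ultrafiltrate in, 2 L/day urine out),
  concentrating what remains; the tubule outflow passes through a
  first-order "bladder" delay compartment (`alpha2 = U_flow / V_B`)
  whose output `alpha2 B(t)` is the measured urinary loss;

- the **renal threshold hypothesis (RTH) model** as the comparison:
  spill rate `S rho max(C - T, 0)` into the same bladder compartment,
  with slope `S = 1` under the strict hypothesis or estimated in
  `(0, 10]`.

Per-subject estimation is ordinary least squares via multi-start
Nelder-Mead on transformed parameters, exposed as scikit-learn style
regressors (`TwoCompartmentGlycemia`, `PTRRegressor`, `RTHRegressor`,
each with `fit(t, y)` / `predict(t)` and fitted `*_` attributes).
Because no raw time courses from the original five-subject cohort were
ever deposited, a first-class synthetic-data generator reproduces the
experiment design, with the published per-subject estimates packaged in
`glycosuria.tables` as the quantitative anchor.

The scientific payoff of the tubular description, reproduced here as
testable signatures: nonzero urinary glucose loss at glycemias below any
threshold, and a counter-clockwise hysteresis loop when urinary loss is
plotted against concurrent glycemia (glycosuria lags glycemia by the
tubular transit time plus the bladder washout).

## Worked example

```python
import glycosuria as g

sub = g.reference_subject()                      # known ground truth
ds = g.generate_dataset(sub, model="ptr",
                        noise=g.NoiseModel(glycemia_cv=0.02,
                                           urine_cv=0.05, seed=1))
curve = g.solve_two_compartment(sub.glycemia, t_end=60.0)
est = g.PTRRegressor(curve, rho=sub.gfr_l_min, u_flow=sub.u_flow,
                     baseline=sub.glycemia.G_b, n_restarts=1, seed=0)
est.fit(ds.urine_loss.times, ds.urine_loss.values)
print(f"fitted T^max = {est.tmax_:.3f} mmol/min, TinTub = {est.tintub_:.2f} min")
print(f"OLS loss = {est.loss_:.3g} (mmol/min)^2")
```

prints

```
fitted T^max = 0.616 mmol/min, TinTub = 1.50 min
OLS loss = 3.87e-10 (mmol/min)^2
```

i.e. from a 5%-noise synthetic experiment the maximal tubular transport
rate is recovered to 0.2% (truth 0.615 mmol/min = 110.8 mg/min), while
the transit time (truth 1.67 min) is only loosely pinned — the
identifiability trade-offs are discussed in `docs/methods.md`.

Cohort bookkeeping mirrors the published summary conventions:

```python
k12, kg = g.derive_equilibrium_rates(0.040, 0.159, 6.39, 9.95, 44.31)
# k12 = 0.2281 1/min  (prints as 0.23 in the reference table)
s = g.summarize_cohort([0.123, 0.159, 0.200, 0.050, 0.200])
# mean=0.146 SD=0.063 CV%=19.17  (standard-error-based CV%)
```

A `glycosuria` command-line tool wraps the library: `synth` (generate
subjects + experiments), `simulate` (forward runs from a scenario
config), `fit` (per-subject OLS fits), `summarize` (cohort tables) and
`phase` (phase-space trajectories with the signed hysteresis loop
area).  All file I/O is plain CSV (`time_min,value`) and flat JSON.

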