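# Methods

## The model

`bispkpd` models depth of anesthesia in three coupled stages.

**Pharmacokinetics.** Drug disposition follows a mammillary
three-compartment model: a central compartment (plasma, volume V1) that
receives all input and clears drug at rate Cl1, exchanging with a rapid
(V2, Cl2) and a slow (V3, Cl3) peripheral compartment. In concentration
form,

    dC1/dt = -(k10 + k12 + k13) C1 + (k21 V2/V1) C2 + (k31 V3/V1) C3 + u(t)/V1
    dC2/dt = (k12 V1/V2) C1 - k21 C2
    dC3/dt = (k13 V1/V3) C1 - k31 C3

with micro constants k10 = Cl1/V1, k12 = Cl2/V1, k13 = Cl3/V1,
k21 = Cl2/V2, k31 = Cl3/V3. The parameters are predicted from patient
covariates: V1 = 4.27 L and V3 = 238 L are fixed, V2 and Cl2 decrease
linearly with age from their values at the reference age of 53 years
(18.9 L and 1.29 L/min), Cl3 = 0.836 L/min, and Cl1 is corrected linearly
for weight, lean body mass and height around the 77 kg / 59 kg / 177 cm
reference (1.89 L/min there). Lean body mass uses the sex-specific James
approximation, `1.07 w - 148 w²/h²` for women and `1.10 w - 128 w²/h²` for
men (weight in kg, height in cm). Covariates that drive any volume or
clearance non-positive raise an error rather than being clamped; synthetic
cohorts are generated inside the valid envelope.

**Effect site.** The hypothetical effect site equilibrates with plasma by
first-order dynamics, dCe/dt = ke0 (C1 - Ce). ke0 defaults to 0.456 min⁻¹,
the standard literature value used with this covariate set; it is
configurable (`EffectLinkConfig`) and zero is allowed for closed-system
checks.

**Pharmacodynamics.** BIS follows the sigmoid Emax (Hill) curve

    BIS = E0 - Emax · Ce^γ / (EC50^γ + Ce^γ)

with E0 the awake baseline (0–100], Emax the maximal depression
(0 < Emax ≤ E0), EC50 the effect-site concentration at half-maximal
depression (µg/mL) and γ > 0 the slope. The curve is strictly decreasing
in Ce and bounded in [E0 − Emax, E0].

## Units

Volumes in liters, clearances in L/min, time in minutes, concentrations in
µg/mL, doses in mg, rates in mg/min. BIS is dimensionless (0–100). The
default output grid spacing is one second (1/60 min), the cadence of a BIS
monitor.

## Numerical integration

The PK system is linear and its input is piecewise constant (constant-rate
segments plus instantaneous boluses), so the trajectory is advanced with
the exact matrix exponential of the 5×5 augmented system, one step per
interval between output points and input events. Matrix exponentials are
cached per distinct (step, rate) pair, so uniform grids cost a handful of
`expm` calls plus one 5×5 mat-vec per step. Accuracy is therefore
independent of grid spacing and of the stiffness of the rate constants
(k31 ≈ 0.0035 min⁻¹ against k10 ≈ 0.44 min⁻¹ at reference covariates);
the constant-infusion steady state C1 = u/Cl1 = C2 = C3 = Ce is met to
machine precision. Boluses are applied as instantaneous jumps of dose/V1
on C1; the recorded trace is right-continuous at bolus instants, and bolus
or segment events that fall between grid points are honored as internal
breakpoints.

## PD identification by particle swarm

Per patient, the Hill parameters θ = (E0, Emax, EC50, γ) are fitted by
minimizing RMSE between the observed BIS trace and the Hill curve applied
to the simulated Ce(t). RMSE has the same minimizer as the squared loss
and is reported directly as a fit metric.

The swarm follows the canonical update: velocity = inertia term +
cognitive pull toward the particle's personal best + social pull toward
the global best, each pull weighted by a fresh uniform(0,1) draw per
particle and dimension; position then moves by the velocity. Defaults:
30 particles, 200 iterations, inertia ω = 0.729, learning factors
C1 = C2 = 1.494 (the constriction-equivalent setting), velocity clamped to
half the bound span per dimension, uniform random initialization inside
the box, zero initial velocities. Positions leaving the box are clipped
and the violating velocity component zeroed. Termination is a fixed
iteration budget; the global-best value is recorded per iteration and is
non-increasing by construction. A seeded run is bitwise reproducible.

Default search bounds: E0 ∈ [80, 100], Emax ∈ [40, 100], EC50 ∈ [0.5, 10]
µg/mL, γ ∈ [0.5, 6]. `identify_pd` supports multiple restarts (independent
swarms with seeds spawned from the config seed; best solution kept) and a
warm start that seeds one particle at a previous fit. For the
parameter-recovery studies we run 5 restarts of 400–600 iterations so the
optimizer, not its budget, limits accuracy; the pipeline default
(3 restarts × 200 iterations) is sufficient for fit-quality reporting.

Degenerate identifiability: if Ce ≡ 0 the objective depends on E0 alone;
the remaining parameters are returned as the swarm left them, except that
Emax is clipped to E0 (where the objective is flat the clip is free, and
the returned parameter set is always a valid Hill curve). If the observed
trace is constant, R² and MAPE are undefined; the fit report carries NaN
there rather than raising.

## Gradient-boosted regression trees

The BIS regressor is an additive model built by forward stagewise
boosting under squared loss: f0(x) = 0, and stage m fits a regression tree
to the residuals y − f_{m−1}(x) (the negative gradient of the squared
loss), giving f_m = f_{m−1} + ν·T_m. The shrinkage ν defaults to 0.1;
ν = 1 reproduces the plain recursion, in which case a single-stage model
is identical to one regression tree (tested against exactly that oracle).
f0 = 0 rather than the target mean is deliberate — the first tree absorbs
the mean — and configurable only by wrapping.

Trees are grown greedily by variance reduction. Split candidates are
midpoints between consecutive distinct sorted values of each feature; the
best candidate is the one minimizing the children's summed squared error,
with exact ties resolved to the lowest feature index and then the lowest
threshold, so fitting is deterministic given row order. Zero-gain splits
on impure nodes are allowed (an interaction such as XOR has no first-level
gain but needs the split); pure nodes, depth limits and `min_samples_leaf`
stop recursion. Leaf values are mean residuals. No row or column
subsampling and no loss other than squared error are implemented.

The spectral extractor cuts a sampled signal into non-overlapping epochs
and reduces each periodogram to band powers (delta 0.5–4, theta 4–8,
alpha 8–13, beta 13–30, gamma 30–45 Hz), total power, 95% spectral edge
frequency, and normalized spectral entropy (0 by convention for a silent
epoch).

## Synthetic cohorts

The generator portrays the study population the package is exercised on:
elderly surgical patients with ages uniform on 65–85 years, weights 55–85
kg, heights 150–180 cm, balanced sex. Dosing mirrors clinical induction
and maintenance: a 1.0–1.5 mg/kg induction bolus at t = 0 followed by a
constant maintenance infusion of 4–8 mg/kg/h over a 40 min window. True
Hill parameters are drawn from a sub-box of the identification bounds
(E0 85–95, Emax 50–85, EC50 1.5–4 µg/mL, γ 1.5–3), so truth is always
interior to the search region and Emax ≤ E0 holds by construction. Each
generated patient's noiseless trace is checked to dip below BIS 60 — the
surgical band — which the dosing ranges guarantee; this keeps EC50 and γ
identifiable.

Observed BIS adds i.i.d. Gaussian monitor noise (default sd 3 BIS units)
and clips to [0, 100]. EEG-feature surrogates are monotone transforms of
Ce(t) (identity, saturating Ce/(1+Ce), decaying exp(−Ce/2)) with
proportional Gaussian perturbation, plus pure-noise distractor columns.

What the generator does **not** emulate: real EEG microstructure and
artifacts, burst suppression, inter-drug interactions (opioids, volatile
agents), time-varying ke0, autocorrelated monitor noise, or model
misspecification — the data-generating PKPD model is exactly the model
being fitted. Passing recovery tests therefore demonstrate the
correctness of the estimation machinery, not clinical validity on real
recordings.

## Experiment sizes and reporting

The bundled experiment identifies a 10-patient cohort on a 40 min, 1 s
grid (2 401 points per trace) at noise sd 3; recovery studies use 5
noiseless and 20 noisy patients. The report CSV
(`patient_id,r2_percent,rmse`) gives R² in percent to two decimals; the
summary counts patients above the 80% and 90% fit levels. Every reported
number is recomputable from the on-disk trace CSVs with the metrics module
alone. With noiseless observations all per-patient R² exceed 99%; at
monitor-noise level mean R² typically falls in the high-70s to high-80s
percent because the plateau phase of a maintenance trace leaves the noise
variance a substantial fraction of the total signal variance.

## Metrics

R² = 1 − SSE/SST (raw, unclipped; negative for fits worse than the mean
predictor, and undefined — an error — when the observations are
constant), RMSE = √(mean squared residual), MAPE = mean(|obs − pred|/|obs|)
× 100 with a hard error on zero observations rather than a silent epsilon.

## Known limitations

- The covariate model is a single published adult parameter set; no
  alternative covariate models are provided.
- The effect-site constant ke0 is fixed by configuration, not identified;
  adding it to the search vector is possible by re-parameterizing the
  objective but is not wired in.
- PSO with a fixed budget can under-resolve weakly identifiable
  parameters (flat valleys in γ/EC50 when a trace saturates quickly);
  restarts mitigate but do not eliminate this.
- Only squared-loss boosting is implemented; no early stopping — capacity
  is controlled by depth, leaf size, shrinkage and stage count.
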