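# Methods

## Scope and state variables

`mousemetab` models the energy metabolism of adult male C57BL/6 mice on
the time scale of days to months. The state is body composition
(FM, FFM) in grams; body weight is their sum. Within-day dynamics
(fed/fasted transitions, circadian structure) are deliberately outside
the model's resolution: all intakes and expenditures are daily rates.
Units are fixed internally to grams, days, and kilocalories; inputs in
other units are rejected rather than converted.

## Energy balance and partitioning

The master equation is energy conservation,
`rho_FM dFM/dt + rho_FFM dFFM/dt = EI − EE`, with energy densities of
*tissue change* rho_FM = 9.4 kcal/g and rho_FFM = 1.8 kcal/g. The FFM
density is far below the ~5.65 kcal/g of pure protein because an FFM
change is mostly protein plus its associated intracellular water
(roughly 1.8/5.65 ≈ 0.32 g protein per gram of FFM change); the water
carries no energy.

Lean change is tied to fat change by the empirical, time-invariant
partition function `alpha(FM) = c + d·exp(k·FM)` with c = 0.1,
d = 1.89e-4, k = 0.45 g⁻¹, measured on adult C57BL/6 males. Because the
underlying measurements cover adult mice only, evaluation is restricted
to FM in [0.1, 60] g; outside that range the library raises instead of
extrapolating (the exponential grows steeply and extrapolation would be
meaningless). Path integrals of alpha use adaptive quadrature at 1e-10
absolute tolerance — alpha feeds the master ODE and must not dominate
solver error; the analytic antiderivative serves as an independent check
in the test suite.

## The expenditure model and its closed-form resolution

`EE = K + gamma_FFM·FFM + gamma_FM·FM + lambda·BW + beta·ΔEI +
eta_FFM·dFFM/dt + eta_FM·dFM/dt`. Parameters (defaults in parentheses):

- `K` (2.1 kcal/d): basal thermogenesis for individually housed mice at
  22 °C; a calibrated constant, expected to change with housing
  temperature.
- `gamma_FFM` (0.15), `gamma_FM` (0.03 kcal/g/d): mass-specific
  metabolic rates obtained by quarter-power (Kleiber) rescaling of human
  values (22 and 3.6 kcal/kg/d). The reference masses are not uniquely
  determined by the sources; the package exposes them and defaults to
  70 kg and 30 g, which reproduces 0.15 exactly at two decimals and 0.03
  at one significant figure (the exact rescaled value is ≈0.025).
- `lambda` (diet-dependent, see below): physical-activity cost per gram
  of body weight.
- `beta` (0.4): diet-induced thermogenesis as a fraction of the intake
  change ΔEI relative to the chow baseline. ΔEI may be negative, in
  which case DIT reduces EE.
- `eta_FM` (0.18), `eta_FFM` (0.23 kcal/g): biochemical deposition
  costs. They are applied with the sign of the tissue rate exactly as
  the expenditure equation is written — mobilization reduces EE. The
  model does not distinguish synthesis from mobilization efficiency.

EE and the tissue rates determine each other (the deposition terms
contain the rates, the balance equation contains EE). Substituting
`dFFM/dt = alpha·dFM/dt` into both and eliminating EE gives the unique
simultaneous solution

    dFM/dt = (EI − M) / (rho_FM + A·rho_FFM + eta_FM + A·eta_FFM),
    M      = K + gamma_FFM·FFM + gamma_FM·FM + lambda·BW + beta·ΔEI,
    EE     = EI − (rho_FM + A·rho_FFM)·dFM/dt,

which satisfies the balance identity algebraically. A fixed-point
iteration between the two original equations is kept in the test suite
as an independent oracle.

The baseline intake for ΔEI defaults to the mean intake over the leading
run of intervals on the starting diet; protocols that begin on a
high-energy diet should supply the chow reference explicitly.

## Physical-activity dynamics

lambda is a deterministic function of diet history: `lambda_C0`
(0.22 kcal/g/d) on baseline chow; an immediate drop to `lambda_H` (0.13;
0.16 for Ensure-supplemented groups) on switching to a high-energy diet;
and on each return to chow an immediate jump to `lambda_C1` (0.27)
relaxing exponentially to `lambda_C2` (0.19) with time constant
tau = 14 d. The impulse/step construction is realized as exact
right-continuous piecewise evaluation, not as a stiff ODE. Protocols
with repeated episodes generalize naturally: an ordered event list where
every high-fat entry sets the plateau and every chow return restarts the
relaxation — the minimal generalization consistent with the two-switch
dynamics.

## Fuel selection

With glycogen stores tiny relative to daily carbohydrate intake, the
system is treated as in average carbohydrate balance, and de novo
lipogenesis and gluconeogenesis are absorbed into *net* oxidation rates:
`NetCarbOx = I_C`, `NetProtOx = I_P − rho_FFM·dFFM/dt` (FFM change is
proportional to body protein, and the energy of an FFM change is its
protein energy), and `NetFatOx = EE − NetCarbOx − NetProtOx`, which by
the balance identity equals `I_F − rho_FM·dFM/dt`. Closure to EE is
exact by construction.

RQ is the O2-flux-weighted mean of the macronutrient stoichiometric
quotients (carbohydrate 1.00, fat 0.71, protein 0.835) with energy
equivalents of oxygen 5.05, 4.69, and 4.66 kcal per liter O2. The food
quotient FQ applies the same weighting to the diet's energy fractions;
this form yields FQ = 0.92 for chow (24/12/64 protein/fat/carbohydrate)
and 0.80 for the high-fat diet (14/59/27) at two decimals. (A plain
energy-fraction-weighted mean of the quotients does *not* reproduce both
values; the O2 weighting is the standard indirect-calorimetry form and
does.) In energy and macronutrient balance RQ = FQ. For the first two
days after a diet change the carbohydrate-balance approximation is least
reliable, and the trajectory flags RQ as approximate there.

## Numerical integration

The forcings are piecewise with known breakpoints, so the simulator
integrates segment-wise with adaptive RK45 (rtol 1e-8, atol 1e-10),
restarting at every diet switch and intake breakpoint; no event
root-finding is needed. Leaving the supported FM domain terminates the
run with an error naming the time. An auxiliary state accumulates
∫(EI − EE)dt along the solution; comparing it with rho·ΔMass at the
output times gives a cumulative conservation residual, typically
~1e-13 kcal over 200-day protocols.

Likelihood evaluations during MCMC use a numba-compiled fixed-step RK4
over the same segment structure with dt = 1 d. The dynamics relax on a
~30 d time scale, so the fixed step's error (~2e-5 g against the
adaptive solution, cross-checked in the tests) is negligible relative to
observation noise (~0.4–0.5 g).

## Calibration

Free parameters: {K, lambda_C0, lambda_C1, lambda_C2, lambda_H}, flat
priors on (0, ∞). The likelihood is Gaussian in the observed group-mean
BW and FM at their empirical standard errors (the package deliberately
uses the SEs supplied with the data — the same uncertainties a reader
would see as error bars). Intake measurement error is propagated by
treating each per-interval intake as a nuisance parameter with a
Gaussian prior centered on the measurement at the group's intake SE,
sampled jointly with the free parameters; posterior EE bands therefore
reflect intake uncertainty.

The sampler is random-walk Metropolis, acceptance probability
min(1, r). Default chain length 100,000 with a 30,000-iteration burn-in
and retention of every 5th subsequent draw. During burn-in (only) two
adaptations run and are then frozen, preserving detailed balance for the
retained draws: a Robbins–Monro global step scale targeting ~0.25
acceptance, and periodic re-estimation of the proposal covariance from
the burn-in history. The covariance adaptation is essential, not
cosmetic: K and the lambdas are strongly correlated through the
energy-balance constraint (EE only ever sees K + lambda·BW), and a
diagonal proposal mixes too slowly along that ridge to converge at
practical chain lengths — pilot runs showed Geweke |z| up to 30 with
diagonal proposals versus |z| < 3 with the adapted covariance.

Convergence is assessed by the Geweke z-score per parameter (mean of the
first 10% vs the last 50% of the chain, standardized by
spectral-density-estimated segment variances; the spectral estimate uses
a Bartlett lag window of width √n). Implemented in-package and
Monte-Carlo calibrated in the tests (iid chains flagged ≲1% of the time,
drifting chains flagged reliably). Credible bands for predicted EE are
pointwise 2.5/97.5 percentiles across retained draws.

Joint versus per-group fitting: the default fits all supplied groups
jointly with shared parameters, which matches the physiological claim
that K and the activity coefficients are properties of the housing
conditions and diets, not of the group; per-group fits are available by
passing a single observation set. Parameters a protocol never exercises
(e.g. lambda_H for a chow-only group) are unidentified under flat priors
and should not be fitted from such a group alone.

## The synthetic-data generator

`synth.generate_study` simulates ground truth with the package's own
simulator and adds independent Gaussian noise at the configured standard
errors to the weekly BW/FM observations and the per-interval intakes.
Default protocols mirror the five validation-style arms (chow control;
high fat for 4, 7, or 20 weeks then chow; and a high-fat/chow/high-fat/
chow double episode) with intake SEs of 0.42, 0.48, 0.50, 0.53, and
0.55 kcal/d. The intake truths encode the stereotypical behavior of
these experiments: chow baseline 12.0 kcal/d; first-week high-fat
hyperphagia 15.0 settling to 13.5 kcal/d (producing ~41 g BW at 7 weeks
and ~47 g at 20 weeks, typical diet-induced-obesity trajectories); a
deep voluntary intake dip to 6.5 kcal/d in the first week after an early
switch back to chow, but only to 9.5 kcal/d after the late (week-20)
switch, when the heavier animals restrict less. BW/FM group-mean SEs
default to 0.5 and 0.4 g, typical for groups of 6–12 animals. Initial
composition defaults to FM 4 g, FFM 23 g (a 27 g three-month-old male).

What the generator does not emulate: per-animal variation (litter, cage
effects), autocorrelated measurement error, digestibility differences
between diets, non-Gaussian intake error, and appetite feedback (intake
is an input, not a response). Passing recovery tests therefore
demonstrates internal consistency of the estimation machinery under the
stated noise model, not robustness to these real-data features.

A three-arm recovery design (`synth.recovery_protocols`: chow control,
chow→high-fat, chow→high-fat→chow over 98 d) is provided for closed-loop
calibration experiments; it was designed so every free parameter is
exercised, including a 42-day (3 tau) post-switch tail for the
relaxation parameters. The test suite runs 20 seeded fits at reduced
chain length (20,000 iterations, 5,000 burn-in) and checks <10% bias of
posterior medians and ≥90% coverage of the 95% intervals.

## Degenerate inputs and tie-breaks

Schedules are right-continuous; an output time equal to a switch time
reports post-switch forcing. Two consecutive switches to the same diet
are rejected, as are non-increasing breakpoints. Zero total oxidation
makes RQ undefined and raises. Negative net oxidation rates are allowed
(net synthesis); a net lipogenic mix can push RQ above 1, and the
documented sanity range is 0.5 < RQ < 1.3. Intake between measurement
breakpoints is piecewise-constant by default; a monotone-cubic (PCHIP)
interpolation is available by flag for smoothly varying intake records,
but the fast calibration path requires the piecewise-constant form.

## Known limitations

- Calibrated for individually housed mice at 22 °C without running
  wheels; K (and plausibly beta and gamma_FM) are temperature-dependent
  and would need refitting for other environments.
- Ensure-supplemented (mixed liquid/solid) arms require a user-composed
  effective diet composition; no mixing rule is built in.
- The model is deterministic group-mean dynamics; it does not simulate
  per-animal stochasticity.
- RQ is least reliable during the first days after a diet switch (the
  carbohydrate-balance assumption), and the trajectory flags this
  window.
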