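# Methods

## The model family

`exminmod` implements a family of six exercise extensions of the Bergman
minimal model for people with type 1 diabetes. The state is plasma glucose
`G` (mmol/L) and remote insulin action `X` (1/min); plasma insulin
`Ins(t)` (mU/L) and oxygen uptake `VO2(t)` are measured forcings, not
modelled states (open-loop identification: exercise is an exogenous input,
and the pump's closed-loop dosing is treated as part of the measured
insulin signal):

    dX/dt = -p2 X + p3 (1 + inc2(t)) Ins(t)
    dG/dt = -p1 (1 + inc1(t)) G - X G + p1 Gp0

`inc1` raises glucose effectiveness (insulin-independent uptake), `inc2`
raises insulin sensitivity (insulin-dependent uptake). Both are zero
outside the exercise window — the family does not model post-exercise
carry-over, early or late. Inside the window the six variants combine
fixed gains `e1`, `e2` with intensity `pvo2(t) = (VO2 - VO2rest)/(VO2max -
VO2rest)` (clipped to [0, 1]) and normalised duration `te(t) = (t -
t_start)/60 min`:

| variant | inc1      | inc2              |
|--------:|-----------|-------------------|
| 1       | e1        | e2                |
| 2       | 0         | e1                |
| 3       | e1        | 0                 |
| 4       | e1·pvo2   | e2·pvo2           |
| 5       | e1·te     | e2·te             |
| 6       | e1·pvo2   | e2·(pvo2 + te)    |

Initial conditions are the pre-exercise equilibrium at basal insulin:
`X(0) = (p3/p2) Insb` and `G(0) = Gp0 p1 / (p1 + X(0))` — the unique
reading under which the right-hand side vanishes (verified symbolically
and asserted by tests for every variant). `Insb = 0` is accepted as the
zero-insulin limit, where `G(0) = Gp0`.

Parameter magnitudes that matter (defaults used throughout the package,
taken from the selected variant's reported cross-subject medians):
`Gp0 = 32.1` mmol/L, `p1 = 0.0021` /min, `p2 = 0.031` /min,
`p3 = 1.6e-5` /min² per mU/L, `e1 = 1.60`, `e2 = 0.778` (gains are stored
as dimensionless fractions; presentation layers may format them as
percentages). VO2 is carried in mL/kg/min with rest 3.5 and max 40 by
default; only the normalised `pvo2` enters the dynamics, so the absolute
units cancel.

## Numerics

Two integration paths solve the same equations:

* **`simulate`** (general purpose): scipy LSODA with rtol 1e-8 / atol
  1e-10, restarted at every insulin knot, VO2 knot and exercise-window
  edge. Window membership is decided per segment (from its midpoint) so no
  solver step straddles the inc-term switch. `G` is floored at 1e-6 mmol/L
  inside the right-hand side to keep the bilinear `X·G` term well behaved
  on degenerate parameter draws.
* **likelihood kernel** (MCMC): a numba-compiled fixed-step RK4 with steps
  ≤ 0.5 min between the same breakpoints. Because a dataset's integration
  grid never changes across parameter draws, all forcing values at the RK4
  stage times are tabulated once per dataset; each likelihood evaluation
  is then pure arithmetic (~5 µs). The system's time constants (1/p1 ≈ 500
  min, 1/p2 ≈ 30 min) put the 0.5-min step deep inside RK4's accuracy
  region; tests pin the two paths together to < 1e-6 relative for all six
  variants.

`counterfactual_pair` integrates the no-exercise run over the identical
segment structure, so paired trajectories are bitwise equal before the
window and the exercise comparison is clean to ~1e-9 mmol/L (an absolute
tolerance absorbing solver round-off, orders of magnitude below the
physical effect).

## Bayesian estimation

The measurement model is Gaussian with a 2% coefficient of variation,
`y_i ~ N(Ghat(t_i), 0.02·Ghat(t_i))`; the scale is proportional to the
*prediction*, not the observation, so the likelihood remains a proper
density in the parameters. Solver failures and non-positive predictions
map to log-likelihood −inf (rejected proposals).

Priors are independent log-normals. The defaults — geometric means
`Gp0 = 35`, `p1 = 0.0025`, `p2 = 0.03`, `p3 = 1.5e-5`, `e1 = e2 = 1.0`,
log-sd 0.5 for the rate constants and 1.0 for the gains — centre the rate
constants on literature-plausible values and are deliberately weak. They
are configurable, not canonical: the short pre-exercise window carries
little information about `p1` and `p2` on its own, so these priors do real
work and any downstream use should treat them as modelling choices.
`Insb` is fixed per subject to the mean of the pre-exercise insulin
observations rather than estimated. Variants 2 and 3 estimate a single
gain (`e1`); the others estimate both.

Sampling is adaptive random-walk Metropolis on the log-parameters:
proposal covariance estimated from the chain history (Haario-style, with a
Robbins–Monro global scale targeting ~30% acceptance), adapted only during
burn-in and frozen afterwards to preserve detailed balance in the kept
draws. Defaults are 100,000 iterations keeping the last 20,000; a fast
mode (10,000 / keep 2,000) exists for smoke runs and cohort-scale
screening. Fixed seeds give bit-identical chains. Acceptance below 1%
attaches a diagnostic warning rather than failing.

## DIC and the plug-in parameterisation

Model comparison uses the deviance information criterion,
`pD = Dbar − D(theta_bar)`, `DIC = Dbar + pD`, pooled across independently
fitted subjects by summation (deviance is additive over independent
likelihoods). Both DIC identities hold exactly by construction on every
result.

The one genuinely open design choice was *where* to take the plug-in mean
`theta_bar`. The data pin the initial glucose
`G0 = Gp0 p1/(p1 + (p3/p2) Insb)` to a fraction of a percent while leaving
wide, prior-dominated ridges in the raw parameters; the posterior is a
thin curved shell, and coordinate means taken on the natural scale (and
even geometric means of the raw parameters) land far off it, producing
large spurious negative pD that turn model rankings into noise. The
plug-in is therefore the coordinate mean in the **initial-condition
parameterisation** — geometric means of (G0, p1, p2, p3, e1, e2), with
Gp0 backed out — the coordinate system in which the posterior is
near-Gaussian. There pD is stable, positive and of the order of the
number of identified parameter combinations, and pooled DIC tracks
goodness of fit. pD can still come out slightly negative on short chains;
that is logged, never asserted away.

A variant is additionally flagged when the cross-subject median posterior
CV of any free parameter exceeds 100% (the identifiability screen applied
alongside the DIC ranking); the aggregation across subjects (median) is a
package choice. Ties in pooled DIC break to the lower variant id.

## Synthetic cohorts: what they emulate and what they do not

No clinical data ship with the package, so `synthetic_cohort` generates
study-design-faithful datasets: closed-loop control from minute 930
(15:30), a 60-min session at 60% VO2max from minute 1080 (18:00), 30-min
recovery, samples every 30 min before / 10 min during / 15 min after
exercise (14 points), and 2%-CV multiplicative glucose noise (non-positive
draws are redrawn and logged). Subject parameters are log-normal around
the reference medians with spreads resembling the reported interquartile
ranges; cohorts are reproducible under a fixed seed. The default VO2 trace
is a constant-intensity plateau with ≤ 2-min linear on/off ramps (a
discontinuous forcing would not occur in measured breath-by-breath data).
The default insulin forcing is a basal plateau with a piecewise-linear
decline to 60% of basal during exercise and recovery afterwards — a
clearly labelled stand-in for unavailable closed-loop dosing, motivated by
the fact that insulin infusion is mostly suspended during exercise.

Features of real data deliberately *not* emulated: glucagon dynamics,
meal-driven pre-exercise excursions in the fitting datasets, VO2
measurement noise and slow drift, post-exercise physiology, and
between-visit variability. Consequently, passing tests demonstrate the
pipeline's internal correctness and calibration, not fidelity to any real
cohort.

One identifiability consequence deserves emphasis. Under a
constant-intensity session, `pvo2(t)` is constant, so variant 6's
`inc2 = e2(pvo2 + te)` differs from variant 4's `e2'·pvo2` only by a
smooth ramp that the 30-min remote-insulin filter and the free
(Gp0, p1, p3) absorb almost exactly. `scripts/acceptance.py` computes
this as the best-fit weighted SS of rival variants on noiseless
variant-6 data: variant 4's gap is of order 0.03 per 14-point subject —
two orders of magnitude below the χ² noise floor at 2% CV — while
variant 5's is of order 5 and separable. Variants 1, 4 and 6 are
therefore an observational equivalence class in this design, and the
model-selection recovery experiment can identify the class but not the
member: the corresponding test is expected to fail and is left failing
as an honest record of this limit. Variants 2, 3 and 5 do separate, and
data generated without an insulin-sensitivity increase (`e2 = 0`)
reliably rank variant 3 above variant 2. Discrimination *within* the
{1, 4, 6} class on real data plausibly rests on all six variants being
misspecified against real physiology — a situation within-family
synthetic data cannot reproduce.

## Calibration experiments

* **Parameter recovery** draws 20 virtual subjects from the *fitting
  priors* (simulation-based calibration — the design under which credible
  intervals have exactly their nominal coverage if the sampler is
  correct), generates 14-point datasets at 2% noise, and checks that 90%
  credible intervals cover the truth in ≥ 80% of parameter × subject
  cells. Full-length chains are used; the short fast-mode chains
  understate posterior spread and undercover.
* **DIC oracle**: on the conjugate normal-mean toy with exact posterior
  draws, pD reproduces the closed form n·τ²/(nτ² + σ²) within Monte-Carlo
  error.
* **Prior recovery**: with a flat likelihood the sampler's marginals
  reproduce the prior (KS distance < 0.05).

## Protocol engine

The two in-silico validation studies run the selected variant per virtual
subject with two standard submodels standing in for unavailable
supplementary equations, implemented behind a small kinetics interface so
alternatives can be slotted in:

* **Subcutaneous insulin**: two-compartment absorption chain (time-to-peak
  55 min) with first-order plasma clearance (ke = 0.138 /min, Vi = 8.4 L ≈
  0.12 L/kg × 70 kg). Each subject's basal rate is set so the steady
  plasma level equals their `Insb`, making protocol simulations start at
  the model's equilibrium. Meal boluses use a 10 g/U carbohydrate ratio.
* **Meal appearance**: gamma-shaped `Ra(t)` (time-to-peak 40 min,
  bioavailability 0.8) scaled by the glucose distribution volume
  (Vg = 11.2 L ≈ 0.16 L/kg × 70 kg) and added to dG/dt; its integral is
  exactly carbs × bioavailability / Vg in concentration units.

Study 1 replays an 8-arm grid (25/50/75% VO2max × 30/60 min × 0–75%
premeal bolus reduction) with a 75-g breakfast 90 min before exercise.
Study 2 replays a 60-min session at 50% VO2max split into four 15-min
bouts with 5-min rests (a 75-min window), under pump stop at onset, 80%
basal reduction 90 min ahead, or 50% basal reduction 90 min ahead; "pump
stop" sets the basal rate to zero and lets the absorption chain drain.
During rest periods the intensity-driven increments return to zero; the
duration term of variant 6 keeps accruing inside the session window.
Glycemic outcomes (time in 4–8, 4–10, < 4, < 3.3 mmol/L; start-to-end
exercise drop) are computed by exact piecewise-linear band occupancy on
the reporting grid.

The expected orderings — a 75% bolus reduction safer than 50% at 50%
VO2max/60 min, and the 80%-basal arm showing the smallest exercise drop —
emerge from the dynamics (they are asserted, not built in): larger insulin
reductions monotonically raise glucose under linear kinetics, and the
80% pre-reduction lowers plasma insulin during the session below both the
50% arm and the late-acting pump stop.

## Problem sizes

Default experiment sizes were chosen to make every calibration experiment
a routine desk run: 20 recovery subjects at full chain length (~1 min),
three replicate 10-subject cohorts with 40,000-iteration chains for the
six-way ranking (~4 min), 200 random draws for the exercise-monotonicity
sweep, and 12-subject protocol cohorts. The compiled likelihood makes a
full-length 100,000-iteration fit take roughly one second, so all sizes
can be scaled up freely.

## Known limitations

* Moderate continuous exercise only: the family cannot produce the glucose
  *rise* seen in interval/anaerobic exercise, and no post-exercise effect
  is modelled.
* Glucagon is ignored (the source study measured it; the equations do not
  use it).
* The meal/insulin submodels are standard stand-ins, not the original
  supplementary equations; protocol results are qualitative orderings, not
  quantitative reproductions.
* Priors and `Insb` handling are package choices where the methodology was
  underspecified; both are configurable and documented above.
* DIC's parameterisation dependence is resolved by an explicit choice of
  plug-in coordinates; other choices give different pD.
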