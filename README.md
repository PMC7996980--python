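# exminmod

Exercise-extended Bergman minimal models of glucose dynamics in type 1
diabetes: forward simulation, Bayesian MCMC parameter estimation,
DIC-based model selection, synthetic study-design cohorts, and in-silico
replay of exercise-management protocols.

`exminmod` is aimed at people building or evaluating artificial-pancreas
simulation environments who need a glucoregulatory model that responds to
moderate aerobic exercise. It implements a family of six variants of the
Bergman minimal model,

```
dX/dt = -p2·X + p3·(1 + inc2(t))·Ins(t)
dG/dt = -p1·(1 + inc1(t))·G − X·G + p1·Gp0
```

where `G` is plasma glucose (mmol/L), `X` remote insulin action (1/min),
and `Ins(t)` measured plasma insulin (mU/L). During exercise the
increments `inc1` (glucose effectiveness) and `inc2` (insulin
sensitivity) switch on; the six variants combine fixed gains `e1`, `e2`
with exercise intensity `pvo2(t)` (fraction of the rest-to-max oxygen
uptake span) and normalised duration `te(t)`. The selected variant
(model 6) uses `inc1 = e1·pvo2` and `inc2 = e2·(pvo2 + te)` — an
intensity-driven rise in insulin-independent uptake plus an intensity-
and duration-driven rise in insulin-dependent uptake.

Per-subject parameters are estimated by adaptive random-walk Metropolis
on log-parameters with log-normal priors and a 2%-CV Gaussian measurement
model; competing variants are ranked by the deviance information
criterion (`DIC = D̄ + pD`) pooled over subjects. Because the underlying
clinical dataset is not publicly deposited, the package ships a seeded
synthetic-cohort generator that emulates the study design (14 samples per
session around a 60-min bout at 60% VO2max), making every stage testable
end to end. See `docs/methods.md` for the model, the estimation and
selection machinery, and the documented limits of what synthetic data can
show.

## Worked example

Generate a 3-subject virtual cohort with study-design datasets, then fit
the selected variant to one subject:

```
$ exminmod synth --n 3 --seed 7 --out data
wrote cohort of 3 subjects to data

$ exminmod fit --data data/S00.csv --variant 6 --seed 1 --out chains/S00_v6.csv
subject S00, variant 6:
       median       q25       q75      mean        sd     cv
Gp0     31.98     24.29     41.75     33.82     11.94 0.3532
p1   0.002175  0.001698  0.002865  0.002396  0.001109 0.4627
p2    0.02822   0.02017    0.0393   0.03088   0.01503 0.4866
p3  1.559e-05 1.199e-05 1.969e-05 1.613e-05 5.716e-06 0.3543
e1      1.334    0.9326      1.87     1.508    0.8015 0.5315
e2     0.6022     0.491    0.7306    0.6199    0.1954 0.3152
acceptance rate: 30.2%
```

The table is the posterior summary for the subject: the median column is
the point estimate (this subject's true generating values were
`Gp0 = 32.1`, `p1 = 0.0017`, `p2 = 0.027`, `p3 = 1.2e-5`, `e1 = 1.70`,
`e2 = 0.72`; all six lie inside their 90% credible intervals),
`cv = sd/mean` is the identifiability screen (all below
the 100% criterion, most below 50%). The exercise gains are reported as
fractions — `e1 = 1.334` means a 133% increase in glucose effectiveness
at full intensity.

Replay a validation protocol (intermittent 50%-VO2max exercise with an
80% basal reduction set 90 min ahead) on the default 12-subject cohort:

```
$ exminmod protocol --study 2 --strategy basal-80-90min --n 12 --seed 0 --out proto
Glycemic outcomes 80% basal reduction 90 min pre-exercise
window: 180-255 min
Time spent between 4-8 mmol/L: 25 (45)
Time spent between 4-10 mmol/L: 42 (51)
Time spent below 4 mmol/L: 0 (0)
Time spent below 3.3 mmol/L: 0 (0)
Glucose drop start-to-end of exercise: 0.65 (0.53) mmol/L
```

Values are cohort mean (sd) percentages of the exercise window. The
0.65 mmol/L mean drop under the 80% reduction is the smallest of the
three strategies (pump stop at onset: 1.50; 50% reduction: 1.01 on the
same cohort) — the qualitative ordering this protocol engine is designed
to reproduce: reducing basal insulin well ahead of exercise leaves less
circulating insulin during the session than stopping the pump at onset.

Other subcommands: `simulate` (single trajectory CSV), `select`
(six-variant DIC ranking from saved chains), `report` (time-in-range
metrics from trajectory CSVs). Everything is also available as a library
(`import exminmod`); every artifact carries its seed and configuration in
a manifest or sidecar, and fixed seeds give byte-identical outputs.

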