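# hypertx

Virtual-patient simulation of antihypertensive therapy on a reduced
cardiovascular–renal–RAAS model.

Hypertension trials compare drug classes with different mechanisms — AT1
blockade (losartan), calcium-channel blockade (amlodipine), ACE inhibition
(enalapril), direct renin inhibition (aliskiren), thiazide diuresis
(hydrochlorothiazide), β-blockade (bisoprolol) — on populations whose
individual physiology varies widely.  `hypertx` is for modelers and
quantitative pharmacologists who want to run such trials *in silico*: it
generates virtual hypertensive patients as constrained equilibrium
parameterizations of a mechanistic circulatory–renal model, calibrates the
drug layer against published monotherapy outcomes, and simulates 4-week
mono- and dual therapy with population-level statistics.

## The model in brief

Each drug multiplies its physiological target quantities by an influence
function

    F = 1 ± Σ_D E(D)·d_F

summed over the dosages of one drug class, where `E(D)` is the dimensionless
effect magnitude at dose `D` (for the renin inhibitor an Emax law
`E(D) = 0.99·D/(D + 20)`; for the thiazide's systemic action a slow ramp
`min(0.074·t/1,950,000, 0.074)`), and `d_F ∈ {0, 1}` switches the drug on.
The targets live in a reduced model with Frank–Starling ventricles
(`SV = K·SVmax·δ(EDV)`, `K = K0 + 0.25·σ(H, K0)`), a compliance-partitioned
circulation closed by `MAP = HR·SV·SVR + CVP` with a baroreflex, a
three-resistor glomerular divider with autoregulation and pressure
natriuresis, and a first-order renin → Ang I → Ang II → AT1 → aldosterone
cascade.

Virtual patients minimize the normalized distance to their clinical targets

    f_dist = Σ_i (ω_min/ω_i)·(X_i − X_i^exp)²,   ω_i = X_i^exp

subject to physiological ranges enforced by the quadratic penalty

    f_penalty = Σ_t [ Σ_j max(0, Y_j^min − Y_j(t))² + Σ_j max(0, Y_j(t) − Y_j^max)² ]

via a stochastic-ranking (μ, λ) evolution strategy; each patient must also
survive a sodium-loading test (intake stepped to 0.243 mEq/min; systolic
rise must stay in (0, 25] mmHg without pulmonary congestion).

See `docs/methods.md` for the full model description, assumptions and
limitations.

## Worked example

```python
from hypertx import (default_patient, find_equilibrium, parse_regimen,
                     generate_population, treat_population)

# one reference hypertensive patient (160/100 mmHg, HR 75, 80 kg)
p = default_patient()
base = find_equilibrium(p)
post = find_equilibrium(p, parse_regimen("enalapril:20"))
print(f"untreated {base.SBP:.0f}/{base.DBP:.0f}, HR {base.HR:.0f}")
print(f"ACE inhibitor {post.SBP:.0f}/{post.DBP:.0f}, HR {post.HR:.0f}, "
      f"PRA x{post.PRA:.1f}, AngII x{post.AngII:.2f}")
```

prints

```
untreated 160/100, HR 75
ACE inhibitor 134/80, HR 78, PRA x3.0, AngII x0.12
```

— the uncalibrated reference patient drops ~26/20 mmHg under full-dose ACE
inhibition with a reactive rise in plasma renin activity (×3.0) and a
collapse of angiotensin II to 12 % of baseline, while heart rate barely
moves.  Population-level work goes through the pipeline:

```python
pop = generate_population(n=10, seed=7)          # rejection-sampled trial cohort
outcomes = treat_population(pop, parse_regimen("aliskiren:150+amlodipine:5"))
```

The same steps are available from the shell:

```bash
hypertx generate --n 50 --seed 1 --out pop.json
hypertx calibrate --population pop.json --out calibration.json
hypertx treat --population pop.json --calibration calibration.json \
        --regimen "enalapril:20+hctz:12.5" --out treatment.csv
hypertx report --population pop.json --calibration calibration.json \
        --treatments "aliskiren:150+amlodipine:5" --out-dir report/
```

## Layout

| path | contents |
|---|---|
| `src/hypertx/drugs.py` | pharmacodynamic layer (effect table, Emax, ramp) |
| `src/hypertx/model.py` | physiology core: closures, ODE, equilibria, shock detection |
| `src/hypertx/params.py` | patient parameterization and construction |
| `src/hypertx/optimize.py` | distance/penalty objectives and the SRES optimizer |
| `src/hypertx/population.py` | target sampling, two-stage patient fit, sodium test |
| `src/hypertx/therapy.py` | treatment simulation, validity screen, calibration, statistics |
| `src/hypertx/study.py` | the end-to-end reference study |
| `src/hypertx/io.py`, `cli.py` | config, serialization, report tables, CLI |
| `configs/` | shipped effect table and default run config |
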