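# Methods

`hypertx` simulates antihypertensive mono- and dual therapy in virtual
hypertensive patients.  It couples three pieces: a reduced-order
cardiovascular–renal model with a renin–angiotensin–aldosterone (RAAS)
cascade; a pharmacodynamic layer that maps drug regimens onto multiplicative
influence functions at named target sites; and a constrained-optimization
machinery (normalized distance objective, quadratic range penalty, and a
stochastic-ranking evolution strategy) used both to generate virtual
patients and to calibrate the therapy parameters.

## The physiological model

### States and closures

Five slow states are integrated in time (seconds): total exchangeable sodium
`Na_tot` (mEq), pulmonary venous volume `V_pv` (ml), plasma renin
concentration, angiotensin I and angiotensin II (normalized concentrations,
drug-free baseline ≡ 1).  Everything else — pressures, flows, heart rate,
renal function, hormone levels — is closed algebraically at each instant.
This is a deliberate reduction: beat-resolved hemodynamics are replaced by
beat-averaged relations, and the fast circulatory states (arterial and
venous volumes) are assumed instantaneously partitioned by compliances.

**Heart.**  Each ventricle obeys a Frank–Starling law
`SV = K·SVmax·δ(EDV)` with effective contractility
`K = K0 + 0.25·σ(H, K0)`.  `SVmax` scales with body weight (200 ml at
70 kg).  The ejection-effectiveness factor

    δ(EDV) = max(0, 1 − exp(−(EDV − 10)/60)) · (1 − 0.002·max(0, EDV − 180))

rises with filling and declines beyond 180 ml; the declining branch is what
allows a failing, congested ventricle to spiral into cardiogenic shock.  The
sympathetic inotropic modulation is a sigmoid in the neurohumoral factor H,

    σ(H, K0) = [2/(1 + e^(−k_H·(H−H0))) − 1] · (0.8 − K0)/0.6 ,

zero at neutral drive and scaled by the inotropic headroom so K stays in
(0, 1); β-blockade gates this term.  Filling maps venous pressure to
end-diastolic volume through a saturating exponential whose pressure
constant shortens at higher heart rates (less diastole); at the constructed
operating point each ventricle uses one third of its filling-map reserve.

**Circulation and baroreflex.**  Blood volume is a fixed plasma fraction of
extracellular fluid volume (`ECFV = Na_tot/[Na]`), corrected for hematocrit.
Mean arterial pressure solves the scalar fixed point
`MAP = HR·SV·SVR_eff + CVP`, where systemic venous pressure follows from the
compliance partition of the blood volume and `SVR_eff` is the microvessel
resistance modulated by H, by AT1-bound angiotensin II (a clipped power law
— receptor occupancy saturates) and by the vasodilating drug sites.  The
residual of this equation is strictly increasing in MAP, so a bracketing
scalar root find is used.  H itself carries the baroreflex:
`H = H0 + g_b·(MAP_set − MAP)/MAP_set·baro_mod + g_s·(S − S0)`, where
`baro_mod` is the AT1-dependent reflex-gain modulation (`sl_baro`) and S the
stress-receptor activity (modulated by `sl_stress` and the thiazide and
β-blocker sites).  Heart rate splits into a parasympathetic floor and a
β-gated sympathetic share driven by H and S.  Pulse pressure is `SV/Ca_eff`
with an arterial compliance that stiffens at elevated pressure
(`Ca_eff ∝ (MAP_set/MAP)^0.5`), and `SBP = MAP + 2·PP/3`,
`DBP = MAP − PP/3`.

**Kidney.**  A three-resistor series divider (pre-glomerular, afferent,
efferent-plus-postglomerular) sets renal blood flow and glomerular pressure.
Pre-glomerular resistance carries myogenic autoregulation
(`∝ (MAP/MAP_ref)^2.5`); afferent tone carries tubuloglomerular feedback
(afferent resistance ∝ (GFR/GFR_ref)^2, solved as an inner bracketed fixed
point); efferent tone follows AT1-bound angiotensin II more sensitively than
afferent tone.  Filtration is sublinear in net filtration pressure
(exponent 0.5 — filtration-pressure equilibrium along the capillary) with an
AT1-dependent filtration-coefficient modulation (`sl_KFG`).  Sodium
handling: proximal fractional reabsorption carries pressure natriuresis
(`∝ MAP^−0.25`), volume feedback (`∝ ECFV^−0.8`) and peritubular washout
(`∝ RBF^−0.1`); distal fractional reabsorption follows aldosterone
(`∝ ALD^0.4`) and hosts the thiazide site.  Aldosterone is algebraic in
AT1-bound angiotensin II and potassium.

**RAAS.**  Renin secretion responds to renal perfusion pressure
(exponent 2) and macula-densa sodium delivery (exponent 1.15), with the
β-blocker and thiazide sites acting multiplicatively; the
renin → Ang I → Ang II cascade uses first-order kinetics (renin turnover
15 min, Ang I 1 min with a 10 % non-ACE conversion share, Ang II 30 s split
between AT1 binding and degradation).  All rate constants are derived from
the normalized drug-free baselines, so with zero drug effects and reference
signals the cascade is exactly at rest.

### Construction of a patient

A patient is *constructed* rather than fitted from scratch: given target
SBP/DBP/HR, anthropometrics and the unmeasured boundary values (cardiac
output, hematocrit, ejection fraction, filling pressures, GFR, RBF, sodium
intake, fluid volume), the dependent parameters — compliances, resistances,
inotropic states, unstressed volumes and all renal/RAAS reference values —
are solved in closed form so that the target state is an exact fixed point
of the drug-free dynamics (residual ~1e−13).  Draws that are not realizable
(implied inotropy outside [0.2, 0.8], infeasible pressures) raise and are
discarded.  This anchoring also means the AT1-modulation sensitivities
(`sl_*`) do not move the drug-free equilibrium: all their terms vanish at
neutral AT1 occupancy.

### Equilibria and integration

`find_equilibrium` follows the dynamical branch: it relaxes the ODE system
(LSODA; the ~30 s RAAS turnover next to multi-day sodium dynamics makes the
system mildly stiff) and polishes the endpoint with a log-parameterized
Powell-hybrid root solve; the log parameterization keeps all states
positive.  The acceptance threshold is a scaled residual — the largest
relative state change per characteristic time — below 1e−8.
`polish_equilibrium` is the root-only fast path used inside calibration
loops, seeded with the previous solution.  The thiazide systemic ramp is
evaluated at saturation for equilibrium solves and time-resolved in
trajectory simulations.

## Drug layer

Each agent multiplies its target quantities by `1 ± Σ E(D)·dF` (inhibition
−, stimulation +), summed over the dosages of one class; dual therapy is the
union of the two drugs' effect sets.  Magnitudes are fixed per (drug, dose)
except the renin inhibitor (a saturating Emax dose–response, half-maximal at
20 mg/day) and the thiazide systemic vasodilation (linear ramp over
1,950,000 s ≈ 22.6 days, plateau 0.074 — the slow conductivity rise that
lets extracellular volume recover over 4–6 weeks of treatment).  Only the
listed dosages are supported; other doses raise an error rather than
extrapolate, because only the renin inhibitor has a dose–response formula.
The table ships as a versioned plain-text config
(`configs/effect_table.yaml`).

## Virtual patients and populations

Targets are drawn from independent normals (defaults: SBP 160±10, DBP
100±10 mmHg, HR 75±10 /min, BMI 29±5 kg/m², weight 80±20 kg, 50/50 sex) and
rejection-sampled against the trial criteria (essential hypertension;
no severe hypertension SBP>179.5 / DBP>109.5; HR 60–90; BMI 22–36; height —
derived as `100·√(weight/BMI)` — within 160–180 cm; the whole joint draw is
rejected when any criterion fails).  Patient generation is a two-stage
constrained fit: the renal block first, under fixed boundary values (MAP
from cuff pressures via `DBP + PP/3`, cardiac output and hematocrit drawn
uniformly from their physiological ranges when unmeasured), then the
cardiovascular block against the drawn SBP/DBP/HR — both stages minimized
by the stochastic-ranking evolution strategy with the normalized distance
objective and the quadratic range penalty over the constraint set (systemic
vascular resistance 700–1600 dyn·s/cm⁵, LV end-diastolic pressure
3–12 mmHg, heart rate 60–90, sodium intake 0.0280–0.2088 mEq/min, inotropy
0.2–0.8, ejection fraction 50–75 %, blood volume within ±10 % of the
anthropometric Nadler estimate).  An accepted patient must reproduce its
targets within 2 units with zero penalty, and must pass a sodium-loading
test: stepping intake to 0.243 mEq/min must yield a new equilibrium with a
positive systolic rise of at most 25 mmHg and no sustained pulmonary-venous
pressure rise (ceiling 3 mmHg).  Per-patient seeds are spawned from the
master seed, so populations are bitwise reproducible.

Because the construction hits the drawn targets exactly, the generator's
distributional fidelity is set by the rejection sampling itself.  One
consequence worth noting: when the sampling moments are placed at the
analyzed-population values (DBP 101.34 ± 5.64), the severe-hypertension
cutoff at 109.5 truncates the upper DBP tail (~1.45 SD), so the achieved
DBP mean sits ~1–1.5 mmHg below the configured mean.  That bias is a
property of the prescribed sampling rule, not of the fit.

## Calibration

Two documented steps, in order:

1. **Neurohumoral sensitivities.**  For each patient, (`sl_baro`,
   `sl_stress`, `sl_KFG`) are fitted so the equilibrium heart rate and GFR
   under the renin inhibitor (150 mg/day) equal their drug-free values —
   the clinically established chronotropic and renal neutrality of that
   agent.  The population means are then frozen into every patient and the
   (unchanged, by the anchoring above) drug-free equilibria re-verified.
   In this closure `sl_KFG` is searched over a signed range: AT1-bound
   angiotensin II already lowers filtration hemodynamically through
   efferent tone, so neutrality requires the filtration-coefficient
   modulation to act with the opposite sign (fitted means are ≈ +0.76,
   +0.52, −0.13).
2. **Per-drug gain multipliers.**  One scalar per drug jointly rescales all
   of that drug's effect magnitudes (the renin inhibitor's ED50 stays
   fixed; only its Emax scales), fitted by the same optimizer so the
   population-mean simulated 4-week SBP/DBP/HR deltas match the published
   monotherapy deltas applied to this population's own baseline means.
   Multipliers are bounded above so no inhibitory magnitude reaches 1.  A
   single scalar cannot match all three observables exactly for every drug
   (e.g., the thiazide's diastolic response trades against its systolic
   and chronotropic response); residuals above 1 unit rms are reported as
   calibration warnings, not errors.

Combinations receive no combination-specific calibration: the pipeline's
combination predictions are genuine model output.

## Statistics

Population summaries report mean ± SD per regimen; two-sample
Kolmogorov–Smirnov tests compare each post-treatment distribution against
baseline and, for combinations, against each component monotherapy; Pearson
correlations relate baseline covariates (BMI, sodium intake, baseline
SBP/DBP/GFR/renin activity, arterial tone and elasticity proxies, an
afferent-diameter proxy, fractional proximal reabsorption) to the
achieved SBP/DBP reductions.  Degenerate-variance cases are reported as
undefined rather than zero.

## Response-validity screen

The screen classifies each variable's 4-week change as no-change (<5 %),
directed (>10 %) or transitional (5–10 %, compatible with both) and
compares against a per-drug table of clinically expected directions
(shipped as editable data).  The table is a reconstruction from published
trial observations; two known surrogate limitations show up here: the
calcium-channel blocker's GFR rise and the thiazide's renin activation are
stronger in this reduced model than the no-change band allows for some
patients, so screened inclusion rates are lower than a full-scale model
would give.  The screen is mechanical and population-independent, so
populations remain reusable across regimens.

## Problem sizes and numerical choices

The reference study uses n = 50 patients (generation ~1 s/patient;
full pipeline with calibration and seven 4-week treatments in a few
minutes).  Optimizer budgets: patient generation (μ=10, λ=40, 12
generations renal; μ=8, λ=32, 14 cardiovascular), neurohumoral fit (μ=4,
λ=14, 7), gain fit (μ=3, λ=8, 6) — all with pf = 0.45 and boundary
reflection; the general-purpose default is the literature-standard (30,
200, 250).  Equilibrium tolerance 1e−8 (scaled residual); integration
rtol 1e−7.  Ties in the stochastic ranking keep insertion order; the
ranking RNG is seeded per problem.

## What the generator does and does not emulate

The synthetic populations reproduce the *marginal* distributions of the
clinical targets under the trial's inclusion/exclusion rules, and
physiologically plausible joint variation of the hidden parameters through
the constraint set.  They do not emulate: real covariance structure between
clinical variables (targets are drawn independently before rejection),
comorbidities, adherence, pharmacokinetic variability (doses map directly
to effect magnitudes), or within-day blood-pressure variation.  Passing
tests therefore demonstrate internal consistency of the model and pipeline
and agreement with published population-level outcomes — not
patient-level predictive validity.

## Known limitations

* The cardiovascular closure is beat-averaged; within-beat quantities
  (valve flows, early/active filling-rate peaks) are out of scope.
* The effective contractility range implied by ejection-fraction targets
  (K0 ≈ 0.35–0.5 for normal EF) sits lower than the nominal 0.55 midpoint
  of the inotropy scale, a consequence of the fixed δ(EDV) shape.
* Chronic blood-pressure setting is dominated by the renal
  sodium-balance curve; systemic vasodilators act chronically mostly
  through their renal sites, which is why the calcium-channel blocker's
  fitted gain multiplier exceeds 1.
* The thiazide's diastolic response is under-predicted (volume loss narrows
  pulse pressure less in the clinic than in this closure), and its renin
  activation overshoots the published ~+45 % PRA.
* The calcium-channel blocker's population-mean RAAS change is ~+7 %
  (renal-perfusion renin feedback during the pressure fall outweighs
  macula-densa suppression), one band above the strict ±5 % no-change
  criterion though inside the 5–10 % "insignificant" classification band.
* Combination heart-rate predictions inherit the monotherapy compromises of
  the single-scalar calibration.
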