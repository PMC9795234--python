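"""Virtual-patient and virtual-population generation.

Clinical targets (SBP, DBP, HR, BMI, weight) are drawn from independent
normals and rejection-sampled against the trial's inclusion/exclusion
criteria; each accepted draw is turned into a model parameterization by a
two-stage constrained fit (renal block first under fixed boundary values,
then the cardiovascular block against the pressure/heart-rate targets), and
every candidate patient must additionally survive a sodium-loading test
before entering the population.

Default sampling settings describe an uncomplicated-hypertension trial
population: SBP 160±10 mmHg, DBP 100±10 mmHg, HR 75±10 /min, BMI 29±5 kg/m²,
weight 80±20 kg, 50/50 sex ratio, height restricted to 160–180 cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .drugs import DrugRegimen
from .model import (EquilibriumError, EquilibriumState, ModelState,
                    baseline_state, equilibrium_residual, find_equilibrium,
                    observe, simulate)
from .optimize import (BoxConstraint, OptimizationProblem, f_dist, f_penalty,
                       sres_minimize)
from .params import (PatientParameters, build_patient, du_bois_bsa,
                     nadler_blood_volume)

__all__ = [
    "SamplingSettings", "TargetDraw", "ConstraintSet", "VirtualPatient",
    "GenerationError", "sample_targets", "generate_patient",
    "sodium_loading_test", "generate_population", "nadler_blood_volume",
]

#: Sodium-loading step level (mEq/min) and acceptance limits.
SODIUM_TEST_PHI = 0.243
SODIUM_TEST_MAX_DSBP = 25.0
SODIUM_TEST_MAX_DPVP = 3.0


class GenerationError(RuntimeError):
    """A target draw could not be realized as a valid virtual patient."""


@dataclass(frozen=True)
class SamplingSettings:
    sbp_mean: float = 160.0       # mmHg
    sbp_sd: float = 10.0
    dbp_mean: float = 100.0       # mmHg
    dbp_sd: float = 10.0
    hr_mean: float = 75.0         # beats/min
    hr_sd: float = 10.0
    bmi_mean: float = 29.0        # kg/m²
    bmi_sd: float = 5.0
    weight_mean: float = 80.0     # kg
    weight_sd: float = 20.0
    male_fraction: float = 0.5
    height_min: float = 160.0     # cm
    height_max: float = 180.0

    def __post_init__(self) -> None:
        for name in ("sbp_sd", "dbp_sd", "hr_sd", "bmi_sd", "weight_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")


def passes_criteria(sbp: float, dbp: float, hr: float, bmi: float,
                    weight: float, height: float,
                    settings: SamplingSettings | None = None) -> bool:
    """Inclusion/exclusion logic for one joint draw.

    Inclusion requires essential hypertension (SBP ≥ 140 and/or DBP ≥ 90,
    with SBP > 130 and DBP > 80); exclusion removes severe hypertension
    (SBP > 179.5 or DBP > 109.5), abnormal heart rate (outside 60–90),
    BMI outside 22–36, and height outside the sampling band.
    """
    s = settings or SamplingSettings()
    if (sbp < 140.0 and dbp < 90.0) or dbp > 109.5 or sbp > 179.5 \
            or sbp < 130.0 or dbp < 80.0:
        return False
    if hr < 60.0 or hr > 90.0:
        return False
    if bmi < 22.0 or bmi > 36.0:
        return False
    if weight <= 0:
        return False
    if height < s.height_min or height > s.height_max:
        return False
    return True


@dataclass(frozen=True)
class TargetDraw:
    sbp: float
    dbp: float
    hr: float
    bmi: float
    weight: float
    height: float
    sex: str
    seed: int

    def asdict(self) -> dict:
        return asdict(self)


def sample_targets(settings: SamplingSettings, seed: int,
                   max_tries: int = 100_000) -> TargetDraw:
    """Rejection-sample one joint target draw satisfying all criteria.

    Height is derived from weight and BMI (``height = 100·√(weight/BMI)``);
    a draw whose derived height falls outside the allowed band is rejected
    as a whole.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        sbp = rng.normal(settings.sbp_mean, settings.sbp_sd)
        dbp = rng.normal(settings.dbp_mean, settings.dbp_sd)
        hr = rng.normal(settings.hr_mean, settings.hr_sd)
        bmi = rng.normal(settings.bmi_mean, settings.bmi_sd)
        weight = rng.normal(settings.weight_mean, settings.weight_sd)
        sex = "M" if rng.random() < settings.male_fraction else "F"
        if bmi <= 0 or weight <= 0:
            continue
        height = 100.0 * math.sqrt(weight / bmi)
        if passes_criteria(sbp, dbp, hr, bmi, weight, height, settings):
            return TargetDraw(sbp, dbp, hr, bmi, weight, height, sex, seed)
    raise RuntimeError(
        "acceptance probability too low under the supplied sampling settings")


@dataclass
class ConstraintSet:
    """Physiological ranges enforced (as a quadratic penalty) on patients.

    Defaults: systemic vascular resistance within the normal 700–1600
    dyn·s/cm⁵ band, LV end-diastolic pressure 3–12 mmHg, heart rate 60–90,
    sodium intake 0.0280–0.2088 mEq/min, ventricular inotropic state within
    0.2–0.8, ejection fraction 50–75 %, and total blood volume within ±10 %
    of the anthropometric (Nadler) estimate.  Extensible: extra
    ``BoxConstraint`` rows are applied to equilibrium observables by name.
    """

    svr: tuple[float, float] = (700.0, 1600.0)
    lvedp: tuple[float, float] = (3.0, 12.0)
    hr: tuple[float, float] = (60.0, 90.0)
    phi_sod_in: tuple[float, float] = (0.0280, 0.2088)
    k0: tuple[float, float] = (0.2, 0.8)
    ef: tuple[float, float] = (50.0, 75.0)
    co: tuple[float, float] = (4.0, 8.0)
    hct: tuple[float, float] = (0.37, 0.49)
    gfr: tuple[float, float] = (85.0, 125.0)
    rbf: tuple[float, float] = (900.0, 1300.0)
    blood_volume_tolerance: float = 0.10    # fraction of the Nadler estimate
    extra: list[BoxConstraint] = field(default_factory=list)

    def equilibrium_constraints(self, nadler_l: float) -> list[BoxConstraint]:
        vb = self.blood_volume_tolerance
        rows = [
            BoxConstraint("SVR", *self.svr),
            BoxConstraint("LVEDP", *self.lvedp),
            BoxConstraint("HR", *self.hr),
            BoxConstraint("EF", *self.ef),
            BoxConstraint("CO", *self.co),
            BoxConstraint("V_blood", nadler_l * (1 - vb), nadler_l * (1 + vb)),
        ]
        return rows + list(self.extra)


@dataclass
class VirtualPatient:
    params: PatientParameters
    equilibrium: EquilibriumState
    draw: TargetDraw
    objective: float
    penalty: float
    evaluations: int
    sodium_test: dict | None = None

    @property
    def state(self) -> ModelState:
        return self.equilibrium.state


def _stage1_renal(draw: TargetDraw, constraints: ConstraintSet, rng,
                  budget: tuple[int, int, int] = (10, 40, 12)):
    """Stage 1 of the two-stage fit: the renal block.

    With mean arterial pressure, cardiac output and hematocrit fixed as
    boundary values (drawn from their physiological ranges when unmeasured),
    the renal parameters — filtration and perfusion scales, resistance
    split, proximal reabsorption fraction, sodium intake, fluid volume — are
    fitted so the renal block balances filtration against intake.  Returns
    the renal keyword arguments for the patient constructor plus the fixed
    boundary values.
    """
    gfr_t = rng.uniform(*constraints.gfr)
    rbf_t = rng.uniform(*constraints.rbf)
    # cardiac output is drawn from the part of its physiological range that
    # is consistent with the vascular-resistance constraint at this MAP
    map0 = draw.dbp + (draw.sbp - draw.dbp) / 3.0
    co_lo, co_hi = constraints.co
    co_lo = max(co_lo, (map0 - 4.0) * 79993.2 / (constraints.svr[1] * 1000.0))
    co_hi = min(co_hi, (map0 - 4.0) * 79993.2 / (constraints.svr[0] * 1000.0))
    if co_lo >= co_hi:
        raise GenerationError("no cardiac output satisfies the resistance "
                              "constraint at this pressure")
    co = rng.uniform(co_lo, co_hi)
    hct = rng.uniform(*constraints.hct)

    mu, lam, gens = budget
    names = ["gfr0", "rbf0", "rho_pre", "f_prox", "phi_sod_in", "ecfv_per_kg"]
    lo = np.array([constraints.gfr[0], constraints.rbf[0], 0.50, 0.89,
                   constraints.phi_sod_in[0], 0.17])
    hi = np.array([constraints.gfr[1], constraints.rbf[1], 0.75, 0.95,
                   constraints.phi_sod_in[1], 0.23])
    prob = OptimizationProblem(names, lo, hi, mu=mu, lam=lam, generations=gens,
                               seed=int(rng.integers(2**31)))

    def evaluate(x):
        gfr0, rbf0, rho, fpx, phi, ecfk = x
        delivery = gfr0 * 142.0 / 1000.0 * (1.0 - fpx)
        f_dist0 = 1.0 - phi / delivery
        pen = f_penalty([[f_dist0]], [BoxConstraint("f_dist0", 0.70, 0.99)])
        return f_dist([gfr0, rbf0], [gfr_t, rbf_t]), pen

    res = sres_minimize(prob, evaluate)
    kw = dict(zip(names, map(float, res.x)))
    return kw, dict(co_lpm=co, hct=hct), res


def _stage2_cardio(draw: TargetDraw, renal_kw: dict, boundary: dict,
                   constraints: ConstraintSet, rng,
                   budget: tuple[int, int, int] = (8, 32, 14)):
    """Stage 2: the cardiovascular block.

    The renal equilibrium hands over blood volume and AT1-bound angiotensin
    II; the cardiovascular parameters (operating filling pressures, ejection
    fraction, hence compliances/inotropy) are fitted so the joint whole-model
    equilibrium reproduces the drawn SBP/DBP/HR within the physiological
    constraint set (objective per the normalized distance, penalty per the
    quadratic range violations).
    """
    nadler = nadler_blood_volume(draw.height, draw.weight, draw.sex)
    cons = constraints.equilibrium_constraints(nadler)
    mu, lam, gens = budget
    names = ["ef_pct", "cvp0", "pvp0", "p_glom_margin"]
    lo = np.array([constraints.ef[0], 2.0, 5.0, 12.0])
    hi = np.array([constraints.ef[1], 6.0, 11.0, 18.0])
    prob = OptimizationProblem(names, lo, hi, mu=mu, lam=lam, generations=gens,
                               seed=int(rng.integers(2**31)))
    target = [draw.sbp, draw.dbp, draw.hr]

    def build(x) -> PatientParameters:
        ef, cvp0, pvp0, margin = x
        return build_patient(
            sbp=draw.sbp, dbp=draw.dbp, hr=draw.hr,
            weight=draw.weight, height=draw.height, sex=draw.sex,
            ef_pct=ef, cvp0=cvp0, pvp0=pvp0, p_glom_margin=margin,
            **boundary, **renal_kw)

    def evaluate(x):
        try:
            p = build(x)
            eq = observe(baseline_state(p), p)
        except (ValueError, EquilibriumError):
            return 1e6, 1e6
        obj = f_dist([eq.SBP, eq.DBP, eq.HR], target)
        series = [[getattr(eq, c.name)] for c in cons]
        pen = f_penalty(series, cons)
        pen += f_penalty([[p.KL0]], [BoxConstraint("K0", *constraints.k0)])
        return obj, pen

    res = sres_minimize(prob, evaluate)
    try:
        params = build(res.x)
    except (ValueError, EquilibriumError) as exc:
        raise GenerationError(f"cardiovascular stage infeasible: {exc}") from exc
    return params, res


def generate_patient(draw: TargetDraw, constraints: ConstraintSet | None = None,
                     seed: int = 0) -> VirtualPatient:
    """Two-stage constrained fit of one virtual patient.

    Raises :class:`GenerationError` when either stage ends infeasible or the
    assembled whole-model equilibrium misses the targets by more than 2
    units — the caller discards the draw.
    """
    constraints = constraints or ConstraintSet()
    rng = np.random.default_rng(seed)
    renal_kw, boundary, res1 = _stage1_renal(draw, constraints, rng)
    params, res2 = _stage2_cardio(draw, renal_kw, boundary, constraints, rng)

    pd_free = DrugRegimen.none()
    try:
        eq = find_equilibrium(params, pd_free)
    except EquilibriumError as exc:
        raise GenerationError(f"no joint equilibrium: {exc}") from exc

    mismatch = max(abs(eq.SBP - draw.sbp), abs(eq.DBP - draw.dbp),
                   abs(eq.HR - draw.hr))
    if res2.penalty > 0.0 or mismatch > 2.0:
        raise GenerationError(
            f"fit rejected: penalty={res2.penalty:.3g}, "
            f"target mismatch={mismatch:.2f}")
    return VirtualPatient(params=params, equilibrium=eq, draw=draw,
                          objective=res2.objective, penalty=res2.penalty,
                          evaluations=res1.evaluations + res2.evaluations)


def sodium_loading_test(patient: VirtualPatient,
                        phi_elevated: float = SODIUM_TEST_PHI,
                        max_dsbp: float = SODIUM_TEST_MAX_DSBP,
                        max_dpvp: float = SODIUM_TEST_MAX_DPVP) -> dict:
    """Step sodium intake to the elevated level and judge the new state.

    The intake jumps instantaneously from the patient value to
    ``phi_elevated``; the verdict is *pass* iff the model converges to a new
    equilibrium with a positive, bounded rise in systolic pressure
    (ΔSBP ∈ (0, 25] mmHg) and no sustained pulmonary-venous pressure rise
    (ΔPVP below the ceiling).  Deterministic: no randomness is involved.
    """
    p_loaded = patient.params.copy(Phi_sod_in=phi_elevated)
    base = patient.equilibrium
    try:
        eq = find_equilibrium(p_loaded, DrugRegimen.none(), y0=patient.state)
    except EquilibriumError:
        return {"passed": False, "reason": "pulmonary congestion "
                "(no equilibrium under sodium loading)",
                "dSBP": None, "dPVP": None}
    dsbp = eq.SBP - base.SBP
    dpvp = eq.PVP - base.PVP
    passed = (0.0 < dsbp <= max_dsbp) and (dpvp <= max_dpvp)
    reason = None
    if not passed:
        if dpvp > max_dpvp or dsbp <= 0:
            # a flat or falling systolic pressure under loading reflects
            # volume decompensation into the pulmonary bed, not salt
            # resistance
            reason = (f"pulmonary venous congestion under loading "
                      f"(dSBP {dsbp:.1f}, dPVP {dpvp:.1f} mmHg)")
        else:
            reason = f"excessive SBP elevation ({dsbp:.1f} mmHg)"
    return {"passed": bool(passed), "reason": reason,
            "dSBP": float(dsbp), "dPVP": float(dpvp)}


def generate_population(settings: SamplingSettings | None = None,
                        constraints: ConstraintSet | None = None,
                        n: int = 50, seed: int = 0,
                        max_attempts_factor: int = 40,
                        progress: bool = False) -> list[VirtualPatient]:
    """Generate ``n`` unique virtual patients.

    Per-patient seeds are spawned from the master seed, so the population is
    reproducible and the per-patient work is order-independent.  Rejection
    reasons are tallied; generation aborts when the overall yield collapses.
    """
    if n < 1:
        raise ValueError("population size must be at least 1")
    settings = settings or SamplingSettings()
    constraints = constraints or ConstraintSet()
    master = np.random.SeedSequence(seed)
    patients: list[VirtualPatient] = []
    reasons: dict[str, int] = {}
    attempts = 0
    max_attempts = max_attempts_factor * n
    while len(patients) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"virtual-patient yield too low ({len(patients)}/{attempts} "
                f"accepted); failure histogram: {reasons}")
        child = master.spawn(1)[0]
        s_draw, s_fit = (int(x) % (2**31) for x in child.generate_state(2))
        attempts += 1
        draw = sample_targets(settings, s_draw)
        try:
            vp = generate_patient(draw, constraints, seed=s_fit)
        except GenerationError as exc:
            reasons[f"fit: {str(exc)[:40]}"] = \
                reasons.get(f"fit: {str(exc)[:40]}", 0) + 1
            continue
        verdict = sodium_loading_test(vp)
        vp.sodium_test = verdict
        if not verdict["passed"]:
            key = f"sodium test: {verdict['reason']}"
            reasons[key] = reasons.get(key, 0) + 1
            continue
        patients.append(vp)
        if progress:
            print(f"  accepted {len(patients)}/{n} "
                  f"(attempt {attempts})", flush=True)
    return patients
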