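"""Patient parameterization of the reduced cardiovascular–renal–RAAS model.

A *virtual patient* is a single equilibrium parameterization: every
:class:`PatientParameters` instance is built so that, drug-free, the model
sits exactly at the patient's own hemodynamic operating point (the
construction derives compliances, resistances, inotropic states and renal
reference values from the target observables, so the target state is a fixed
point of the dynamics by construction).

Two groups of constants live here:

* **personal parameters** — differ between patients (weight, inotropy,
  compliances, renal resistances, sodium intake, RAAS references, ...);
* **structural constants** — gains and exponents of the reduced closures,
  shared across the population (baroreflex gain, pressure-natriuresis
  exponent, RAAS rate constants, ...).  They are ordinary dataclass fields,
  so a config can override any of them.

Pressures are mmHg, volumes ml (fluid volumes in L where field names say
so), flows ml/min, resistances mmHg·min/ml, time in seconds, sodium in mEq.
RAAS species use normalized concentration units with all drug-free baselines
at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = ["PatientParameters", "build_patient", "default_patient",
           "nadler_blood_volume", "du_bois_bsa"]

# RAAS turnover constants (1/s): renin ~15 min, Ang I ~1 min (90% via ACE),
# Ang II ~30 s split evenly between AT1 binding and degradation.
K_REN = 1.0 / 900.0
K_AT1 = 1.0 / 60.0
K_DEG = 1.0 / 60.0
K_ACE = K_AT1 + K_DEG          # so AngI0 = AngII0 = 1 balances
K_NONACE = K_ACE / 9.0         # non-ACE conversion share ~10%


def nadler_blood_volume(height_cm: float, weight_kg: float, sex: str) -> float:
    """Total blood volume (L) from height, weight and sex (Nadler formula)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    h = height_cm / 100.0
    if sex.upper().startswith("M"):
        return 0.3669 * h ** 3 + 0.03219 * weight_kg + 0.6041
    if sex.upper().startswith("F"):
        return 0.3561 * h ** 3 + 0.03308 * weight_kg + 0.1833
    raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")


def du_bois_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m²), Du Bois formula."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return 0.007184 * weight_kg ** 0.425 * height_cm ** 0.725


@dataclass
class PatientParameters:
    # --- identity / anthropometrics -------------------------------------
    weight: float = 80.0          # kg
    height: float = 170.0         # cm
    sex: str = "M"
    Hct: float = 0.42             # hematocrit, fraction
    K_blood: float = 4.2          # mEq/L plasma potassium
    Urea: float = 30.0            # mg/dl blood urea
    Na_conc: float = 142.0        # mEq/L plasma sodium

    # --- cardiac ---------------------------------------------------------
    SVmax: float = 228.6          # ml, theoretical maximum stroke volume
    KL0: float = 0.40             # LV inotropic state, in [0.2, 0.8]
    KR0: float = 0.40             # RV inotropic state
    EDVmax_L: float = 375.0       # ml, LV filling-map saturation
    EDVmax_R: float = 375.0       # ml
    kf_L: float = 29.6            # mmHg, LV filling-map pressure constant
    kf_R: float = 19.7            # mmHg, RV filling-map pressure constant
    HR_base: float = 75.0         # beats/min at neutral autonomic drive
    HR_ref: float = 75.0          # beats/min reference for rate-dependent filling
    dP_valve: float = 18.0        # mmHg, LV peak systolic minus aortic systolic

    # --- circulation -----------------------------------------------------
    Ca: float = 1.25              # ml/mmHg arterial compliance
    Cv: float = 100.0             # ml/mmHg systemic venous compliance
    Cpv: float = 25.0             # ml/mmHg pulmonary venous compliance
    Vu: float = 3800.0            # ml unstressed systemic venous volume
    V_pv_u: float = 350.0         # ml unstressed pulmonary venous volume
    R_micro0: float = 0.0205      # mmHg·min/ml systemic microvessel resistance
    MAP_set: float = 120.0        # mmHg baroreflex set point

    # --- renal -----------------------------------------------------------
    R_pre0: float = 0.042         # mmHg·min/ml pre-glomerular arteries
    R_aa0: float = 0.026          # mmHg·min/ml afferent arterioles
    R_ea0: float = 0.048          # mmHg·min/ml efferent (and post-glomerular)
    KfG0: float = 14.3            # ml/min/mmHg glomerular filtration coefficient
    f_prox: float = 0.92          # fractional proximal sodium reabsorption
    f_dist0: float = 0.91         # fractional distal sodium reabsorption
    Phi_sod_in: float = 0.10      # mEq/min sodium intake
    MAP_ref: float = 120.0        # mmHg renal reference pressure
    NaDel_ref: float = 1.14       # mEq/min reference distal sodium delivery
    GFR_ref: float = 100.0        # ml/min tubuloglomerular-feedback reference
    RBF_ref: float = 1000.0       # ml/min reference renal blood flow
    P_out: float = 4.0            # mmHg renal outflow pressure
    P_net: float = 45.0           # mmHg Bowman + oncotic opposing pressure

    # --- fluid volumes ---------------------------------------------------
    ECFV0: float = 16.0           # L extracellular fluid volume reference
    k_plasma: float = 0.18        # blood plasma as fraction of ECFV

    # --- RAAS references (normalized units) ------------------------------
    PRC0: float = 1.0
    AngI0: float = 1.0
    AngII0: float = 1.0
    AT1B0: float = 1.0
    ALD0: float = 1.0

    # --- neurohumoral sensitivities (recalibrated by the pipeline) -------
    sl_baro: float = 0.5          # AT1-bound AngII modulation of baroreflex gain
    sl_stress: float = 0.3        # ... of stress-receptor activity
    sl_KFG: float = -0.04         # exponent: filtration coefficient ~ AT1B^sl_KFG

    # --- structural gains of the reduced closures ------------------------
    H0: float = 1.0               # neutral neurohumoral factor
    g_b: float = 4.0              # baroreflex gain into H
    g_s: float = 0.3              # stress-activity afferent gain into H
    k_H: float = 0.25             # slope of the sympathetic inotropic sigmoid
    alpha_H: float = 0.35         # chronotropic gain of H
    alpha_S: float = 0.15         # chronotropic gain of stress activity
    h_sym: float = 0.5            # sympathetic share of resting heart rate
    g_H: float = 0.05             # H gain on systemic resistance
    g_ANG: float = 0.12           # AT1-bound AngII gain on systemic resistance
    g_ald: float = 0.4            # aldosterone exponent on distal reabsorption
    p_ald: float = 0.3            # AT1B exponent of aldosterone secretion
    q_ald: float = 3.0            # potassium exponent of aldosterone secretion
    n1: float = 2.0               # renal-pressure exponent of renin secretion
    n2: float = 1.15          # macula-densa exponent of renin secretion
    e_aa: float = 0.02            # AT1B exponent, afferent resistance
    e_ea: float = 0.06            # AT1B exponent, efferent resistance
    m_auto: float = 2.5           # myogenic autoregulation exponent (pre-glom)
    tgf: float = 2.0              # tubuloglomerular-feedback exponent (afferent)
    a_pn: float = 0.25            # pressure-natriuresis exponent (proximal)
    a_v: float = 0.8              # ECFV exponent on proximal reabsorption
    a_rbf: float = 0.10           # renal-blood-flow exponent on proximal reabsorption
    s_filt: float = 0.5           # sublinearity of filtration in net pressure
    p_glom_margin0: float = 15.0  # mmHg reference net filtration pressure
    c_a: float = 0.5              # pressure dependence of arterial compliance
    P_floor_fill: float = -4.0    # mmHg, filling-map pressure offset

    # --- derived at construction time ------------------------------------
    V_blood0: float = 4.98        # L drug-free total blood volume (Nadler)
    bsa: float = 1.92             # m² Du Bois body surface area

    def copy(self, **changes) -> "PatientParameters":
        return replace(self, **changes)


def build_patient(
    *,
    sbp: float,
    dbp: float,
    hr: float,
    weight: float,
    height: float,
    sex: str = "M",
    co_lpm: float = 6.0,
    hct: float = 0.42,
    ef_pct: float = 60.0,
    cvp0: float = 4.0,
    pvp0: float = 8.0,
    gfr0: float = 100.0,
    rbf0: float = 1000.0,
    rho_pre: float = 0.62,
    f_prox: float = 0.92,
    phi_sod_in: float = 0.10,
    ecfv_per_kg: float = 0.20,
    p_glom_margin: float = 15.0,
    **structural,
) -> PatientParameters:
    """Construct a patient whose drug-free equilibrium hits the targets.

    ``sbp``/``dbp``/``hr`` are the clinical targets; ``co_lpm``, ``hct``,
    ``ef_pct``, ``gfr0``, ``rbf0`` etc. are the unmeasured boundary values
    (drawn from physiological ranges by the generator).  Dependent
    parameters — compliances, resistances, inotropic states, unstressed
    volumes, renal reference values — are derived so that the target state
    is an exact fixed point of the drug-free dynamics.

    Raises ``ValueError`` when the draw is physiologically unrealizable
    (e.g., the implied inotropic state leaves [0.2, 0.8]); the generator
    treats that as an infeasible candidate.
    """
    pp = sbp - dbp
    if pp <= 0:
        raise ValueError("need SBP > DBP")
    map0 = dbp + pp / 3.0
    co = co_lpm * 1000.0                      # ml/min
    sv0 = co / hr                             # ml
    ca = sv0 / pp
    r_micro0 = (map0 - cvp0) / co
    if r_micro0 <= 0:
        raise ValueError("MAP must exceed CVP")

    svmax = 200.0 * weight / 70.0
    edv0 = sv0 / ef_pct * 100.0
    # import here to avoid a cycle: model.py needs PatientParameters
    from .model import delta_edv

    d0 = delta_edv(edv0)
    if d0 <= 0:
        raise ValueError("end-diastolic volume below the filling threshold")
    kl0 = sv0 / (svmax * d0)
    if not 0.2 <= kl0 <= 0.8:
        raise ValueError(f"implied inotropic state {kl0:.3f} outside [0.2, 0.8]")

    p_floor = structural.get("P_floor_fill", -4.0)
    fill0 = 1.0 / 3.0                          # baseline filling-map utilization
    kf_l = (pvp0 - p_floor) / (-math.log(1.0 - fill0))
    kf_r = (cvp0 - p_floor) / (-math.log(1.0 - fill0))
    edvmax = edv0 / fill0

    vb0 = nadler_blood_volume(height, weight, sex)
    ecfv0 = ecfv_per_kg * weight
    k_plasma = vb0 * (1.0 - hct) / ecfv0

    cv = structural.pop("Cv", 100.0)
    cpv = structural.pop("Cpv", 25.0)
    v_pv_u = structural.pop("V_pv_u", 350.0)
    v_pv0 = v_pv_u + cpv * pvp0
    vu = vb0 * 1000.0 - ca * map0 - v_pv0 - cv * cvp0
    if vu <= 0:
        raise ValueError("unstressed volume came out nonpositive")

    # renal series divider: pre+afferent drop to P_glom, efferent drop to P_out
    p_out = structural.get("P_out", 4.0)
    p_net = structural.get("P_net", 45.0)
    p_glom0 = p_net + p_glom_margin
    if not p_out < p_glom0 < map0:
        raise ValueError("glomerular pressure must lie between P_out and MAP")
    r_ea0 = (p_glom0 - p_out) / rbf0
    r_upstream = (map0 - p_glom0) / rbf0
    r_pre0 = rho_pre * r_upstream
    r_aa0 = (1.0 - rho_pre) * r_upstream
    kfg0 = gfr0 / p_glom_margin

    delivery0 = gfr0 * 142.0 / 1000.0 * (1.0 - f_prox)
    f_dist0 = 1.0 - phi_sod_in / delivery0
    if not 0.0 < f_dist0 < 1.0:
        raise ValueError("sodium intake incompatible with distal delivery")

    return PatientParameters(
        weight=weight, height=height, sex=sex, Hct=hct,
        SVmax=svmax, KL0=kl0, KR0=kl0,
        EDVmax_L=edvmax, EDVmax_R=edvmax, kf_L=kf_l, kf_R=kf_r,
        HR_base=hr, HR_ref=hr,
        Ca=ca, Cv=cv, Cpv=cpv, Vu=vu, V_pv_u=v_pv_u,
        R_micro0=r_micro0, MAP_set=map0,
        R_pre0=r_pre0, R_aa0=r_aa0, R_ea0=r_ea0, KfG0=kfg0, GFR_ref=gfr0,
        RBF_ref=rbf0, p_glom_margin0=p_glom_margin,
        f_prox=f_prox, f_dist0=f_dist0,
        Phi_sod_in=phi_sod_in, MAP_ref=map0, NaDel_ref=delivery0,
        ECFV0=ecfv0, k_plasma=k_plasma,
        V_blood0=vb0, bsa=du_bois_bsa(height, weight),
        **structural,
    )


def default_patient(**overrides) -> PatientParameters:
    """Reference uncomplicated-hypertension patient (160/100, HR 75, 80 kg)."""
    kw = dict(sbp=160.0, dbp=100.0, hr=75.0, weight=80.0, height=170.0)
    kw.update(overrides)
    return build_patient(**kw)
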