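"""Reduced-order cardiovascular–renal–RAAS model.

The model tracks five slow states — total exchangeable sodium, pulmonary
venous volume, plasma renin concentration, angiotensin I and angiotensin II —
and closes the beat-averaged hemodynamics and renal sodium handling
algebraically at each instant:

* **heart**: two Frank–Starling ventricles, ``SV = K·SVmax·δ(EDV)`` with
  ``K = K0 + 0.25·σ(H, K0)``; a saturating, rate-dependent filling map from
  the venous filling pressure to end-diastolic volume;
* **circulation**: arterial/venous/pulmonary-venous compliances partition the
  blood volume; mean arterial pressure solves ``MAP = HR·SV·SVR + CVP`` with
  the systemic resistance modulated by the neurohumoral factor H, AT1-bound
  angiotensin II and the vasodilating drugs;
* **baroreflex**: ``H`` rises when MAP falls below the set point; sympathetic
  chronotropic/inotropic drive follows H and stress-receptor activity and is
  gated by β-blockade;
* **kidney**: a three-resistor glomerular divider with myogenic
  autoregulation gives GFR and RBF; sodium excretion follows filtration,
  pressure-natriuresis on proximal reabsorption, and aldosterone-controlled
  distal reabsorption;
* **RAAS**: renin secretion responds to renal perfusion pressure and distal
  sodium delivery; the renin → Ang I → Ang II → AT1 cascade uses first-order
  kinetics whose rate constants are derived from the drug-free baselines, so
  the configured baseline is an exact fixed point.

Every drug target of the pharmacodynamic layer is an explicit multiplicative
site in these closures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .drugs import DrugRegimen, PDEffects, regimen_effects
from .params import PatientParameters

__all__ = [
    "ModelState", "EquilibriumState", "Trajectory",
    "delta_edv", "sigma", "frank_starling_sv",
    "hemodynamic_closure", "renal_fluxes", "raas_rates", "derivatives",
    "baseline_state", "simulate", "find_equilibrium", "polish_equilibrium",
    "observe", "detect_cardiogenic_shock",
    "EquilibriumError", "IntegrationError",
]

# δ(EDV) surrogate constants (ml); overridable via function arguments.
DELTA_V_U_FILL = 10.0
DELTA_K_RISE = 60.0
DELTA_V_CRIT = 180.0
DELTA_K_FALL = 0.002

#: Relative-rate scales (s) used to normalize equilibrium residuals.
_RESIDUAL_TAU = np.array([86400.0, 600.0, 3600.0, 300.0, 300.0])


class EquilibriumError(RuntimeError):
    """No equilibrium found (used by the generator to reject a draw)."""


class IntegrationError(RuntimeError):
    pass


@dataclass
class ModelState:
    """Slow states: sodium mass, pulmonary venous volume, RAAS species."""

    Na_tot: float     # mEq total exchangeable sodium
    V_pv: float       # ml pulmonary venous volume
    PRC: float        # plasma renin concentration (normalized)
    AngI: float
    AngII: float

    def as_array(self) -> np.ndarray:
        return np.array([self.Na_tot, self.V_pv, self.PRC, self.AngI, self.AngII])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(*map(float, y))


@dataclass
class EquilibriumState:
    """Full observable set at one (quasi-)steady operating point."""

    SBP: float; DBP: float; MAP: float; CVP: float; PVP: float
    LVEDP: float; LVPSP: float
    HR: float; SV: float; EDV: float; ESV: float; EF: float
    CO: float                        # L/min
    SVR: float                       # dyn·s/cm^5
    ECFV: float; V_blood: float      # L
    GFR: float; RBF: float           # ml/min
    RVR: float                       # mmHg·min/ml
    R_aa: float                      # mmHg·min/ml effective afferent resistance
    FF: float                        # %
    PRA: float; PRC: float; AngI: float; AngII: float; AT1B: float; ALD: float
    Na_excretion: float              # mEq/min
    H: float
    state: ModelState = None

    def asdict(self) -> dict[str, float]:
        d = {k: v for k, v in self.__dict__.items() if k != "state"}
        return d


@dataclass
class Trajectory:
    t: np.ndarray                    # s, strictly increasing
    states: np.ndarray               # (n, 5)
    params: PatientParameters
    regimen: DrugRegimen
    gains: dict | None = None
    _obs: dict | None = field(default=None, repr=False)

    def observables(self) -> dict[str, np.ndarray]:
        """Per-time-point observables (computed lazily, cached)."""
        if self._obs is None:
            cols: dict[str, list[float]] = {}
            for ti, yi in zip(self.t, self.states):
                pd_t = regimen_effects(self.regimen, ti, self.gains)
                eq = _observe(yi, self.params, pd_t)
                for k, v in eq.asdict().items():
                    cols.setdefault(k, []).append(v)
            self._obs = {k: np.asarray(v) for k, v in cols.items()}
        return self._obs

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_s": self.t, **self.observables()})


# ----------------------------------------------------------------------
# elementary cardiac closures
# ----------------------------------------------------------------------

def delta_edv(edv: float, v_u_fill: float = DELTA_V_U_FILL,
              k_rise: float = DELTA_K_RISE, v_crit: float = DELTA_V_CRIT,
              k_fall: float = DELTA_K_FALL) -> float:
    """Bell-shaped ejection-effectiveness factor δ(EDV) ∈ [0, 1].

    Rises with filling (saturating exponential above the unstressed volume)
    and declines beyond the overdistension volume ``v_crit`` — the declining
    branch is what lets a failing, congested ventricle spiral into shock.
    """
    if edv < 0:
        raise ValueError("EDV must be nonnegative")
    rise = max(0.0, 1.0 - math.exp(-(edv - v_u_fill) / k_rise))
    fall = 1.0 - k_fall * max(0.0, edv - v_crit)
    return min(1.0, max(0.0, rise * max(0.0, fall)))


def sigma(H: float, K0: float, k_H: float = 0.25, H0: float = 1.0) -> float:
    """Sympathetic inotropic modulation σ(H, K0) ∈ (−1, 1)·headroom.

    Zero at neutral drive; scaled by the inotropic headroom (0.8 − K0)/0.6
    so the effective contractility K = K0 + 0.25·σ stays inside (0, 1).
    """
    if not 0.2 <= K0 <= 0.8:
        raise ValueError(f"K0 must lie in [0.2, 0.8], got {K0}")
    s = 2.0 / (1.0 + math.exp(-k_H * (H - H0))) - 1.0
    return s * (0.8 - K0) / 0.6


def frank_starling_sv(edv: float, K0: float, H: float, svmax: float,
                      k_H: float = 0.25, H0: float = 1.0,
                      beta_block: float = 0.0) -> float:
    """Stroke volume ``SV = (K0 + 0.25·σ)·SVmax·δ(EDV)``.

    β-blockade gates the sympathetic inotropic term (the receptor the
    catecholamines would act on is occupied).
    """
    if svmax <= 0:
        raise ValueError("SVmax must be positive")
    k = K0 + 0.25 * sigma(H, K0, k_H, H0) * (1.0 - beta_block)
    return k * svmax * delta_edv(edv)


# ----------------------------------------------------------------------
# algebraic closures
# ----------------------------------------------------------------------

def _fill_edv(p_fill: float, edvmax: float, kf: float, p_floor: float,
              hr: float, hr_ref: float) -> float:
    """Saturating, rate-dependent venous filling map."""
    kf_eff = kf * max(hr / hr_ref, 0.25)   # less diastole at higher rate
    x = max(p_fill - p_floor, 0.0) / kf_eff
    return edvmax * (1.0 - math.exp(-x))


def _at1_ratio(ang2: float, p: PatientParameters, pd: PDEffects) -> float:
    """AT1-bound angiotensin II relative to baseline (clipped away from 0)."""
    return max((1.0 - pd.ARB) * ang2 / p.AngII0, 1e-3)


def _hemo_at_map(m: float, y: np.ndarray, p: PatientParameters,
                 pd: PDEffects) -> dict:
    """All hemodynamic quantities at a candidate MAP value."""
    na_tot, v_pv, _, _, ang2 = y
    at1r = _at1_ratio(ang2, p, pd)
    ecfv = na_tot / p.Na_conc                           # L
    v_blood = 1000.0 * p.k_plasma * ecfv / (1.0 - p.Hct)  # ml
    pvp = (v_pv - p.V_pv_u) / p.Cpv
    cvp = (v_blood - p.Ca * m - v_pv - p.Vu) / p.Cv

    s_act = (1.0 - pd.Diureticstress) * max(0.0, 1.0 + p.sl_stress * (at1r - 1.0))
    baro_mod = min(max(1.0 + p.sl_baro * (at1r - 1.0), 0.1), 1.0)
    h = p.H0 + p.g_b * (p.MAP_set - m) / p.MAP_set * baro_mod \
        + p.g_s * (s_act - 1.0)
    h = min(max(h, 0.0), 6.0)

    d_sym = max(0.0, 1.0 + p.alpha_H * (h - p.H0) + p.alpha_S * (s_act - 1.0))
    hr = p.HR_base * ((1.0 - p.h_sym) + p.h_sym * (1.0 - pd.Bblocker) * d_sym)
    hr = min(max(hr, 20.0), 220.0)

    ca_eff = p.Ca * (p.MAP_set / max(m, 20.0)) ** p.c_a
    edv_l = _fill_edv(pvp, p.EDVmax_L, p.kf_L, p.P_floor_fill, hr, p.HR_ref)
    edv_r = _fill_edv(cvp, p.EDVmax_R, p.kf_R, p.P_floor_fill, hr, p.HR_ref)
    sv_l = frank_starling_sv(edv_l, p.KL0, h, p.SVmax, p.k_H, p.H0, pd.Bblocker)
    sv_r = frank_starling_sv(edv_r, p.KR0, h, p.SVmax, p.k_H, p.H0, pd.Bblocker)

    # AngII pressor effect saturates at both ends (receptor occupancy)
    ang_tone = min(max(at1r ** p.g_ANG, 0.72), 1.08)
    svr = p.R_micro0 * (1.0 - pd.CCBsys) * (1.0 - pd.Diureticsys) \
        * (1.0 + p.g_H * (h - p.H0)) * ang_tone
    svr = max(svr, 1e-5)
    return dict(at1r=at1r, ecfv=ecfv, v_blood=v_blood, pvp=pvp, cvp=cvp,
                s_act=s_act, H=h, HR=hr, edv_l=edv_l, edv_r=edv_r,
                sv_l=sv_l, sv_r=sv_r, svr=svr, ca_eff=ca_eff)


def hemodynamic_closure(y: np.ndarray | ModelState, p: PatientParameters,
                        pd: PDEffects) -> dict:
    """Solve the beat-averaged pressure fixed point ``MAP = HR·SV·SVR + CVP``.

    The residual is strictly increasing in MAP (baroreflex, Frank–Starling
    and compliance couplings all push the right-hand side down as MAP rises),
    so a bracketing scalar root find is reliable.
    """
    if isinstance(y, ModelState):
        y = y.as_array()

    def resid(m: float) -> float:
        hm = _hemo_at_map(m, y, p, pd)
        return m - (hm["HR"] * hm["sv_l"] * hm["svr"] + hm["cvp"])

    lo, hi = 5.0, 400.0
    rlo, rhi = resid(lo), resid(hi)
    if rlo > 0 or rhi < 0:      # extreme states: expand downward
        lo = 0.5
        rlo = resid(lo)
        if rlo > 0 or rhi < 0:
            raise EquilibriumError("pressure closure failed to bracket a root")
    m = brentq(resid, lo, hi, xtol=1e-10, rtol=1e-12)
    hm = _hemo_at_map(m, y, p, pd)
    hm["MAP"] = m
    hm["PP"] = hm["sv_l"] / hm["ca_eff"]
    hm["SBP"] = m + 2.0 * hm["PP"] / 3.0
    hm["DBP"] = m - hm["PP"] / 3.0
    return hm


def renal_fluxes(y: np.ndarray | ModelState, p: PatientParameters,
                 pd: PDEffects, MAP: float) -> dict:
    """Renal hemodynamics and sodium handling at a given perfusion pressure.

    Pre-glomerular resistance carries myogenic autoregulation; afferent and
    efferent tone follow AT1-bound Ang II (efferent more sensitively);
    proximal reabsorption carries pressure natriuresis; distal reabsorption
    follows aldosterone and the thiazide site.
    """
    if isinstance(y, ModelState):
        y = y.as_array()
    at1r = _at1_ratio(y[4], p, pd)
    if MAP <= p.P_out:
        raise EquilibriumError("renal perfusion pressure below outflow pressure")

    r_pre = p.R_pre0 * (MAP / p.MAP_ref) ** p.m_auto \
        * (1.0 - pd.CCBpreglom) * (1.0 - pd.Diureticpreglom)
    r_aa_base = p.R_aa0 * (1.0 - pd.CCBaa) * (1.0 - pd.Diureticaa) * at1r ** p.e_aa
    r_ea = p.R_ea0 * (1.0 - pd.CCBea) * (1.0 - pd.Diureticea) * at1r ** p.e_ea
    if min(r_pre, r_aa_base, r_ea) <= 0:
        raise EquilibriumError("nonpositive renal resistance after drug effects")

    kfg_mod = min(max(at1r ** p.sl_KFG, 0.5), 2.0)
    ecfv = y[0] / p.Na_conc
    f_prox_base = p.f_prox * (MAP / p.MAP_ref) ** (-p.a_pn) \
        * (ecfv / p.ECFV0) ** (-p.a_v)

    def eval_at(r_aa: float) -> tuple[float, float, float, float, float]:
        r_tot = r_pre + r_aa + r_ea
        rbf = (MAP - p.P_out) / r_tot
        p_glom = MAP - rbf * (r_pre + r_aa)
        # filtration saturates in net pressure (filtration-pressure
        # equilibrium along the capillary)
        margin = max(p_glom - p.P_net, 0.0)
        gfr = p.KfG0 * kfg_mod * p.p_glom_margin0 \
            * (margin / p.p_glom_margin0) ** p.s_filt
        # peritubular washout: higher renal flow depresses proximal uptake
        f_prox_eff = f_prox_base * (rbf / p.RBF_ref) ** (-p.a_rbf)
        f_prox_eff = min(max(f_prox_eff, 0.85), 0.985)
        delivery = gfr * p.Na_conc / 1000.0 * (1.0 - f_prox_eff)
        return rbf, p_glom, gfr, delivery, f_prox_eff

    # tubuloglomerular feedback: afferent tone rises with the filtered load;
    # solved as an inner fixed point (the map is a contraction: more tone →
    # less filtration).  Sensing filtration rather than late-distal delivery
    # stabilizes GFR against hemodynamic and drug-induced swings while
    # letting reabsorption-side natriuresis signals pass through.
    def tgf_factor(gfr: float) -> float:
        return min(max((gfr / p.GFR_ref) ** p.tgf, 0.1), 8.0)

    fac = 1.0
    for _ in range(80):
        rbf, p_glom, gfr, delivery, f_prox_eff = eval_at(r_aa_base * fac)
        fac_new = tgf_factor(gfr)
        if abs(fac_new - fac) < 1e-12:
            break
        fac = 0.5 * (fac + fac_new)
    r_aa = r_aa_base * fac
    rbf, p_glom, gfr, delivery, f_prox_eff = eval_at(r_aa)
    r_tot = r_pre + r_aa + r_ea

    ald = p.ALD0 * at1r ** p.p_ald * (1.0 - pd.Diureticpotassium) ** p.q_ald
    f_dist_eff = p.f_dist0 * (ald / p.ALD0) ** p.g_ald * (1.0 - pd.DiureticInhibition)
    f_dist_eff = min(max(f_dist_eff, 0.0), 0.999)
    na_exc = delivery * (1.0 - f_dist_eff)

    return dict(GFR=gfr, RBF=rbf, RVR=r_tot, P_glom=p_glom, R_aa=r_aa,
                Na_excretion=na_exc, distal_delivery=delivery,
                ALD=ald, FF=gfr / (rbf * (1.0 - p.Hct)) * 100.0)


def raas_rates(y: np.ndarray | ModelState, p: PatientParameters,
               pd: PDEffects, MAP_renal: float,
               distal_delivery: float) -> dict:
    """Renin–angiotensin cascade rates (1/s) and algebraic species.

    Rate constants are fixed by the normalized drug-free baselines, so with
    all drug effects zero and reference signals the cascade is at rest.
    """
    from .params import K_ACE, K_AT1, K_DEG, K_NONACE, K_REN

    if isinstance(y, ModelState):
        y = y.as_array()
    _, _, prc, ang1, ang2 = y
    MAP_renal = max(MAP_renal, 1.0)
    distal_delivery = max(distal_delivery, 1e-9)

    pra0 = (K_ACE + K_NONACE) * p.AngI0
    k_act = pra0 / p.PRC0
    r_sec0 = K_REN * p.PRC0

    press = min(max((p.MAP_ref / MAP_renal) ** p.n1, 0.33), 3.0)
    macula = min(max((p.NaDel_ref / distal_delivery) ** p.n2, 0.5), 2.0)
    r_sec = r_sec0 * (1.0 - pd.Bblocker_rs) * (1.0 + pd.DiureticStimulation) \
        * min(max(press * macula, 0.05), 10.0)

    pra = k_act * prc * (1.0 - pd.DRI)
    d_prc = r_sec - K_REN * prc
    d_ang1 = pra - (K_ACE * (1.0 - pd.ACEi) + K_NONACE) * ang1
    d_ang2 = K_ACE * (1.0 - pd.ACEi) * ang1 - (K_AT1 * (1.0 - pd.ARB) + K_DEG) * ang2
    at1b = (1.0 - pd.ARB) * ang2 / p.AngII0 * p.AT1B0

    out = dict(PRA=pra, dPRC=d_prc, dAngI=d_ang1, dAngII=d_ang2, AT1B=at1b)
    if not all(math.isfinite(v) for v in out.values()):
        raise EquilibriumError(f"non-finite RAAS rates at state {y}")
    return out


# ----------------------------------------------------------------------
# assembled dynamics
# ----------------------------------------------------------------------

def derivatives(y: np.ndarray | ModelState, p: PatientParameters,
                pd: PDEffects, t: float = 0.0) -> np.ndarray:
    """Time derivatives (per second) of the five slow states."""
    if isinstance(y, ModelState):
        y = y.as_array()
    hm = hemodynamic_closure(y, p, pd)
    rn = renal_fluxes(y, p, pd, hm["MAP"])
    rr = raas_rates(y, p, pd, hm["MAP"], rn["distal_delivery"])
    d_na = (p.Phi_sod_in - rn["Na_excretion"]) / 60.0
    d_vpv = hm["HR"] * (hm["sv_r"] - hm["sv_l"]) / 60.0
    dy = np.array([d_na, d_vpv, rr["dPRC"], rr["dAngI"], rr["dAngII"]])
    if not np.all(np.isfinite(dy)):
        raise EquilibriumError(f"non-finite derivatives at state {y}")
    return dy


def _observe(y: np.ndarray, p: PatientParameters, pd: PDEffects) -> EquilibriumState:
    hm = hemodynamic_closure(y, p, pd)
    rn = renal_fluxes(y, p, pd, hm["MAP"])
    rr = raas_rates(y, p, pd, hm["MAP"], rn["distal_delivery"])
    sv, edv = hm["sv_l"], hm["edv_l"]
    co = hm["HR"] * sv / 1000.0
    return EquilibriumState(
        SBP=hm["SBP"], DBP=hm["DBP"], MAP=hm["MAP"], CVP=hm["cvp"],
        PVP=hm["pvp"], LVEDP=hm["pvp"], LVPSP=hm["SBP"] + p.dP_valve,
        HR=hm["HR"], SV=sv, EDV=edv, ESV=edv - sv, EF=sv / edv * 100.0,
        CO=co, SVR=hm["svr"] * 79993.2,
        ECFV=hm["ecfv"], V_blood=hm["v_blood"] / 1000.0,
        GFR=rn["GFR"], RBF=rn["RBF"], RVR=rn["RVR"], R_aa=rn["R_aa"],
        FF=rn["FF"],
        PRA=rr["PRA"] * 27.0,      # normalized so the drug-free baseline is 1
        PRC=y[2], AngI=y[3], AngII=y[4], AT1B=rr["AT1B"], ALD=rn["ALD"],
        Na_excretion=rn["Na_excretion"], H=hm["H"],
        state=ModelState.from_array(y),
    )


def baseline_state(p: PatientParameters) -> ModelState:
    """The constructed drug-free operating point of a patient."""
    pvp0 = p.P_floor_fill + p.kf_L * math.log(1.5)
    return ModelState(
        Na_tot=p.ECFV0 * p.Na_conc,
        V_pv=p.V_pv_u + p.Cpv * pvp0,
        PRC=p.PRC0, AngI=p.AngI0, AngII=p.AngII0,
    )


def observe(y, p: PatientParameters,
            regimen: DrugRegimen = DrugRegimen.none(), t: float = 0.0,
            gains: dict | None = None) -> EquilibriumState:
    """Observables of an arbitrary state under a regimen at model time t."""
    if isinstance(y, ModelState):
        y = y.as_array()
    return _observe(np.asarray(y, dtype=float), p,
                    regimen_effects(regimen, t, gains))


def simulate(p: PatientParameters, regimen: DrugRegimen = DrugRegimen.none(),
             t_end: float = 2_419_200.0, y0: ModelState | None = None,
             gains: dict | None = None, n_out: int = 200,
             rtol: float = 1e-7, atol: float = 1e-8) -> Trajectory:
    """Integrate the slow dynamics for ``t_end`` seconds under a regimen.

    The pharmacodynamic effects are re-evaluated along the trajectory so the
    thiazide systemic ramp is time-resolved.  Stiff-capable LSODA handles the
    ~30 s RAAS turnover alongside the multi-day sodium dynamics.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y_init = (y0 or baseline_state(p)).as_array()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return derivatives(y, p, regimen_effects(regimen, t, gains), t)

    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(rhs, (0.0, t_end), y_init, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else 0:.0f} s: "
            f"{sol.message}")
    return Trajectory(t=sol.t, states=sol.y.T, params=p, regimen=regimen,
                      gains=dict(gains) if gains else None)


def equilibrium_residual(y: np.ndarray, p: PatientParameters,
                         pd: PDEffects) -> float:
    """Max relative rate of change (per characteristic time) — 0 at rest."""
    dy = derivatives(y, p, pd)
    scale = np.maximum(np.abs(y), 1e-6)
    return float(np.max(np.abs(dy) * _RESIDUAL_TAU / scale))


def find_equilibrium(p: PatientParameters,
                     regimen: DrugRegimen = DrugRegimen.none(),
                     y0: ModelState | None = None,
                     gains: dict | None = None,
                     tol: float = 1e-8) -> EquilibriumState:
    """Solve ``derivatives = 0`` with the thiazide ramp at saturation.

    Seeded from the constructed baseline (or a supplied state); if direct
    root finding stalls, a long pre-simulation re-seeds it.  Raises
    :class:`EquilibriumError` when no root with residual < ``tol`` exists —
    the population generator treats that as a rejected draw.
    """
    pd = regimen_effects(regimen, t=HCTZ_RAMP_AT_SATURATION, gain=gains)
    y_init = (y0 or baseline_state(p)).as_array()
    scale = np.maximum(np.abs(y_init), 1e-3)

    def fun(z: np.ndarray) -> np.ndarray:
        # log-parameterization keeps every state positive
        y = scale * np.exp(np.clip(z, -30.0, 30.0))
        try:
            return derivatives(y, p, pd) * _RESIDUAL_TAU / scale
        except (EquilibriumError, FloatingPointError, OverflowError):
            return np.full(5, 1e6)

    # already at rest? (constructed baselines are exact fixed points)
    try:
        if equilibrium_residual(y_init, p, pd) < tol:
            return _observe(y_init, p, pd)
    except (EquilibriumError, FloatingPointError, OverflowError):
        raise EquilibriumError("initial state is not evaluable")

    def polish(seed: np.ndarray):
        sol = root(fun, np.log(np.maximum(seed, 1e-12) / scale), method="hybr",
                   options={"xtol": 1e-13, "maxfev": 4000})
        cand = scale * np.exp(np.clip(sol.x, -30.0, 30.0))
        try:
            return cand, equilibrium_residual(cand, p, pd)
        except (EquilibriumError, FloatingPointError, OverflowError):
            return cand, math.inf

    # follow the dynamical branch: relax by simulation, then polish the root
    best = None
    seed = y_init
    for t_relax in (3_000_000.0, 6_000_000.0):
        try:
            traj = simulate(p, regimen, t_end=t_relax,
                            y0=ModelState.from_array(seed), gains=gains, n_out=4)
            seed = traj.states[-1]
        except (IntegrationError, EquilibriumError):
            break
        cand, r = polish(seed)
        if best is None or r < best[1]:
            best = (cand, r)
        if r < tol:
            break
    if best is None or best[1] >= tol:
        cand, r = polish(y_init)    # last resort: direct root from the seed
        if best is None or r < best[1]:
            best = (cand, r)
    if best[1] >= tol:
        raise EquilibriumError(f"no equilibrium (best residual {best[1]:.3e})")
    return _observe(best[0], p, pd)


#: Evaluation time placing the HCTZ systemic ramp at its plateau.
HCTZ_RAMP_AT_SATURATION = 4_000_000.0


def polish_equilibrium(p: PatientParameters,
                       regimen: DrugRegimen = DrugRegimen.none(),
                       y_seed: ModelState | np.ndarray | None = None,
                       gains: dict | None = None,
                       tol: float = 1e-8) -> EquilibriumState:
    """Root-only equilibrium solve from a nearby seed state.

    Much faster than :func:`find_equilibrium` (no relaxation simulation);
    intended for calibration loops where successive evaluations differ by a
    small parameter perturbation and the previous solution seeds the next.
    Raises :class:`EquilibriumError` if the root does not converge — callers
    fall back to the full solver.
    """
    pd = regimen_effects(regimen, t=HCTZ_RAMP_AT_SATURATION, gain=gains)
    if y_seed is None:
        y_seed = baseline_state(p)
    if isinstance(y_seed, ModelState):
        y_seed = y_seed.as_array()
    y_seed = np.asarray(y_seed, dtype=float)
    scale = np.maximum(np.abs(y_seed), 1e-3)

    def fun(z: np.ndarray) -> np.ndarray:
        y = scale * np.exp(np.clip(z, -30.0, 30.0))
        try:
            return derivatives(y, p, pd) * _RESIDUAL_TAU / scale
        except (EquilibriumError, FloatingPointError, OverflowError):
            return np.full(5, 1e6)

    sol = root(fun, np.log(np.maximum(y_seed, 1e-12) / scale), method="hybr",
               options={"xtol": 1e-13, "maxfev": 2000})
    cand = scale * np.exp(np.clip(sol.x, -30.0, 30.0))
    r = equilibrium_residual(cand, p, pd)
    if r >= tol:
        raise EquilibriumError(f"root polish failed (residual {r:.3e})")
    return _observe(cand, p, pd)


# ----------------------------------------------------------------------
# cardiogenic shock detection
# ----------------------------------------------------------------------

def detect_cardiogenic_shock(traj: Trajectory,
                             p: PatientParameters | None = None,
                             min_duration_s: float = 1800.0
                             ) -> tuple[bool, float | None]:
    """Scan a trajectory for sustained cardiogenic shock.

    Verdict is true iff, over a contiguous window of at least 30 minutes,
    SBP < 90 mmHg *and* cardiac index < 2.2 L/min/m² *and* pulmonary venous
    pressure > 15 mmHg simultaneously.  Returns (verdict, onset time in s).
    """
    p = p or traj.params
    if p.height <= 0 or p.weight <= 0:
        raise ValueError("height and weight required for body surface area")
    if traj.t[-1] - traj.t[0] < min_duration_s:
        raise ValueError("trajectory must cover at least the 30 min window")
    obs = traj.observables()
    ci = obs["CO"] / p.bsa
    crit = (obs["SBP"] < 90.0) & (ci < 2.2) & (obs["PVP"] > 15.0)
    t = traj.t
    start = None
    for i, flag in enumerate(crit):
        if flag:
            if start is None:
                start = t[i]
            if t[i] - start >= min_duration_s:
                return True, float(start)
        else:
            start = None
    # window may run into the trajectory end
    if start is not None and t[-1] - start >= min_duration_s:
        return True, float(start)
    return False, None
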