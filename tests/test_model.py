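"""Core physiology: cardiac closures, equilibria, dynamics, shock."""

import numpy as np
import pytest

from hypertx import (DrugRegimen, EquilibriumError, ModelState,
                     baseline_state, build_patient, default_patient,
                     delta_edv, derivatives, detect_cardiogenic_shock,
                     find_equilibrium, frank_starling_sv, observe,
                     polish_equilibrium, renal_fluxes, raas_rates, sigma,
                     simulate)
from hypertx.drugs import Drug, PDEffects, parse_regimen, regimen_effects
from hypertx.model import Trajectory, equilibrium_residual

PD0 = PDEffects()


class TestDeltaEdv:
    def test_zero_below_filling_threshold(self):
        assert delta_edv(0.0) == 0.0
        assert delta_edv(10.0) == 0.0

    def test_saturates_below_overdistension(self):
        assert delta_edv(175.0) > 0.9

    def test_unimodal_on_physiologic_range(self):
        # grid-scan oracle: exactly one sign change of the slope on [0, 400]
        grid = np.linspace(0.0, 400.0, 4001)
        vals = np.array([delta_edv(v) for v in grid])
        slopes = np.sign(np.diff(vals))
        changes = np.sum(np.abs(np.diff(slopes[slopes != 0])) > 0)
        assert changes == 1

    def test_negative_edv_rejected(self):
        with pytest.raises(ValueError):
            delta_edv(-1.0)


class TestSigma:
    def test_zero_at_neutral_drive(self):
        assert sigma(1.0, 0.5) == 0.0

    def test_no_headroom_at_max_inotropy(self):
        assert sigma(3.0, 0.8) == 0.0

    def test_strictly_increasing_in_drive(self):
        hs = np.linspace(0.0, 3.0, 50)
        vals = [sigma(h, 0.4) for h in hs]
        assert np.all(np.diff(vals) > 0)

    def test_out_of_range_inotropy_rejected(self):
        with pytest.raises(ValueError):
            sigma(1.0, 0.1)


class TestFrankStarling:
    def test_neutral_drive_reduces_to_k0(self):
        sv = frank_starling_sv(130.0, 0.5, H=1.0, svmax=200.0)
        assert sv == pytest.approx(0.5 * 200.0 * delta_edv(130.0))

    def test_svmax_scales_with_weight(self):
        p = default_patient(weight=70.0)
        assert p.SVmax == pytest.approx(200.0)

    def test_curves_ordered_by_inotropic_state(self):
        # pointwise ordering of the SV-EDV curves over a K0 grid
        edvs = np.linspace(20.0, 350.0, 34)
        k0s = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        for lo, hi in zip(k0s[:-1], k0s[1:]):
            for edv in edvs:
                if delta_edv(edv) == 0.0:
                    continue
                assert frank_starling_sv(edv, lo, 1.0, 200.0) < \
                    frank_starling_sv(edv, hi, 1.0, 200.0)

    def test_bounded_by_svmax(self):
        assert frank_starling_sv(300.0, 0.8, 5.0, 200.0) <= 200.0


class TestBaselineEquilibrium:
    def test_constructed_baseline_is_exact_fixed_point(self, reference_patient):
        y0 = baseline_state(reference_patient).as_array()
        dy = derivatives(y0, reference_patient, PD0)
        assert np.max(np.abs(dy)) < 1e-9

    def test_find_equilibrium_returns_baseline(self, reference_patient,
                                               reference_equilibrium):
        eq = find_equilibrium(reference_patient)
        assert eq.SBP == pytest.approx(reference_equilibrium.SBP, abs=1e-6)
        assert eq.MAP == pytest.approx(reference_patient.MAP_set, abs=1.0)

    def test_ejection_fraction_identity(self, reference_equilibrium):
        eq = reference_equilibrium
        assert eq.EF == eq.SV / eq.EDV * 100.0
        assert eq.CO == pytest.approx(eq.HR * eq.SV / 1000.0)
        assert eq.DBP < eq.MAP < eq.SBP

    def test_conservation_at_equilibrium(self, reference_patient,
                                         reference_equilibrium):
        p, eq = reference_patient, reference_equilibrium
        assert abs(p.Phi_sod_in - eq.Na_excretion) / p.Phi_sod_in < 1e-6
        # ventricular output balance via the pulmonary-volume derivative
        dy = derivatives(eq.state, p, PD0)
        co_ml_s = eq.CO * 1000.0 / 60.0
        assert abs(dy[1]) / co_ml_s < 1e-6

    def test_filtration_fraction_definition(self, reference_patient,
                                            reference_equilibrium):
        eq = reference_equilibrium
        expected = eq.GFR / (eq.RBF * (1 - reference_patient.Hct)) * 100.0
        assert eq.FF == pytest.approx(expected)


class TestRaasAlgebra:
    def test_baseline_is_cascade_fixed_point(self, reference_patient):
        p = reference_patient
        y0 = baseline_state(p).as_array()
        rr = raas_rates(y0, p, PD0, p.MAP_ref, p.NaDel_ref)
        assert rr["dPRC"] == pytest.approx(0.0, abs=1e-12)
        assert rr["dAngI"] == pytest.approx(0.0, abs=1e-12)
        assert rr["dAngII"] == pytest.approx(0.0, abs=1e-12)

    def test_renin_inhibition_scales_activity(self, reference_patient):
        # at unchanged renin concentration and signals, plasma renin activity
        # is proportional to (1 - DRI): the 150 mg dose leaves 12.65 %
        p = reference_patient
        y0 = baseline_state(p).as_array()
        pd = regimen_effects(parse_regimen("aliskiren:150"))
        rr0 = raas_rates(y0, p, PD0, p.MAP_ref, p.NaDel_ref)
        rr = raas_rates(y0, p, pd, p.MAP_ref, p.NaDel_ref)
        assert rr["PRA"] / rr0["PRA"] == pytest.approx(1 - 0.99 * 150 / 170)

    def test_ace_inhibition_steady_state_directions(self, reference_patient):
        # with conversion blocked, the algebraic steady state at fixed renin
        # concentration has Ang I accumulating and Ang II collapsing
        from hypertx.params import K_ACE, K_AT1, K_DEG, K_NONACE
        acei = 0.996
        ang1_ss = (K_ACE + K_NONACE) / (K_ACE * (1 - acei) + K_NONACE)
        ang2_ss = K_ACE * (1 - acei) * ang1_ss / (K_AT1 + K_DEG)
        assert ang1_ss > 5.0
        assert ang2_ss < 0.1


class TestRenalFluxes:
    def test_baseline_balance(self, reference_patient):
        p = reference_patient
        rn = renal_fluxes(baseline_state(p), p, PD0, p.MAP_ref)
        assert rn["Na_excretion"] == pytest.approx(p.Phi_sod_in, rel=1e-9)
        assert rn["GFR"] == pytest.approx(p.GFR_ref, rel=1e-9)

    def test_distal_blockade_raises_excretion_at_fixed_state(self,
                                                             reference_patient):
        p = reference_patient
        pd = PDEffects(DiureticInhibition=0.304)
        rn0 = renal_fluxes(baseline_state(p), p, PD0, p.MAP_ref)
        rn = renal_fluxes(baseline_state(p), p, pd, p.MAP_ref)
        assert rn["Na_excretion"] > rn0["Na_excretion"]

    def test_calcium_channel_blockade_renal_pattern(self, reference_patient):
        p = reference_patient
        pd = PDEffects(CCBaa=0.413, CCBea=0.107, CCBpreglom=0.413)
        rn0 = renal_fluxes(baseline_state(p), p, PD0, p.MAP_ref)
        rn = renal_fluxes(baseline_state(p), p, pd, p.MAP_ref)
        assert rn["GFR"] > rn0["GFR"]
        assert rn["RVR"] < rn0["RVR"]
        assert rn["RBF"] > rn0["RBF"]


class TestDynamics:
    def test_drug_free_equilibrium_persists_four_weeks(self, reference_patient):
        traj = simulate(reference_patient, DrugRegimen.none(),
                        t_end=2_419_200.0, n_out=30)
        obs = traj.observables()
        for var in ("SBP", "DBP", "HR", "GFR", "MAP"):
            v = obs[var]
            assert np.max(np.abs(v - v[0])) / abs(v[0]) < 1e-3

    def test_sodium_imbalance_sign(self, reference_patient):
        p = reference_patient.copy(Phi_sod_in=reference_patient.Phi_sod_in * 2)
        dy = derivatives(baseline_state(reference_patient), p, PD0)
        assert dy[0] > 0.0

    def test_weak_ventricle_congests_lungs(self, reference_patient):
        p = reference_patient.copy(KL0=0.25)
        dy = derivatives(baseline_state(reference_patient), p, PD0)
        assert dy[1] > 0.0

    def test_ace_inhibitor_monotone_pressure_approach(self, reference_patient):
        reg = parse_regimen("enalapril:20")
        traj = simulate(reference_patient, reg, t_end=2_419_200.0, n_out=40)
        sbp = traj.observables()["SBP"]
        eq = find_equilibrium(reference_patient, reg)
        # trajectory approaches the root-found plateau from above
        assert sbp[-1] == pytest.approx(eq.SBP, rel=1e-3)
        drops = np.diff(sbp[2:])
        assert np.all(drops < 1e-3)

    def test_simulation_matches_root_equilibrium(self, reference_patient):
        for spec in ("aliskiren:150", "bisoprolol:5"):
            reg = parse_regimen(spec)
            traj = simulate(reference_patient, reg, t_end=4_000_000.0, n_out=4)
            eq = find_equilibrium(reference_patient, reg)
            end = observe(traj.states[-1], reference_patient, reg, t=4_000_000.0)
            assert end.SBP == pytest.approx(eq.SBP, rel=1e-3)
            assert end.HR == pytest.approx(eq.HR, rel=1e-3)


class TestBaroreflex:
    def test_resistance_step_moves_heart_rate_opposite(self, reference_patient):
        base = find_equilibrium(reference_patient)
        up = reference_patient.copy(
            R_micro0=reference_patient.R_micro0 * 1.10)
        down = reference_patient.copy(
            R_micro0=reference_patient.R_micro0 * 0.90)
        eq_up = find_equilibrium(up, y0=baseline_state(reference_patient))
        eq_down = find_equilibrium(down, y0=baseline_state(reference_patient))
        assert eq_up.HR <= base.HR
        assert eq_down.HR >= base.HR


class TestCardiogenicShock:
    def test_normal_baseline_is_not_shock(self, reference_patient):
        traj = simulate(reference_patient, DrugRegimen.none(),
                        t_end=7200.0, n_out=30)
        verdict, onset = detect_cardiogenic_shock(traj)
        assert verdict is False and onset is None

    def test_critically_low_inotropy_reaches_shock(self, reference_patient):
        weak = reference_patient.copy(KL0=0.2)
        traj = simulate(weak, DrugRegimen.none(), t_end=720_000.0,
                        y0=baseline_state(reference_patient), n_out=240)
        verdict, onset = detect_cardiogenic_shock(traj)
        assert verdict is True
        assert onset is not None and onset > 0.0

    def test_sub_threshold_duration_is_not_shock(self, reference_patient):
        # synthetic trajectory: criteria met for 29 min only
        p = reference_patient
        t = np.arange(0, 3600.0, 60.0)
        states = np.tile(baseline_state(p).as_array(), (len(t), 1))
        traj = Trajectory(t=t, states=states, params=p,
                          regimen=DrugRegimen.none())
        obs = {k: np.array([v] * len(t), dtype=float)
               for k, v in observe(baseline_state(p), p).asdict().items()}
        window = (t >= 60.0) & (t < 60.0 + 29 * 60.0)
        obs["SBP"] = np.where(window, 85.0, 120.0)
        obs["CO"] = np.where(window, 2.0, 6.0)
        obs["PVP"] = np.where(window, 20.0, 8.0)
        traj._obs = obs
        verdict, _ = detect_cardiogenic_shock(traj)
        assert verdict is False

    def test_short_trajectory_rejected(self, reference_patient):
        traj = simulate(reference_patient, DrugRegimen.none(),
                        t_end=600.0, n_out=5)
        with pytest.raises(ValueError):
            detect_cardiogenic_shock(traj)


@pytest.fixture(scope="module")
def eqs(reference_patient):
    regs = {"ali": "aliskiren:150", "ena": "enalapril:20",
            "los": "losartan:100", "aml": "amlodipine:5",
            "bis": "bisoprolol:5", "hctz": "hctz:12.5"}
    out = {k: find_equilibrium(reference_patient, parse_regimen(v))
           for k, v in regs.items()}
    out["base"] = find_equilibrium(reference_patient)
    return out


class TestDrugEquilibria:
    """Equilibrium directionality for single agents on the uncalibrated
    reference patient (the population-level battery runs in the acceptance
    suite on the calibrated model)."""

    def test_all_monotherapies_lower_pressures_and_rvr(self, eqs):
        base = eqs["base"]
        for k in ("ali", "ena", "los", "aml", "bis", "hctz"):
            eq = eqs[k]
            assert eq.MAP < base.MAP, k
            assert eq.SBP < base.SBP, k
            assert eq.DBP < base.DBP, k
            assert eq.RVR < base.RVR, k

    def test_renin_inhibitor_profile(self, eqs):
        b, e = eqs["base"], eqs["ali"]
        assert e.PRA < b.PRA and e.PRC > b.PRC
        assert e.AngI < b.AngI and e.AngII < b.AngII and e.ALD < b.ALD

    def test_ace_inhibitor_profile(self, eqs):
        b, e = eqs["base"], eqs["ena"]
        assert e.PRA > b.PRA and e.AngI > b.AngI
        assert e.AngII < b.AngII and e.ALD < b.ALD

    def test_at1_blocker_profile(self, eqs):
        b, e = eqs["base"], eqs["los"]
        assert e.PRA > b.PRA and e.PRC > b.PRC
        assert e.AngI > b.AngI and e.AngII > b.AngII
        assert e.AT1B < b.AT1B and e.ALD < b.ALD

    def test_beta_blocker_profile(self, eqs):
        b, e = eqs["base"], eqs["bis"]
        assert e.PRA < b.PRA and e.PRC < b.PRC
        assert e.AngII < b.AngII and e.HR < b.HR

    def test_thiazide_activates_renin(self, eqs):
        b, e = eqs["base"], eqs["hctz"]
        assert e.PRA > b.PRA and e.PRC > b.PRC

    def test_calcium_channel_blocker_reflex_tachycardia(self, eqs):
        assert eqs["aml"].HR > eqs["base"].HR


def test_equilibrium_error_for_unsolvable_patient():
    p = default_patient().copy(KL0=0.2)
    with pytest.raises(EquilibriumError):
        # a congesting ventricle has no finite resting state
        find_equilibrium(p, y0=baseline_state(default_patient()))
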