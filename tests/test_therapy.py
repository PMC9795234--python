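"""Treatment pipeline: classification, screening, calibration, statistics."""

import dataclasses
import math

import numpy as np
import pytest

from hypertx import (DrugRegimen, classify_change, simulate_treatment,
                     summarize_population, treat_population, validity_screen)
from hypertx.drugs import Drug, parse_regimen
from hypertx.therapy import (EXPECTED_RESPONSE, TreatmentOutcome,
                             _compatible, calibrate_drug_gains)


class TestClassifyChange:
    @pytest.mark.parametrize("pct,expected", [
        (4.0, "no_change"),
        (-4.9, "no_change"),
        (12.0, "increase"),
        (-12.0, "decrease"),
        (7.0, "transitional_increase"),
        (-7.0, "transitional_decrease"),
    ])
    def test_banding(self, pct, expected):
        assert classify_change(100.0, 100.0 * (1 + pct / 100.0)) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            classify_change(0.0, 5.0)

    def test_transitional_compatibility(self):
        assert _compatible("transitional_increase", "increase")
        assert _compatible("transitional_increase", "no_change")
        assert not _compatible("transitional_increase", "decrease")
        assert not _compatible("increase", "no_change")
        assert not _compatible("no_change", "decrease")


def _fake_outcome(base_eq, pct_by_var):
    """Outcome whose post state differs from the baseline equilibrium by the
    given per-variable percentages."""
    changes = {k: getattr(base_eq, k) * (1 + v / 100.0)
               for k, v in pct_by_var.items()}
    post = dataclasses.replace(base_eq, **changes)
    pct = {k: v for k, v in pct_by_var.items()}
    return TreatmentOutcome(0, DrugRegimen.none(), base_eq, post, pct)


class TestValidityScreen:
    def _battery(self, base_eq, overrides=None):
        # synthesize a perfectly compliant battery, then apply overrides
        direction_pct = {"increase": 30.0, "decrease": -30.0, "no_change": 0.0}
        outcomes = {}
        for drug, table in EXPECTED_RESPONSE.items():
            pct = {var: direction_pct[exp] for var, exp in table.items()}
            outcomes[drug] = _fake_outcome(base_eq, pct)
        for drug, var, pct in (overrides or []):
            outcomes[drug] = _fake_outcome(
                base_eq, {**outcomes[drug].pct_change, var: pct})
        return outcomes

    def test_compliant_battery_included(self, reference_equilibrium):
        ok, violations = validity_screen(self._battery(reference_equilibrium))
        assert ok and violations == []

    def test_paradoxical_tachycardia_excluded(self, reference_equilibrium):
        # heart rate rising >10% under the β-blocker is invalid dynamics
        outcomes = self._battery(reference_equilibrium,
                                 [(Drug.BISOPROLOL, "HR", 12.0)])
        ok, violations = validity_screen(outcomes)
        assert not ok
        assert any("bisoprolol/HR" in v for v in violations)

    def test_transitional_change_tolerated(self, reference_equilibrium):
        # +6% GFR where no change is expected sits in the transitional band
        outcomes = self._battery(reference_equilibrium,
                                 [(Drug.ALISKIREN, "GFR", 6.0)])
        ok, _ = validity_screen(outcomes)
        assert ok

    def test_missing_drug_rejected(self, reference_equilibrium):
        outcomes = self._battery(reference_equilibrium)
        del outcomes[Drug.HCTZ]
        with pytest.raises(ValueError, match="hctz"):
            validity_screen(outcomes)


class TestSimulateTreatment:
    def test_empty_regimen_is_inert(self, small_population):
        oc = simulate_treatment(small_population[0], DrugRegimen.none())
        for var in ("SBP", "DBP", "HR", "GFR", "CO"):
            assert abs(oc.pct_change[var]) < 0.1
        assert not oc.shock

    def test_beta_blocker_lowers_heart_rate(self, small_population):
        oc = simulate_treatment(small_population[0],
                                parse_regimen("bisoprolol:5"))
        assert classify_change(oc.pre.HR, oc.post.HR).endswith("decrease")

    def test_calcium_channel_blocker_pattern(self, small_population):
        oc = simulate_treatment(small_population[0],
                                parse_regimen("amlodipine:5"))
        assert oc.post.SBP < oc.pre.SBP
        assert oc.post.DBP < oc.pre.DBP
        assert oc.post.HR > oc.pre.HR

    def test_fast_path_matches_simulation(self, small_population):
        reg = parse_regimen("enalapril:20")
        slow = simulate_treatment(small_population[0], reg)
        fast = treat_population([small_population[0]], reg, fast=True)[0]
        assert fast.post.SBP == pytest.approx(slow.post.SBP, abs=0.2)
        assert fast.post.HR == pytest.approx(slow.post.HR, abs=0.2)


class TestCalibration:
    def test_gain_self_consistency(self, small_population):
        """Targets produced by the uncalibrated model itself must be
        recovered with a multiplier of one."""
        base = np.mean([[vp.equilibrium.SBP, vp.equilibrium.DBP,
                         vp.equilibrium.HR] for vp in small_population], axis=0)
        ocs = treat_population(small_population,
                               parse_regimen("amlodipine:5"), fast=True)
        own = np.mean([[o.post.SBP, o.post.DBP, o.post.HR] for o in ocs],
                      axis=0) - base
        cal = calibrate_drug_gains(small_population,
                                   target_deltas={"amlodipine:5": tuple(own)},
                                   drugs=[Drug.AMLODIPINE], seed=5,
                                   budget=(4, 12, 10))
        assert cal["gains"][Drug.AMLODIPINE] == pytest.approx(1.0, abs=1e-3)

    def test_known_multiplier_recovered(self, small_population):
        """Synthetic targets generated with a known gain of 0.8 are
        recovered within 5%."""
        base = np.mean([[vp.equilibrium.SBP, vp.equilibrium.DBP,
                         vp.equilibrium.HR] for vp in small_population], axis=0)
        ocs = treat_population(small_population, parse_regimen("amlodipine:5"),
                               gains={Drug.AMLODIPINE: 0.8}, fast=True)
        synth = np.mean([[o.post.SBP, o.post.DBP, o.post.HR] for o in ocs],
                        axis=0) - base
        cal = calibrate_drug_gains(small_population,
                                   target_deltas={"amlodipine:5": tuple(synth)},
                                   drugs=[Drug.AMLODIPINE], seed=6,
                                   budget=(4, 12, 10))
        assert cal["gains"][Drug.AMLODIPINE] == pytest.approx(0.8, rel=0.05)


class TestSummaries:
    def test_identical_pre_post_gives_null_result(self, small_population):
        ocs = treat_population(small_population, DrugRegimen.none(), fast=True)
        summary = summarize_population({"none": ocs}, small_population)
        entry = summary.regimens["none"]
        base = np.array([vp.equilibrium.SBP for vp in small_population])
        assert entry["SBP"]["mean"] == pytest.approx(base.mean(), abs=1e-6)
        assert entry["SBP"]["p_base"] > 0.99

    def test_monotherapy_lowers_population_pressure(self, small_population,
                                                    small_population_baseline):
        ocs = treat_population(small_population, parse_regimen("enalapril:20"),
                               fast=True)
        summary = summarize_population({"enalapril:20": ocs}, small_population)
        entry = summary.regimens["enalapril:20"]
        assert entry["SBP"]["mean"] < small_population_baseline[:, 0].mean()
        assert entry["DBP"]["mean"] < small_population_baseline[:, 1].mean()

    def test_combination_p_value_columns_present(self, small_population):
        combo = parse_regimen("aliskiren:150+amlodipine:5")
        outcomes = {
            "aliskiren:150": treat_population(
                small_population, parse_regimen("aliskiren:150"), fast=True),
            "amlodipine:5": treat_population(
                small_population, parse_regimen("amlodipine:5"), fast=True),
            combo.label(): treat_population(small_population, combo, fast=True),
        }
        summary = summarize_population(
            outcomes, small_population,
            components={combo.label(): ("aliskiren:150", "amlodipine:5")})
        entry = summary.regimens[combo.label()]
        assert "p_first" in entry["SBP"] and "p_second" in entry["SBP"]
        assert 0.0 <= entry["SBP"]["p_first"] <= 1.0

    def test_pearson_against_manual_formula(self, small_population):
        ocs = treat_population(small_population, parse_regimen("hctz:12.5"),
                               fast=True)
        summary = summarize_population({"hctz:12.5": ocs}, small_population)
        r_pkg = summary.correlations["hctz:12.5"]["sodium_intake"]["dSBP"]
        x = np.array([vp.params.Phi_sod_in for vp in small_population])
        y = np.array([o.pre.SBP - o.post.SBP for o in ocs])
        # independent arithmetic: covariance over the product of SDs
        r_manual = (np.mean((x - x.mean()) * (y - y.mean()))
                    / (x.std() * y.std()))
        assert r_pkg == pytest.approx(r_manual, abs=1e-12)

    def test_strong_treatment_effect_detected(self, small_population):
        ocs = treat_population(small_population, parse_regimen("enalapril:20"),
                               fast=True)
        summary = summarize_population({"enalapril:20": ocs}, small_population)
        # a double-digit mmHg mean shift should be distinguishable from
        # baseline even at this sample size
        assert summary.regimens["enalapril:20"]["SBP"]["p_base"] < 0.2
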