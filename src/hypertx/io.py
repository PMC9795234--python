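"""Configuration, serialization and report generation.

JSON is used for structured artifacts (populations, calibration results),
CSV for tabular exports.  Every artifact embeds the run seed and a hash of
the configuration that produced it, so runs are auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import EquilibriumState, ModelState, observe
from .params import PatientParameters
from .population import (ConstraintSet, SamplingSettings, TargetDraw,
                         VirtualPatient)

__all__ = ["RunConfig", "load_config", "save_config", "config_hash",
           "write_population", "read_population", "population_frame",
           "write_summary_tables", "PopulationIOError"]

FORMAT_VERSION = 1


class PopulationIOError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration (all units as in the field docstrings of
    the underlying dataclasses: pressures mmHg, rates per minute, mg/day
    doses, seconds for durations)."""

    seed: int = 0
    n_patients: int = 50
    output_dir: str = "runs"
    verbosity: int = 1
    sampling: SamplingSettings = field(default_factory=SamplingSettings)
    constraints: ConstraintSet = field(default_factory=ConstraintSet)
    treatment_duration_s: float = 2_419_200.0
    calibration_targets: dict[str, tuple[float, float, float]] | None = None

    def asdict(self) -> dict:
        d = {
            "seed": self.seed,
            "n_patients": self.n_patients,
            "output_dir": self.output_dir,
            "verbosity": self.verbosity,
            "treatment_duration_s": self.treatment_duration_s,
            "sampling": dataclasses.asdict(self.sampling),
            "constraints": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in dataclasses.asdict(self.constraints).items()
                            if k != "extra"},
        }
        if self.calibration_targets is not None:
            d["calibration_targets"] = {k: list(v) for k, v
                                        in self.calibration_targets.items()}
        return d


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the canonical configuration dump."""
    blob = json.dumps(cfg.asdict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


_TOP_KEYS = {"seed", "n_patients", "output_dir", "verbosity",
             "treatment_duration_s", "sampling", "constraints",
             "calibration_targets"}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected with the offending key named; nested sections
    are validated by the dataclasses they populate (e.g., negative SDs fail
    in :class:`SamplingSettings`).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")

    kwargs: dict = {}
    for key in ("seed", "n_patients", "output_dir", "verbosity",
                "treatment_duration_s"):
        if key in raw:
            kwargs[key] = raw[key]
    if "sampling" in raw:
        extra = set(raw["sampling"]) - {f.name for f in
                                        dataclasses.fields(SamplingSettings)}
        if extra:
            raise ValueError(f"{path}: unknown sampling keys {sorted(extra)}")
        kwargs["sampling"] = SamplingSettings(**raw["sampling"])
    if "constraints" in raw:
        known = {f.name for f in dataclasses.fields(ConstraintSet)}
        extra = set(raw["constraints"]) - known
        if extra:
            raise ValueError(f"{path}: unknown constraint keys {sorted(extra)}")
        vals = {k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["constraints"].items()}
        kwargs["constraints"] = ConstraintSet(**vals)
    if "calibration_targets" in raw:
        kwargs["calibration_targets"] = {
            k: tuple(float(x) for x in v)
            for k, v in raw["calibration_targets"].items()}
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.asdict(), sort_keys=True))


# ----------------------------------------------------------------------
# population serialization
# ----------------------------------------------------------------------

def _patient_record(vp: VirtualPatient) -> dict:
    return {
        "params": dataclasses.asdict(vp.params),
        "state": dataclasses.asdict(vp.state),
        "draw": vp.draw.asdict(),
        "objective": vp.objective,
        "penalty": vp.penalty,
        "evaluations": vp.evaluations,
        "sodium_test": vp.sodium_test,
    }


def write_population(population: list[VirtualPatient], path: str | Path,
                     seed: int | None = None,
                     cfg: RunConfig | None = None) -> None:
    """Serialize a population to JSON (lossless for float64 parameters)."""
    doc = {
        "format_version": FORMAT_VERSION,
        "seed": seed,
        "config_hash": config_hash(cfg) if cfg is not None else None,
        "patients": [_patient_record(vp) for vp in population],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_population(path: str | Path) -> list[VirtualPatient]:
    """Read a population written by :func:`write_population`.

    The stored slow-state vector is re-observed through the model closures,
    so the returned equilibria are bit-identical to the written ones.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PopulationIOError(f"{path}: corrupted population file "
                                f"({exc})") from exc
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise PopulationIOError(
            f"{path}: format version {version} needs migration "
            f"(this build reads version {FORMAT_VERSION})")
    out = []
    for rec in doc["patients"]:
        params = PatientParameters(**rec["params"])
        state = ModelState(**rec["state"])
        eq = observe(state, params)
        vp = VirtualPatient(params=params, equilibrium=eq,
                            draw=TargetDraw(**rec["draw"]),
                            objective=rec["objective"],
                            penalty=rec["penalty"],
                            evaluations=rec["evaluations"],
                            sodium_test=rec.get("sodium_test"))
        out.append(vp)
    return out


def population_frame(population: list[VirtualPatient]) -> pd.DataFrame:
    """Flat observable table, one row per patient, units in the headers."""
    unit = {"SBP": "mmHg", "DBP": "mmHg", "MAP": "mmHg", "CVP": "mmHg",
            "PVP": "mmHg", "LVEDP": "mmHg", "LVPSP": "mmHg",
            "HR": "beats/min", "SV": "ml", "EDV": "ml", "ESV": "ml",
            "EF": "%", "CO": "L/min", "SVR": "dyn.s/cm5", "ECFV": "L",
            "V_blood": "L", "GFR": "ml/min", "RBF": "ml/min",
            "RVR": "mmHg.min/ml", "R_aa": "mmHg.min/ml", "FF": "%",
            "PRA": "norm", "PRC": "norm", "AngI": "norm", "AngII": "norm",
            "AT1B": "norm", "ALD": "norm", "Na_excretion": "mEq/min",
            "H": "dimensionless"}
    rows = []
    for i, vp in enumerate(population):
        row = {"patient": i, "sex": vp.draw.sex,
               "weight_kg": vp.draw.weight, "height_cm": vp.draw.height,
               "BMI_kg_m2": vp.draw.bmi,
               "sodium_intake_mEq_min": vp.params.Phi_sod_in}
        for k, v in vp.equilibrium.asdict().items():
            row[f"{k}_{unit.get(k, 'au').replace('/', '_')}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# report tables
# ----------------------------------------------------------------------

def _fmt_p(p: float) -> str:
    if p != p:
        return "-"
    return "SS" if p < 1e-4 else f"{p:.4f}"


def write_summary_tables(summary, population, out_dir: str | Path,
                         baseline_label: str = "Baseline") -> dict[str, Path]:
    """Emit the outcome table (regimen rows; SBP/DBP/HR mean ± SD with
    baseline and per-component p-value columns) and the baseline
    characteristics table, as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    base = {v: np.array([getattr(vp.equilibrium, v) for vp in population])
            for v in ("SBP", "DBP", "HR")}
    row = {"Regimen": baseline_label}
    for v in ("SBP", "DBP", "HR"):
        row[f"{v} (mean±SD)"] = f"{base[v].mean():.0f} ± {base[v].std(ddof=1):.0f}"
        row[f"{v} P_base"] = "-"
        row[f"{v} P_f"] = "-"
        row[f"{v} P_s"] = "-"
    rows.append(row)
    for label, entry in summary.regimens.items():
        row = {"Regimen": label}
        for v in ("SBP", "DBP", "HR"):
            st = entry[v]
            row[f"{v} (mean±SD)"] = f"{st['mean']:.0f} ± {st['sd']:.0f}"
            row[f"{v} P_base"] = _fmt_p(st.get("p_base", float("nan")))
            row[f"{v} P_f"] = _fmt_p(st.get("p_first", float("nan")))
            row[f"{v} P_s"] = _fmt_p(st.get("p_second", float("nan")))
        rows.append(row)
    outcome_path = out_dir / "treatment_outcomes.csv"
    pd.DataFrame(rows).to_csv(outcome_path, index=False)

    base_rows = []
    series = {
        "SBP, mmHg": [vp.equilibrium.SBP for vp in population],
        "DBP, mmHg": [vp.equilibrium.DBP for vp in population],
        "HR, beats/min": [vp.equilibrium.HR for vp in population],
        "BMI, kg/m^2": [vp.draw.bmi for vp in population],
        "Weight, kg": [vp.draw.weight for vp in population],
        "Height, cm": [vp.draw.height for vp in population],
    }
    for name, vals in series.items():
        arr = np.asarray(vals)
        base_rows.append({"Variable": name,
                          "mean±SD": f"{arr.mean():.2f} ± {arr.std(ddof=1):.2f}"})
    males = sum(vp.draw.sex == "M" for vp in population)
    base_rows.append({"Variable": "Sex, M/F",
                      "mean±SD": f"{males}/{len(population) - males}"})
    baseline_path = out_dir / "baseline_characteristics.csv"
    pd.DataFrame(base_rows).to_csv(baseline_path, index=False)
    return {"outcomes": outcome_path, "baseline": baseline_path}
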