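"""Pharmacodynamic drug layer.

Each antihypertensive agent acts on the physiological model through one or
more multiplicative influence functions ``F = 1 ± Σ E(D)·dF``, where ``E(D)``
is the dimensionless magnitude of target stimulation (+) or inhibition (−) at
dose ``D`` (mg/day) and ``dF`` is an on/off indicator.  The sum runs over all
drugs of one class and all simulated dosages, so dual therapy is simply the
union of two single-drug effect sets.

Supported agents and dosages (mg/day): aliskiren 150/300 (direct renin
inhibitor, Emax dose–response), amlodipine 5 (dihydropyridine calcium-channel
blocker), bisoprolol 5 (β1-blocker), enalapril 20 (ACE inhibitor),
hydrochlorothiazide 12.5 (thiazide diuretic, with a time-ramped systemic
vasodilation), losartan 50/100 (AT1-receptor blocker).  Other doses raise
:class:`UnsupportedDoseError` rather than extrapolate: only aliskiren has a
published dose–response formula here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

__all__ = [
    "Drug",
    "RegimenEntry",
    "DrugRegimen",
    "PDEffects",
    "EffectRow",
    "EFFECT_TABLE",
    "UnsupportedDoseError",
    "emax_effect",
    "hctz_sys_ramp",
    "regimen_effects",
    "apply_effect",
    "parse_regimen",
]

#: Duration (s) of the linear rise of the hydrochlorothiazide systemic
#: vasodilation and its plateau magnitude.  ~22.6 days, matching the 4–6 week
#: recovery of extracellular fluid volume under chronic thiazide treatment.
HCTZ_RAMP_DURATION_S = 1_950_000.0
HCTZ_RAMP_EMAX = 0.074

ALISKIREN_EMAX = 0.99
ALISKIREN_ED50_MG = 20.0


class Drug(str, enum.Enum):
    ALISKIREN = "aliskiren"
    AMLODIPINE = "amlodipine"
    BISOPROLOL = "bisoprolol"
    ENALAPRIL = "enalapril"
    HCTZ = "hctz"
    LOSARTAN = "losartan"


class UnsupportedDoseError(ValueError):
    """Raised for a (drug, dose) pair outside the supported dose grid."""


@dataclass(frozen=True)
class EffectRow:
    """One drug→target mapping: magnitude E(D) and its sign.

    ``magnitude`` is either a float (constant effect) or one of the formula
    ids ``"emax"`` (aliskiren dose–response) / ``"hctz_ramp"`` (time-ramped
    systemic effect).
    """

    drug: Drug
    dose: float           # mg/day
    target: str           # PDEffects field name
    sign: str             # "+" stimulation, "-" inhibition
    magnitude: float | str


#: Effect table: every supported (drug, dose) with its target magnitudes.
EFFECT_TABLE: tuple[EffectRow, ...] = (
    EffectRow(Drug.ALISKIREN, 150.0, "DRI", "-", "emax"),
    EffectRow(Drug.ALISKIREN, 300.0, "DRI", "-", "emax"),
    EffectRow(Drug.AMLODIPINE, 5.0, "CCBaa", "-", 0.413),
    EffectRow(Drug.AMLODIPINE, 5.0, "CCBea", "-", 0.107),
    EffectRow(Drug.AMLODIPINE, 5.0, "CCBpreglom", "-", 0.413),
    EffectRow(Drug.AMLODIPINE, 5.0, "CCBsys", "-", 0.107),
    EffectRow(Drug.BISOPROLOL, 5.0, "Bblocker", "-", 0.371),
    EffectRow(Drug.BISOPROLOL, 5.0, "Bblocker_rs", "-", 0.933),
    EffectRow(Drug.ENALAPRIL, 20.0, "ACEi", "-", 0.996),
    EffectRow(Drug.HCTZ, 12.5, "DiureticInhibition", "-", 0.304),
    EffectRow(Drug.HCTZ, 12.5, "DiureticStimulation", "+", 1.113),
    EffectRow(Drug.HCTZ, 12.5, "Diureticaa", "-", 0.469),
    EffectRow(Drug.HCTZ, 12.5, "Diureticea", "-", 0.302),
    EffectRow(Drug.HCTZ, 12.5, "Diureticpreglom", "-", 0.581),
    EffectRow(Drug.HCTZ, 12.5, "Diureticsys", "-", "hctz_ramp"),
    EffectRow(Drug.HCTZ, 12.5, "Diureticstress", "-", 0.389),
    EffectRow(Drug.HCTZ, 12.5, "Diureticpotassium", "-", 0.030),
    EffectRow(Drug.HCTZ, 12.5, "Diureticurea", "+", 0.100),
    EffectRow(Drug.LOSARTAN, 50.0, "ARB", "-", 0.886),
    EffectRow(Drug.LOSARTAN, 100.0, "ARB", "-", 0.954),
)

_SUPPORTED_DOSES: dict[Drug, tuple[float, ...]] = {}
for _row in EFFECT_TABLE:
    _doses = _SUPPORTED_DOSES.setdefault(_row.drug, ())
    if _row.dose not in _doses:
        _SUPPORTED_DOSES[_row.drug] = _doses + (_row.dose,)


@dataclass(frozen=True)
class RegimenEntry:
    drug: Drug
    dose: float     # mg/day
    indicator: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug", Drug(self.drug))
        if self.dose <= 0:
            raise ValueError(f"dose must be positive, got {self.dose}")
        if self.indicator not in (0, 1):
            raise ValueError(f"indicator must be 0 or 1, got {self.indicator}")
        doses = _SUPPORTED_DOSES.get(self.drug, ())
        if self.dose not in doses:
            raise UnsupportedDoseError(
                f"{self.drug.value} {self.dose:g} mg/day is not in the supported "
                f"dose grid; supported doses: {sorted(doses)}"
            )


@dataclass(frozen=True)
class DrugRegimen:
    """A set of (drug, dose, on/off-indicator) entries.

    At most one entry per (drug, dose) pair, and at most one *active* dosage
    per drug: summing two active dosages of one inhibitory agent could push
    its influence function below zero.
    """

    entries: tuple[RegimenEntry, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        seen: set[tuple[Drug, float]] = set()
        active: set[Drug] = set()
        for e in self.entries:
            key = (e.drug, e.dose)
            if key in seen:
                raise ValueError(f"duplicate regimen entry {e.drug.value}:{e.dose:g}")
            seen.add(key)
            if e.indicator:
                if e.drug in active:
                    raise ValueError(
                        f"two active dosages of {e.drug.value}; the model "
                        "simulates one dosage of a drug at a time"
                    )
                active.add(e.drug)

    @classmethod
    def none(cls) -> "DrugRegimen":
        return cls(())

    @classmethod
    def of(cls, *items: tuple[Drug | str, float]) -> "DrugRegimen":
        return cls(tuple(RegimenEntry(Drug(d), dose) for d, dose in items))

    @property
    def active(self) -> tuple[RegimenEntry, ...]:
        return tuple(e for e in self.entries if e.indicator)

    def label(self) -> str:
        return "+".join(f"{e.drug.value}:{e.dose:g}" for e in self.active) or "none"


@dataclass(frozen=True)
class PDEffects:
    """Aggregate effect magnitudes Σ E(D)·dF per model target.

    All fields are dimensionless; inhibitory magnitudes live in [0, 1),
    stimulation magnitudes (DiureticStimulation, Diureticurea) are ≥ 0.
    The multiplicative influence on a target is ``1 − m`` (inhibition) or
    ``1 + m`` (stimulation).
    """

    ACEi: float = 0.0
    ARB: float = 0.0
    DRI: float = 0.0
    CCBaa: float = 0.0
    CCBea: float = 0.0
    CCBpreglom: float = 0.0
    CCBsys: float = 0.0
    Bblocker: float = 0.0
    Bblocker_rs: float = 0.0
    DiureticInhibition: float = 0.0
    Diureticaa: float = 0.0
    Diureticea: float = 0.0
    Diureticpreglom: float = 0.0
    Diureticsys: float = 0.0
    DiureticStimulation: float = 0.0
    Diureticstress: float = 0.0
    Diureticpotassium: float = 0.0
    Diureticurea: float = 0.0

    _STIMULATORY = frozenset({"DiureticStimulation", "Diureticurea"})

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"negative effect magnitude {f.name}={v}")
            if f.name not in self._STIMULATORY and v >= 1.0:
                raise ValueError(
                    f"inhibitory magnitude {f.name}={v} must stay below 1"
                )

    def is_null(self) -> bool:
        return all(getattr(self, f.name) == 0.0 for f in fields(self))

    def asdict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def emax_effect(dose: float, emax: float = ALISKIREN_EMAX,
                ed50: float = ALISKIREN_ED50_MG) -> float:
    """Saturating Emax dose–response: ``emax·D/(D + ED50)``.

    Half-maximal at ``ED50``, strictly increasing in dose, bounded by
    ``emax``.
    """
    if dose < 0:
        raise ValueError(f"dose must be nonnegative, got {dose}")
    if not 0.0 < emax <= 1.0:
        raise ValueError(f"emax must be in (0, 1], got {emax}")
    if ed50 <= 0:
        raise ValueError(f"ed50 must be positive, got {ed50}")
    return emax * dose / (dose + ed50)


def hctz_sys_ramp(t: float, emax: float = HCTZ_RAMP_EMAX,
                  duration: float = HCTZ_RAMP_DURATION_S) -> float:
    """Time-ramped systemic vasodilation of hydrochlorothiazide.

    ``min(emax·t/duration, emax)`` — linear in time since treatment start,
    saturating at ``emax``.  Carries the slow "chronic phase" of the thiazide
    pressure response: extracellular volume dips acutely and then recovers as
    microvessel conductivity rises.
    """
    if t < 0:
        raise ValueError(f"time since treatment start must be >= 0, got {t}")
    return min(emax * t / duration, emax)


def regimen_effects(regimen: DrugRegimen, t: float = 0.0,
                    gain: Mapping[Drug | str, float] | None = None) -> PDEffects:
    """Aggregate the effect-table magnitudes of all active regimen entries.

    ``t`` is model time (s) since treatment start; only the HCTZ systemic
    ramp is time-dependent.  ``gain`` optionally scales all magnitudes of a
    drug jointly (the per-drug calibration multiplier); aliskiren's ED50 is
    never rescaled, its Emax is.  Scaled inhibitory magnitudes are capped
    just below 1 so every influence function stays positive.
    """
    acc: dict[str, float] = {}
    gains = {Drug(k): float(v) for k, v in (gain or {}).items()}
    for entry in regimen.active:
        g = gains.get(entry.drug, 1.0)
        for row in EFFECT_TABLE:
            if row.drug is not entry.drug or row.dose != entry.dose:
                continue
            if row.magnitude == "emax":
                m = emax_effect(entry.dose, emax=min(ALISKIREN_EMAX * g, 0.999))
            elif row.magnitude == "hctz_ramp":
                m = hctz_sys_ramp(t) * g
            else:
                m = float(row.magnitude) * g
            if row.target not in PDEffects._STIMULATORY:
                m = min(m, 0.999)
            acc[row.target] = acc.get(row.target, 0.0) + m
    return PDEffects(**acc)


def apply_effect(value: float, magnitude: float, sign: str,
                 clamp_nonnegative: bool = True) -> float:
    """Apply one influence function: ``value·(1 − m)`` or ``value·(1 + m)``."""
    if magnitude < 0:
        raise ValueError(f"magnitude must be nonnegative, got {magnitude}")
    if sign == "-":
        out = value * (1.0 - magnitude)
    elif sign == "+":
        out = value * (1.0 + magnitude)
    else:
        raise ValueError(f"sign must be '+' or '-', got {sign!r}")
    if clamp_nonnegative and out < 0.0:
        out = 0.0
    return out


def effect_table_to_yaml(path, table: tuple[EffectRow, ...] = EFFECT_TABLE,
                         version: int = 1) -> None:
    """Dump the effect table as a versioned plain-text config."""
    import yaml
    doc = {"effect_table_version": version,
           "rows": [dict(drug=r.drug.value, dose=r.dose, target=r.target,
                         sign=r.sign, magnitude=r.magnitude)
                    for r in table]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def effect_table_from_yaml(path) -> tuple[EffectRow, ...]:
    """Load an effect table written by :func:`effect_table_to_yaml`."""
    import yaml
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("effect_table_version") != 1:
        raise ValueError("unsupported effect-table version")
    return tuple(EffectRow(Drug(r["drug"]), float(r["dose"]), r["target"],
                           r["sign"], r["magnitude"]) for r in doc["rows"])


def parse_regimen(spec: str | Iterable[str]) -> DrugRegimen:
    """Parse ``"enalapril:20+hctz:12.5"`` (or a list of ``drug:dose``)."""
    if isinstance(spec, str):
        if spec in ("", "none", "baseline"):
            return DrugRegimen.none()
        parts = spec.split("+")
    else:
        parts = list(spec)
    entries = []
    for p in parts:
        try:
            name, dose = p.strip().split(":")
            entries.append(RegimenEntry(Drug(name.strip()), float(dose)))
        except UnsupportedDoseError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise ValueError(f"cannot parse regimen item {p!r}: {exc}") from exc
    return DrugRegimen(tuple(entries))
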