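"""Clinical action map and outcome rules for the 144-cell decision tree.

Three band-reported readouts (bacterial: low/moderate/high, viral: low/high,
mortality risk: low/moderate/high) give 3*2*3 = 18 prediction combinations.
Each combination is mapped to a suggested clinical action (disposition,
antibiotic regimen, viral PCR + oseltamivir, blood culture) which physicians
are assumed to follow exactly. Crossing the 18 combinations with the
2*2*2 = 8 ground-truth states (bacterial infection, viral infection, true
30-day mortality risk) yields 144 prediction-truth cells; an ordered,
first-match-wins rule list assigns each cell an outcome record (ward days,
ICU days, antibiotic days, death probability, readmission flag, cost
events).

The shipped default ledger is a reconstruction: the action grid follows the
triage logic of severity-driven disposition with infection-driven therapy,
and the outcome rules encode concordant care, missed-bacterial
readmission, and missed-severity rehospitalization, parameterized entirely
by :class:`ClinicalParams` / cost-catalog keys so a user holding a complete
cell-by-cell outcome listing can transcribe it. Every rule carries a
provenance note.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Iterable

import pandas as pd

__all__ = [
    "BACTERIAL_BANDS",
    "VIRAL_BANDS",
    "MORTALITY_BANDS",
    "PredictionCombo",
    "GroundTruth",
    "ClinicalAction",
    "OutcomeRecord",
    "ClinicalParams",
    "CostParams",
    "OutcomeRule",
    "Ledger",
    "LedgerError",
    "ValidationReport",
    "enumerate_combos",
    "enumerate_truths",
    "enumerate_cells",
    "default_ledger",
    "action_for",
    "outcome_for",
    "validate_ledger",
    "action_map_to_csv",
    "action_map_from_csv",
]

BACTERIAL_BANDS = ("low", "moderate", "high")
VIRAL_BANDS = ("low", "high")
MORTALITY_BANDS = ("low", "moderate", "high")

DISPOSITIONS = ("discharge_home", "ed_observation", "ward_admit", "icu_admit")
REGIMENS = ("none", "oral_outpatient", "oral_iv_ward", "iv_icu")

ACTION_MAP_SCHEMA = "triage-cim-action-map-v1"


class LedgerError(ValueError):
    """Configuration error in a ledger (coverage gap or invalid rule)."""


@dataclass(frozen=True, order=True)
class PredictionCombo:
    """One of the 18 bacterial x viral x mortality band combinations."""

    bacterial_band: str
    viral_band: str
    mortality_band: str

    def __post_init__(self) -> None:
        if self.bacterial_band not in BACTERIAL_BANDS:
            raise ValueError(f"bad bacterial band {self.bacterial_band!r}")
        if self.viral_band not in VIRAL_BANDS:
            raise ValueError(f"bad viral band {self.viral_band!r}")
        if self.mortality_band not in MORTALITY_BANDS:
            raise ValueError(f"bad mortality band {self.mortality_band!r}")


@dataclass(frozen=True, order=True)
class GroundTruth:
    """Actual patient state on the three axes, independent of predictions."""

    bacterial: bool
    viral: bool
    mortality_risk: bool


@dataclass(frozen=True)
class ClinicalAction:
    """Suggested management for one prediction combination."""

    disposition: str
    antibiotic_regimen: str
    viral_pcr_ordered: bool
    oseltamivir_given: bool
    blood_culture_ordered: bool

    def __post_init__(self) -> None:
        if self.disposition not in DISPOSITIONS:
            raise ValueError(f"bad disposition {self.disposition!r}")
        if self.antibiotic_regimen not in REGIMENS:
            raise ValueError(f"bad regimen {self.antibiotic_regimen!r}")
        if self.antibiotic_regimen == "iv_icu" and self.disposition != "icu_admit":
            raise ValueError("iv_icu antibiotics require icu_admit disposition")
        if self.oseltamivir_given and not self.viral_pcr_ordered:
            raise ValueError("oseltamivir requires a viral PCR order")

    @property
    def admitted(self) -> bool:
        return self.disposition in ("ward_admit", "icu_admit")

    @property
    def any_antibiotics(self) -> bool:
        return self.antibiotic_regimen != "none"


@dataclass(frozen=True)
class OutcomeRecord:
    """Expected outcome of one (prediction, truth) cell.

    Day counts are expectations over the within-cell death lottery where the
    length of stay depends on survival (missed-severity readmissions);
    ``cost_events`` name cost-catalog keys with (possibly fractional)
    multiplicities. ``days_if_death``/``days_if_survival`` expose the two
    branches for patient-level simulation.
    """

    hospital_ward_days: float
    icu_days: float
    antibiotic_days: float
    death_probability: float
    readmission: bool
    cost_events: tuple[tuple[str, float], ...]
    ward_days_if_death: float = None  # type: ignore[assignment]
    icu_days_if_death: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0.0 <= self.death_probability <= 1.0):
            raise ValueError("death_probability outside [0, 1]")
        for v in (self.hospital_ward_days, self.icu_days, self.antibiotic_days):
            if not (v >= 0.0 and v < float("inf")):
                raise ValueError("day counts must be finite and >= 0")
        if self.ward_days_if_death is None:
            object.__setattr__(self, "ward_days_if_death", self.hospital_ward_days)
        if self.icu_days_if_death is None:
            object.__setattr__(self, "icu_days_if_death", self.icu_days)

    @property
    def ward_days_if_survival(self) -> float:
        p = self.death_probability
        if p >= 1.0:
            return self.hospital_ward_days
        return (self.hospital_ward_days - p * self.ward_days_if_death) / (1.0 - p)

    @property
    def icu_days_if_survival(self) -> float:
        p = self.death_probability
        if p >= 1.0:
            return self.icu_days
        return (self.icu_days - p * self.icu_days_if_death) / (1.0 - p)


@dataclass(frozen=True)
class ClinicalParams:
    """Clinical outcome parameters (days and probabilities).

    Defaults are the base-case values: antibiotic course lengths by care
    setting, initial-admission lengths of stay, 30-day mortality structure,
    and rehospitalization stays used when a missed diagnosis forces a
    readmission.
    """

    antibiotic_days_ed: float = 3.18
    antibiotic_days_ward: float = 5.02
    antibiotic_days_icu: float = 6.86
    los_short_ward: float = 1.77
    los_icu: float = 4.85
    mortality_septic_icu_viral: float = 0.23
    mortality_reduction_timely: float = 0.30
    mortality_arti: float = 0.10
    mortality_viral: float = 0.067
    rehosp_icu_los: float = 8.30
    nonsurvivor_los: float = 19.90

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("mortality"):
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{f.name} must be a probability, got {v}")
            elif not v > 0.0:
                raise ValueError(f"{f.name} must be > 0, got {v}")


@dataclass(frozen=True)
class CostParams:
    """Unit-cost catalog (US$). ``*_per_day`` keys multiply day counts; the
    composite ``missed_*`` items are all-in penalty costs for a missed
    diagnosis and already include the associated readmission stay."""

    pcr_viral: float = 129.00
    blood_culture: float = 290.00
    oseltamivir_course: float = 82.00
    abx_oral_outpatient: float = 32.33
    abx_oral_iv_ward: float = 108.67
    abx_iv_icu_per_day: float = 277.50
    ward_day: float = 2285.00
    icu_day: float = 4300.00
    ed_visit_incl_pct: float = 207.00
    missed_bact_no_mort: float = 2869.88
    missed_bact_with_mort: float = 51680.76
    missed_mort_no_bact: float = 37730.51
    hostdx_test_cost: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0.0:
                raise ValueError(f"{f.name} must be >= 0")

    def price(self, events: Iterable[tuple[str, float]]) -> float:
        """Total cost of a cost-event list against this catalog."""
        total = 0.0
        for key, mult in events:
            total += getattr(self, key) * mult
        return total


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_combos() -> list[PredictionCombo]:
    """All 18 prediction combinations in canonical band order."""
    return [
        PredictionCombo(bb, vb, mb)
        for bb in BACTERIAL_BANDS
        for vb in VIRAL_BANDS
        for mb in MORTALITY_BANDS
    ]


def enumerate_truths() -> list[GroundTruth]:
    """All 8 ground-truth states in canonical bit order."""
    return [
        GroundTruth(b, v, m)
        for b in (False, True)
        for v in (False, True)
        for m in (False, True)
    ]


def enumerate_cells() -> list[tuple[PredictionCombo, GroundTruth]]:
    """All 144 (prediction, truth) cells, combos outer, truth bits inner."""
    return [(c, t) for c in enumerate_combos() for t in enumerate_truths()]


# ---------------------------------------------------------------------------
# default action map
# ---------------------------------------------------------------------------

def _default_action(combo: PredictionCombo) -> tuple[ClinicalAction, str]:
    """Default triage logic plus a provenance note.

    Disposition follows the mortality-risk band (high -> ICU, moderate ->
    ward, low -> home) with two refinements: a high bacterial band keeps an
    otherwise-dischargeable patient in ED observation on oral antibiotics,
    and an ICU bed requires corroborating infection signal (bacterial band
    at least moderate or a high viral band) — a high severity score alone
    admits to the ward. Antibiotics are empiric by care setting; a high
    viral band triggers confirmatory PCR plus oseltamivir; blood cultures
    accompany admission whenever the bacterial band is not low.
    """
    bb, vb, mb = combo.bacterial_band, combo.viral_band, combo.mortality_band
    note = []
    if mb == "high":
        if bb == "low" and vb == "low":
            dispo = "ward_admit"
            note.append(
                "high mortality band without infection signal: ward admission "
                "for monitoring rather than ICU"
            )
        else:
            dispo = "icu_admit"
            note.append("high mortality band with infection signal: ICU")
    elif mb == "moderate":
        dispo = "ward_admit"
        note.append("moderate mortality band: ward admission")
    elif bb == "high":
        dispo = "ed_observation"
        note.append("low mortality but high bacterial band: ED observation")
    else:
        dispo = "discharge_home"
        note.append("low mortality band: discharge home")

    regimen = {
        "icu_admit": "iv_icu",
        "ward_admit": "oral_iv_ward",
        "ed_observation": "oral_outpatient",
        "discharge_home": "none",
    }[dispo]
    if regimen != "none":
        note.append(f"empiric antibiotics for the care setting ({regimen})")

    pcr = vb == "high"
    if pcr:
        note.append("high viral band: PCR confirmation and oseltamivir")
    culture = bb in ("moderate", "high") and dispo in ("ward_admit", "icu_admit")
    if culture:
        note.append("admitted with non-low bacterial band: blood culture")

    return (
        ClinicalAction(
            disposition=dispo,
            antibiotic_regimen=regimen,
            viral_pcr_ordered=pcr,
            oseltamivir_given=pcr,
            blood_culture_ordered=culture,
        ),
        "; ".join(note),
    )


# ---------------------------------------------------------------------------
# outcome rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeRule:
    """One first-match-wins outcome rule.

    ``applies(combo, action, truth)`` decides whether the rule owns a cell;
    ``build(combo, action, truth, clinical)`` constructs its OutcomeRecord.
    """

    name: str
    applies: Callable[[PredictionCombo, ClinicalAction, GroundTruth], bool]
    build: Callable[
        [PredictionCombo, ClinicalAction, GroundTruth, ClinicalParams],
        OutcomeRecord,
    ]
    provenance: str = ""


def _death_probability(
    action: ClinicalAction, truth: GroundTruth, cl: ClinicalParams
) -> float:
    """30-day mortality of a cell.

    Every patient in the suspected-ARTI cohort carries the baseline
    mortality; true high-risk (septic) patients carry the septic-ICU level,
    reduced by the timely-admission fraction when the action puts them in
    the ICU; viral-only non-severe patients treated with oseltamivir carry
    the viral-specific level.
    """
    if truth.mortality_risk:
        p = cl.mortality_septic_icu_viral
        if action.disposition == "icu_admit":
            p *= 1.0 - cl.mortality_reduction_timely
        return p
    if truth.viral and not truth.bacterial and action.oseltamivir_given:
        return cl.mortality_viral
    return cl.mortality_arti


def _base_stay(
    combo: PredictionCombo,
    action: ClinicalAction,
    truth: GroundTruth,
    cl: ClinicalParams,
) -> tuple[float, float, float, list[tuple[str, float]]]:
    """Ward days, ICU days, antibiotic days and cost events of the initial
    episode implied by the action (before any missed-diagnosis correction)."""
    ward = icu = abx = 0.0
    events: list[tuple[str, float]] = [("ed_visit_incl_pct", 1.0)]
    if action.disposition == "icu_admit":
        icu = cl.los_icu
        abx = cl.antibiotic_days_icu
        events += [("icu_day", icu), ("abx_iv_icu_per_day", abx)]
    elif action.disposition == "ward_admit":
        # extended stay when the patient is truly severe (deterioration) or
        # was admitted on a high mortality band (care follows the score)
        extended = truth.mortality_risk or combo.mortality_band == "high"
        ward = cl.rehosp_icu_los if extended else cl.los_short_ward
        abx = cl.antibiotic_days_ward
        events += [("ward_day", ward), ("abx_oral_iv_ward", 1.0)]
        if truth.mortality_risk:
            # deterioration on the ward: escalation to ICU-grade antibiotics
            abx += cl.antibiotic_days_icu
            events.append(("abx_iv_icu_per_day", cl.antibiotic_days_icu))
    elif action.disposition == "ed_observation":
        abx = cl.antibiotic_days_ed
        events.append(("abx_oral_outpatient", 1.0))
    if action.blood_culture_ordered:
        events.append(("blood_culture", 1.0))
    if action.viral_pcr_ordered:
        events.append(("pcr_viral", 1.0))
    if action.oseltamivir_given:
        events.append(("oseltamivir_course", 1.0))
    return ward, icu, abx, events


def _build_standard(combo, action, truth, cl) -> OutcomeRecord:
    ward, icu, abx, events = _base_stay(combo, action, truth, cl)
    return OutcomeRecord(
        hospital_ward_days=ward,
        icu_days=icu,
        antibiotic_days=abx,
        death_probability=_death_probability(action, truth, cl),
        readmission=False,
        cost_events=tuple(events),
    )


def _build_missed_severe(combo, action, truth, cl) -> OutcomeRecord:
    ward, icu, abx, events = _base_stay(combo, action, truth, cl)
    p = _death_probability(action, truth, cl)  # unreduced: not in ICU
    events.append(
        ("missed_bact_with_mort" if truth.bacterial else "missed_mort_no_bact", 1.0)
    )
    # rehospitalization: survivors spend the rehosp ICU stay, nonsurvivors
    # the nonsurvivor stay; antibiotics at ICU course length
    return OutcomeRecord(
        hospital_ward_days=ward + p * cl.nonsurvivor_los,
        icu_days=icu + (1.0 - p) * cl.rehosp_icu_los,
        antibiotic_days=abx + cl.antibiotic_days_icu,
        death_probability=p,
        readmission=True,
        cost_events=tuple(events),
        ward_days_if_death=ward + cl.nonsurvivor_los,
        icu_days_if_death=icu,
    )


def _build_missed_bacterial(combo, action, truth, cl) -> OutcomeRecord:
    ward, icu, abx, events = _base_stay(combo, action, truth, cl)
    events.append(("missed_bact_no_mort", 1.0))
    return OutcomeRecord(
        hospital_ward_days=ward + 1.0,
        icu_days=icu,
        antibiotic_days=abx + cl.antibiotic_days_ed,
        death_probability=_death_probability(action, truth, cl),
        readmission=True,
        cost_events=tuple(events),
    )


def _default_rules() -> tuple[OutcomeRule, ...]:
    return (
        OutcomeRule(
            name="missed_severe",
            applies=lambda c, a, t: t.mortality_risk and not a.admitted,
            build=_build_missed_severe,
            provenance=(
                "truly high-mortality patient sent home or held in "
                "observation: 7-day-style readmission, costed by the "
                "missed-with-mortality composite; rehospitalization stay "
                "8.30 ICU days for survivors, 19.90 days for nonsurvivors; "
                "timely-admission mortality reduction forfeited"
            ),
        ),
        OutcomeRule(
            name="missed_bacterial",
            applies=lambda c, a, t: t.bacterial and not a.any_antibiotics,
            build=_build_missed_bacterial,
            provenance=(
                "bacterial infection discharged without antibiotics: "
                "+1 hospital day composite penalty plus a short oral course "
                "at readmission"
            ),
        ),
        OutcomeRule(
            name="standard_care",
            applies=lambda c, a, t: True,
            build=_build_standard,
            provenance=(
                "care as actioned: setting-specific length of stay and "
                "antibiotic course; true severity extends a ward stay to the "
                "rehospitalization length with antibiotic escalation"
            ),
        ),
    )


# ---------------------------------------------------------------------------
# ledger
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ledger:
    """Action map over the 18 combos plus ordered outcome rules."""

    action_map: dict[PredictionCombo, ClinicalAction]
    outcome_rules: tuple[OutcomeRule, ...]
    provenance: dict[PredictionCombo, str] = field(default_factory=dict)
    schema: str = ACTION_MAP_SCHEMA

    def with_action_map(self, action_map, provenance=None) -> "Ledger":
        return replace(
            self, action_map=dict(action_map), provenance=dict(provenance or {})
        )


def default_ledger() -> Ledger:
    """The shipped reconstruction of the action/outcome assignments."""
    amap, notes = {}, {}
    for combo in enumerate_combos():
        amap[combo], notes[combo] = _default_action(combo)
    return Ledger(action_map=amap, outcome_rules=_default_rules(), provenance=notes)


def action_for(combo: PredictionCombo, ledger: Ledger) -> ClinicalAction:
    """Look up the suggested action for a prediction combination."""
    try:
        return ledger.action_map[combo]
    except KeyError:
        missing = [c for c in enumerate_combos() if c not in ledger.action_map]
        raise LedgerError(
            f"ledger action map does not cover {len(missing)} combos, "
            f"including {missing[0]}"
        ) from None


def outcome_for(
    combo: PredictionCombo,
    truth: GroundTruth,
    ledger: Ledger,
    clinical: ClinicalParams,
) -> OutcomeRecord:
    """Outcome record of one cell: first matching rule wins."""
    action = action_for(combo, ledger)
    for rule in ledger.outcome_rules:
        if rule.applies(combo, action, truth):
            return rule.build(combo, action, truth, clinical)
    raise LedgerError(
        f"no outcome rule matches cell ({combo}, {truth}); "
        "ledger failed coverage"
    )


@dataclass
class ValidationReport:
    ok: bool
    missing_combos: list[PredictionCombo]
    uncovered_cells: list[tuple[PredictionCombo, GroundTruth]]
    invalid_cells: list[tuple[PredictionCombo, GroundTruth, str]]
    unreachable_rules: list[str]
    n_cells_covered: int = 0


def validate_ledger(
    ledger: Ledger, clinical: ClinicalParams | None = None
) -> ValidationReport:
    """Exhaustively check totality over 18 combos / 144 cells, invariant
    compliance of every produced record, and rule reachability."""
    clinical = clinical or ClinicalParams()
    missing = [c for c in enumerate_combos() if c not in ledger.action_map]
    uncovered, invalid = [], []
    hits = {r.name: 0 for r in ledger.outcome_rules}
    covered = 0
    if not missing:
        for combo, truth in enumerate_cells():
            action = ledger.action_map[combo]
            matched = False
            for rule in ledger.outcome_rules:
                if rule.applies(combo, action, truth):
                    matched = True
                    hits[rule.name] += 1
                    try:
                        rec = rule.build(combo, action, truth, clinical)
                        if rec.readmission and action.admitted:
                            raise ValueError(
                                "readmission flagged for an admitted patient"
                            )
                        covered += 1
                    except ValueError as exc:
                        invalid.append((combo, truth, f"{rule.name}: {exc}"))
                    break
            if not matched:
                uncovered.append((combo, truth))
    unreachable = [name for name, n in hits.items() if n == 0]
    ok = not (missing or uncovered or invalid or unreachable)
    return ValidationReport(
        ok=ok,
        missing_combos=missing,
        uncovered_cells=uncovered,
        invalid_cells=invalid,
        unreachable_rules=unreachable,
        n_cells_covered=covered,
    )


# ---------------------------------------------------------------------------
# action-map serialization (human-editable CSV)
# ---------------------------------------------------------------------------

_ACTION_COLUMNS = [
    "schema",
    "bacterial_band",
    "viral_band",
    "mortality_band",
    "disposition",
    "antibiotic_regimen",
    "viral_pcr_ordered",
    "oseltamivir_given",
    "blood_culture_ordered",
    "provenance",
]


def action_map_to_csv(ledger: Ledger) -> str:
    """18-row CSV of the action map, editable and round-trippable."""
    rows = []
    for combo in enumerate_combos():
        a = ledger.action_map[combo]
        rows.append(
            {
                "schema": ledger.schema,
                "bacterial_band": combo.bacterial_band,
                "viral_band": combo.viral_band,
                "mortality_band": combo.mortality_band,
                "disposition": a.disposition,
                "antibiotic_regimen": a.antibiotic_regimen,
                "viral_pcr_ordered": a.viral_pcr_ordered,
                "oseltamivir_given": a.oseltamivir_given,
                "blood_culture_ordered": a.blood_culture_ordered,
                "provenance": ledger.provenance.get(combo, ""),
            }
        )
    return pd.DataFrame(rows, columns=_ACTION_COLUMNS).to_csv(index=False)


def action_map_from_csv(text: str, base: Ledger | None = None) -> Ledger:
    """Parse an action-map CSV back into a ledger (strict schema).

    Unknown columns, a wrong schema tag, or missing combos are errors. The
    outcome rules are taken from ``base`` (default shipped rules).
    """
    base = base or default_ledger()
    df = pd.read_csv(io.StringIO(text), dtype=str).fillna("")
    extra = set(df.columns) - set(_ACTION_COLUMNS)
    if extra:
        raise LedgerError(f"unknown action-map columns: {sorted(extra)}")
    missing_cols = set(_ACTION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise LedgerError(f"missing action-map columns: {sorted(missing_cols)}")
    bad_schema = set(df["schema"]) - {ACTION_MAP_SCHEMA}
    if bad_schema:
        raise LedgerError(f"unsupported action-map schema tag(s): {bad_schema}")
    amap, notes = {}, {}
    for _, row in df.iterrows():
        combo = PredictionCombo(
            row["bacterial_band"], row["viral_band"], row["mortality_band"]
        )
        if combo in amap:
            raise LedgerError(f"duplicate action-map row for {combo}")
        amap[combo] = ClinicalAction(
            disposition=row["disposition"],
            antibiotic_regimen=row["antibiotic_regimen"],
            viral_pcr_ordered=row["viral_pcr_ordered"] == "True",
            oseltamivir_given=row["oseltamivir_given"] == "True",
            blood_culture_ordered=row["blood_culture_ordered"] == "True",
        )
        notes[combo] = row["provenance"]
    absent = [c for c in enumerate_combos() if c not in amap]
    if absent:
        raise LedgerError(f"action map missing {len(absent)} combos: {absent[:3]}")
    return base.with_action_map(amap, notes)
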