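"""Deterministic expectation engine over the 144-cell decision tree.

For a scenario (three readout AUROCs, prevalences, clinical parameters,
costs, a ledger and a cohort size) the engine solves the band profiles,
forms the joint distribution over the 8 ground-truth states, computes each
cell's occupancy as

    cohort_size * P(truth) * P(prediction combo | truth)

with the three readouts conditionally independent given truth, prices each
cell's outcome record against the cost catalog, and aggregates to the
cohort level: mean hospital (ward) days, ICU days, antibiotic days, 30-day
mortality, and per-patient / total cost, plus an 8-row by-truth breakdown.
Two scenario results difference into a comparison table; the reimbursement
helpers cover the payer-arithmetic around the new test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decision_rules import (
    ClinicalAction,
    ClinicalParams,
    CostParams,
    GroundTruth,
    Ledger,
    OutcomeRecord,
    PredictionCombo,
    default_ledger,
    enumerate_combos,
    enumerate_truths,
    validate_ledger,
)
from .roc_banding import BandProfile, ReadoutSpec, solve_band_cutoffs

__all__ = [
    "EpidemiologyParams",
    "ScenarioConfig",
    "DecisionCell",
    "CohortResult",
    "ScenarioComparison",
    "base_case_config",
    "hostdx_config",
    "joint_truth_distribution",
    "prediction_probability",
    "run_scenario",
    "compare_scenarios",
    "cms_reimbursement",
    "net_savings_after_reimbursement",
    "annual_hospital_savings",
]

READOUT_NAMES = ("bacterial", "viral", "mortality")

#: base-case (procalcitonin standard of care) and host-response AUROCs
BASE_CASE_AUROCS = {"bacterial": 0.80, "viral": 0.80, "mortality": 0.78}
HOSTDX_AUROCS = {"bacterial": 0.85, "viral": 0.90, "mortality": 0.88}

#: 2020 clinical lab fee schedule components for the host-response assay:
#: full rate for the 12-25-target RNA panel code plus half the 6-11-target
#: panel rate.
CMS_RATE_87507 = 416.78
CMS_RATE_87506 = 218.06

#: ED patients with suspected acute respiratory infection seen per hospital
#: per year, for the annual-savings projection.
ANNUAL_ARTI_PATIENTS_PER_HOSPITAL = 750


@dataclass(frozen=True)
class EpidemiologyParams:
    """Prevalences of the four infection states and of true mortality risk.

    The four infection-state probabilities must sum to one; mortality risk
    is crossed with infection state independently (an optional explicit
    8-vector ``joint_override`` in truth-enumeration order replaces the
    product construction)."""

    p_bacterial_only: float = 0.25
    p_viral_only: float = 0.45
    p_coinfection: float = 0.10
    p_no_infection: float = 0.20
    p_mortality_risk: float = 0.10
    joint_override: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        probs = (
            self.p_bacterial_only,
            self.p_viral_only,
            self.p_coinfection,
            self.p_no_infection,
            self.p_mortality_risk,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("EpidemiologyParams: probabilities must lie in [0, 1]")
        s = sum(probs[:4])
        if abs(s - 1.0) > 1e-12:
            raise ValueError(
                f"EpidemiologyParams: infection-state probabilities sum to {s!r}, "
                "expected 1"
            )
        if self.joint_override is not None:
            j = np.asarray(self.joint_override, dtype=float)
            if j.shape != (8,) or (j < 0).any() or abs(j.sum() - 1.0) > 1e-12:
                raise ValueError(
                    "joint_override must be 8 nonnegative probabilities summing to 1"
                )


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run one scenario deterministically."""

    label: str
    readout_specs: dict[str, ReadoutSpec]
    epidemiology: EpidemiologyParams = field(default_factory=EpidemiologyParams)
    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    costs: CostParams = field(default_factory=CostParams)
    ledger: Ledger = field(default_factory=default_ledger)
    cohort_size: float = 1000
    charge_test_cost: bool = False
    lr_convention: str = "band"

    def __post_init__(self) -> None:
        if not self.cohort_size >= 0:
            raise ValueError("cohort_size must be >= 0")
        if set(self.readout_specs) != set(READOUT_NAMES):
            raise ValueError(
                f"readout_specs must cover exactly {set(READOUT_NAMES)}, "
                f"got {set(self.readout_specs)}"
            )

    def aurocs(self) -> dict[str, float]:
        return {k: v.auroc for k, v in self.readout_specs.items()}


def _make_specs(aurocs: dict[str, float], lr_low=0.1, lr_high=10.0):
    return {
        "bacterial": ReadoutSpec("bacterial", aurocs["bacterial"], 3, lr_low, lr_high),
        "viral": ReadoutSpec("viral", aurocs["viral"], 2, lr_low, lr_high),
        "mortality": ReadoutSpec("mortality", aurocs["mortality"], 3, lr_low, lr_high),
    }


def base_case_config(**overrides) -> ScenarioConfig:
    """Standard-of-care (procalcitonin) scenario at default parameters."""
    return ScenarioConfig(
        label="base_case", readout_specs=_make_specs(BASE_CASE_AUROCS), **overrides
    )


def hostdx_config(**overrides) -> ScenarioConfig:
    """Host-response-assay scenario: identical except the three AUROCs (the
    assay's cost is carried at its configured value, 0 by default)."""
    overrides.setdefault("charge_test_cost", True)
    return ScenarioConfig(
        label="hostdx", readout_specs=_make_specs(HOSTDX_AUROCS), **overrides
    )


# ---------------------------------------------------------------------------
# probabilities
# ---------------------------------------------------------------------------

def joint_truth_distribution(epi: EpidemiologyParams) -> pd.Series:
    """Probability of each of the 8 ground-truth states.

    Infection states map to (bacterial, viral) booleans and cross with
    mortality risk independently unless an explicit joint is configured.
    Returned as a Series indexed by GroundTruth in canonical order,
    summing to 1."""
    truths = enumerate_truths()
    if epi.joint_override is not None:
        return pd.Series(list(epi.joint_override), index=truths, dtype=float)
    p_inf = {
        (False, False): epi.p_no_infection,
        (False, True): epi.p_viral_only,
        (True, False): epi.p_bacterial_only,
        (True, True): epi.p_coinfection,
    }
    vals = [
        p_inf[(t.bacterial, t.viral)]
        * (epi.p_mortality_risk if t.mortality_risk else 1.0 - epi.p_mortality_risk)
        for t in truths
    ]
    return pd.Series(vals, index=truths, dtype=float)


def prediction_probability(
    combo: PredictionCombo,
    truth: GroundTruth,
    profiles: dict[str, BandProfile],
) -> float:
    """P(prediction combo | truth): product of the three per-readout band
    probabilities, each conditioned on that readout's truth bit."""
    p = 1.0
    for name, band, bit in (
        ("bacterial", combo.bacterial_band, truth.bacterial),
        ("viral", combo.viral_band, truth.viral),
        ("mortality", combo.mortality_band, truth.mortality_risk),
    ):
        prof = profiles[name]
        idx = prof.band_names.index(band)
        vec = prof.p_band_given_positive if bit else prof.p_band_given_negative
        p *= float(vec[idx])
    return p


# ---------------------------------------------------------------------------
# scenario evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionCell:
    """One (prediction, truth) cell with its expected patient mass."""

    combo: PredictionCombo
    truth: GroundTruth
    action: ClinicalAction
    outcome: OutcomeRecord
    expected_patients: float
    cost_per_patient: float


@dataclass(frozen=True)
class CohortResult:
    """Aggregated scenario result (the shape of the paper-style tables)."""

    label: str
    cohort_size: float
    per_cell: tuple[DecisionCell, ...]
    profiles: dict[str, BandProfile]
    mean_hospital_days: float
    mean_icu_days: float
    mean_antibiotic_days: float
    mortality_fraction: float
    cost_per_patient: float
    total_cost: float
    expected_deaths: float
    by_truth: pd.DataFrame = field(repr=False)

    def cell_table(self) -> pd.DataFrame:
        """144-row table of the full decision tree."""
        rows = []
        for c in self.per_cell:
            rows.append(
                {
                    "bacterial_band": c.combo.bacterial_band,
                    "viral_band": c.combo.viral_band,
                    "mortality_band": c.combo.mortality_band,
                    "truth_bacterial": c.truth.bacterial,
                    "truth_viral": c.truth.viral,
                    "truth_mortality_risk": c.truth.mortality_risk,
                    "disposition": c.action.disposition,
                    "antibiotic_regimen": c.action.antibiotic_regimen,
                    "expected_patients": c.expected_patients,
                    "hospital_ward_days": c.outcome.hospital_ward_days,
                    "icu_days": c.outcome.icu_days,
                    "antibiotic_days": c.outcome.antibiotic_days,
                    "death_probability": c.outcome.death_probability,
                    "readmission": c.outcome.readmission,
                    "cost_per_patient": c.cost_per_patient,
                    "expected_cost": c.expected_patients * c.cost_per_patient,
                }
            )
        return pd.DataFrame(rows)


def run_scenario(config: ScenarioConfig, validate: bool = True) -> CohortResult:
    """Evaluate one scenario exactly (no sampling)."""
    if validate:
        report = validate_ledger(config.ledger, config.clinical)
        if not report.ok:
            raise ValueError(
                f"scenario {config.label!r}: ledger failed validation "
                f"(missing={len(report.missing_combos)}, "
                f"uncovered={len(report.uncovered_cells)}, "
                f"invalid={len(report.invalid_cells)}, "
                f"unreachable={report.unreachable_rules})"
            )
    profiles = {
        name: solve_band_cutoffs(spec, convention=config.lr_convention)
        for name, spec in config.readout_specs.items()
    }
    p_truth = joint_truth_distribution(config.epidemiology)
    test_cost = config.costs.hostdx_test_cost if config.charge_test_cost else 0.0

    cells = []
    n = float(config.cohort_size)
    tot = {"ward": 0.0, "icu": 0.0, "abx": 0.0, "deaths": 0.0, "cost": 0.0}
    by_truth: dict[GroundTruth, dict[str, float]] = {
        t: {"patients": 0.0, "cost": 0.0, "ward": 0.0, "icu": 0.0,
            "abx": 0.0, "deaths": 0.0}
        for t in enumerate_truths()
    }
    for combo in enumerate_combos():
        action = config.ledger.action_map[combo]
        for truth in enumerate_truths():
            mass = n * float(p_truth[truth]) * prediction_probability(
                combo, truth, profiles
            )
            outcome = None
            for rule in config.ledger.outcome_rules:
                if rule.applies(combo, action, truth):
                    outcome = rule.build(combo, action, truth, config.clinical)
                    break
            assert outcome is not None  # validation guarantees coverage
            cost = config.costs.price(outcome.cost_events) + test_cost
            cells.append(
                DecisionCell(combo, truth, action, outcome, mass, cost)
            )
            tot["ward"] += mass * outcome.hospital_ward_days
            tot["icu"] += mass * outcome.icu_days
            tot["abx"] += mass * outcome.antibiotic_days
            tot["deaths"] += mass * outcome.death_probability
            tot["cost"] += mass * cost
            bt = by_truth[truth]
            bt["patients"] += mass
            bt["cost"] += mass * cost
            bt["ward"] += mass * outcome.hospital_ward_days
            bt["icu"] += mass * outcome.icu_days
            bt["abx"] += mass * outcome.antibiotic_days
            bt["deaths"] += mass * outcome.death_probability

    denom = n if n > 0 else 1.0
    by_truth_df = pd.DataFrame(
        [
            {
                "truth_bacterial": t.bacterial,
                "truth_viral": t.viral,
                "truth_mortality_risk": t.mortality_risk,
                "patients": v["patients"],
                "cost": v["cost"],
                "antibiotic_days": v["abx"],
                "hospital_days": v["ward"],
                "icu_days": v["icu"],
                "deaths": v["deaths"],
            }
            for t, v in by_truth.items()
        ]
    )
    return CohortResult(
        label=config.label,
        cohort_size=n,
        per_cell=tuple(cells),
        profiles=profiles,
        mean_hospital_days=tot["ward"] / denom,
        mean_icu_days=tot["icu"] / denom,
        mean_antibiotic_days=tot["abx"] / denom,
        mortality_fraction=tot["deaths"] / denom,
        cost_per_patient=tot["cost"] / denom,
        total_cost=tot["cost"],
        expected_deaths=tot["deaths"],
        by_truth=by_truth_df,
    )


@dataclass(frozen=True)
class ScenarioComparison:
    """Differences (alternative minus base) and percent changes."""

    base: CohortResult
    alt: CohortResult
    table: pd.DataFrame = field(repr=False)

    @property
    def per_patient_savings(self) -> float:
        """Base minus alternative cost per patient (positive = alt cheaper)."""
        return self.base.cost_per_patient - self.alt.cost_per_patient


def compare_scenarios(base: CohortResult, alt: CohortResult) -> ScenarioComparison:
    """Aggregate comparison of two scenario runs on the same cohort."""
    if abs(base.cohort_size - alt.cohort_size) > 1e-9:
        raise ValueError(
            f"cohort sizes differ: {base.cohort_size} vs {alt.cohort_size}"
        )
    rows = []
    for label, attr, scale in (
        ("hospital_days", "mean_hospital_days", 1.0),
        ("icu_days", "mean_icu_days", 1.0),
        ("antibiotic_days", "mean_antibiotic_days", 1.0),
        ("mortality_30d", "mortality_fraction", 100.0),
        ("cost_per_patient", "cost_per_patient", 1.0),
        ("total_cost", "total_cost", 1.0),
    ):
        b = getattr(base, attr) * scale
        a = getattr(alt, attr) * scale
        diff = a - b
        rows.append(
            {
                "quantity": label,
                base.label: b,
                alt.label: a,
                "difference": diff,
                "pct_change": (100.0 * diff / b) if b != 0 else float("nan"),
            }
        )
    return ScenarioComparison(base=base, alt=alt, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# payer arithmetic
# ---------------------------------------------------------------------------

def cms_reimbursement(
    rate_87507: float = CMS_RATE_87507, rate_87506: float = CMS_RATE_87506
) -> float:
    """Expected lab-fee reimbursement for the assay: the 12-25-probe panel
    rate plus half of the 6-11-probe panel rate."""
    return round(rate_87507 + 0.5 * rate_87506, 2)


def net_savings_after_reimbursement(
    per_patient_savings: float, reimbursement: float
) -> float:
    """Savings floor if the test is priced at the reimbursement rate."""
    if per_patient_savings < 0 or reimbursement < 0:
        raise ValueError("savings and reimbursement must be >= 0")
    return round(per_patient_savings - reimbursement, 2)


def annual_hospital_savings(
    per_patient_savings: float,
    annual_patients: float = ANNUAL_ARTI_PATIENTS_PER_HOSPITAL,
) -> float:
    """Projected yearly savings for an average hospital's ED ARTI volume."""
    return per_patient_savings * annual_patients
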