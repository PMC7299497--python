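"""Patient-level Monte Carlo oracle and synthetic parameter sets.

The microsimulation brute-forces the same model the deterministic engine
evaluates in expectation: it samples each patient's ground truth from the
joint prevalence distribution, draws one continuous score per readout from
the binormal component matching the truth bit, bands the scores with the
scenario's solved cutoffs, applies the identical ledger and cost catalog,
and samples the death lottery (which also decides stay length in
missed-severity cells). Agreement of its empirical aggregates with the
closed-form expectations, within Monte Carlo error, validates the engine's
patient-placement algebra end to end.

Sampling uses one root seed with per-variable child streams (truth, three
score streams, death), so extending ``n`` leaves earlier patients'
draws unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_engine import (
    ScenarioConfig,
    joint_truth_distribution,
    run_scenario,
)
from .decision_rules import enumerate_combos, enumerate_truths, validate_ledger
from .roc_banding import solve_band_cutoffs
from .sensitivity import (
    ParameterPerturbation,
    _set_on_config,
    default_perturbation_set,
)

__all__ = [
    "SimulatedCohort",
    "SyntheticParameterSet",
    "simulate_cohort",
    "generate_parameter_sets",
]


@dataclass(frozen=True)
class SimulatedCohort:
    """Empirical aggregates of a sampled cohort, with standard errors."""

    label: str
    n: int
    seed: int
    means: dict[str, float]
    standard_errors: dict[str, float]
    band_frequencies: dict[str, np.ndarray] = field(repr=False)
    patients: pd.DataFrame | None = field(default=None, repr=False)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": list(self.means),
                "mean": list(self.means.values()),
                "standard_error": [
                    self.standard_errors[k] for k in self.means
                ],
            }
        )


def _cell_arrays(config: ScenarioConfig):
    """Flatten the 144 cells into lookup arrays indexed by
    combo_index * 8 + truth_index."""
    combos = enumerate_combos()
    truths = enumerate_truths()
    ncell = len(combos) * len(truths)
    cost = np.empty(ncell)
    abx = np.empty(ncell)
    p_death = np.empty(ncell)
    ward_surv = np.empty(ncell)
    ward_death = np.empty(ncell)
    icu_surv = np.empty(ncell)
    icu_death = np.empty(ncell)
    test_cost = config.costs.hostdx_test_cost if config.charge_test_cost else 0.0
    for ci, combo in enumerate(combos):
        action = config.ledger.action_map[combo]
        for ti, truth in enumerate(truths):
            for rule in config.ledger.outcome_rules:
                if rule.applies(combo, action, truth):
                    rec = rule.build(combo, action, truth, config.clinical)
                    break
            k = ci * len(truths) + ti
            cost[k] = config.costs.price(rec.cost_events) + test_cost
            abx[k] = rec.antibiotic_days
            p_death[k] = rec.death_probability
            ward_surv[k] = rec.ward_days_if_survival
            ward_death[k] = rec.ward_days_if_death
            icu_surv[k] = rec.icu_days_if_survival
            icu_death[k] = rec.icu_days_if_death
    return cost, abx, p_death, ward_surv, ward_death, icu_surv, icu_death


def simulate_cohort(
    config: ScenarioConfig,
    n: int,
    seed: int,
    return_patients: bool = False,
) -> SimulatedCohort:
    """Sample ``n`` patients and return empirical aggregates.

    Fully reproducible: identical (config, n, seed) triples give identical
    results, and a larger ``n`` extends rather than reshuffles the cohort.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    report = validate_ledger(config.ledger, config.clinical)
    if not report.ok:
        raise ValueError(f"ledger failed validation: {report}")

    root = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(5)]
    rng_truth, rng_bact, rng_viral, rng_mort, rng_death = streams

    p_truth = joint_truth_distribution(config.epidemiology).to_numpy()
    truth_idx = np.searchsorted(np.cumsum(p_truth), rng_truth.random(n), side="right")
    truth_idx = np.minimum(truth_idx, 7)
    # truth bits in canonical enumeration order: bacterial, viral, mortality
    t_bact = truth_idx // 4
    t_viral = (truth_idx // 2) % 2
    t_mort = truth_idx % 2

    profiles = {
        name: solve_band_cutoffs(spec, convention=config.lr_convention)
        for name, spec in config.readout_specs.items()
    }

    def band_of(rng, name, bit):
        prof = profiles[name]
        scores = rng.standard_normal(n) + prof.d_prime * bit
        return np.searchsorted(np.asarray(prof.cutoffs), scores), scores

    b_band, b_score = band_of(rng_bact, "bacterial", t_bact)
    v_band, v_score = band_of(rng_viral, "viral", t_viral)
    m_band, m_score = band_of(rng_mort, "mortality", t_mort)

    combo_idx = (b_band * 2 + v_band) * 3 + m_band
    cell_idx = combo_idx * 8 + truth_idx

    cost, abx, p_death, w_s, w_d, i_s, i_d = _cell_arrays(config)
    died = rng_death.random(n) < p_death[cell_idx]
    ward = np.where(died, w_d[cell_idx], w_s[cell_idx])
    icu = np.where(died, i_d[cell_idx], i_s[cell_idx])
    samples = {
        "hospital_days": ward,
        "icu_days": icu,
        "antibiotic_days": abx[cell_idx],
        "mortality_30d": died.astype(float),
        "cost_per_patient": cost[cell_idx],
    }
    means = {k: float(v.mean()) for k, v in samples.items()}
    ses = {k: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
           for k, v in samples.items()}
    freqs = {
        "bacterial": np.bincount(b_band, minlength=3) / n,
        "viral": np.bincount(v_band, minlength=2) / n,
        "mortality": np.bincount(m_band, minlength=3) / n,
    }
    patients = None
    if return_patients:
        patients = pd.DataFrame(
            {
                "truth_bacterial": t_bact.astype(bool),
                "truth_viral": t_viral.astype(bool),
                "truth_mortality_risk": t_mort.astype(bool),
                "score_bacterial": b_score,
                "score_viral": v_score,
                "score_mortality": m_score,
                "bacterial_band": b_band,
                "viral_band": v_band,
                "mortality_band": m_band,
                "died": died,
                "hospital_ward_days": ward,
                "icu_days": icu,
                "antibiotic_days": abx[cell_idx],
                "cost": cost[cell_idx],
            }
        )
    return SimulatedCohort(
        label=config.label,
        n=n,
        seed=seed,
        means=means,
        standard_errors=ses,
        band_frequencies=freqs,
        patients=patients,
    )


def deterministic_reference(config: ScenarioConfig) -> dict[str, float]:
    """The engine's expectations keyed like :attr:`SimulatedCohort.means`."""
    res = run_scenario(config)
    return {
        "hospital_days": res.mean_hospital_days,
        "icu_days": res.mean_icu_days,
        "antibiotic_days": res.mean_antibiotic_days,
        "mortality_30d": res.mortality_fraction,
        "cost_per_patient": res.cost_per_patient,
    }


@dataclass(frozen=True)
class SyntheticParameterSet:
    """One sampled, validated scenario configuration."""

    config: ScenarioConfig
    seed: int


def generate_parameter_sets(
    n: int,
    seed: int,
    template: ScenarioConfig | None = None,
    ranges: list[ParameterPerturbation] | None = None,
) -> list[SyntheticParameterSet]:
    """Latin-hypercube spread of scenario configs over perturbation ranges.

    Each range contributes one dimension; sampled infection-state
    prevalences are renormalized to sum to one (the assignment machinery
    rescales the remaining states at each set). Every returned config has
    passed dataclass validation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from scipy.stats import qmc

    if template is None:
        from .cohort_engine import base_case_config

        template = base_case_config()
    if ranges is None:
        ranges = [
            p
            for p in default_perturbation_set(template)
            if not p.parameter_path.startswith(("base.", "alt."))
        ] + [
            ParameterPerturbation(
                f"readouts.{r}.auroc",
                max(0.51, template.readout_specs[r].auroc - 0.05),
                min(0.99, template.readout_specs[r].auroc + 0.05),
                range_source="literature_range",
            )
            for r in ("bacterial", "viral", "mortality")
        ]
    sampler = qmc.LatinHypercube(d=len(ranges), seed=seed)
    unit = sampler.random(n)
    out = []
    for i in range(n):
        cfg = template
        for j, pert in enumerate(ranges):
            value = pert.low_value + unit[i, j] * (
                pert.high_value - pert.low_value
            )
            cfg = _set_on_config(cfg, pert.parameter_path.split("."), value)
        cfg = ScenarioConfig(
            label=f"{template.label}_synthetic_{i}",
            readout_specs=cfg.readout_specs,
            epidemiology=cfg.epidemiology,
            clinical=cfg.clinical,
            costs=cfg.costs,
            ledger=cfg.ledger,
            cohort_size=cfg.cohort_size,
            charge_test_cost=cfg.charge_test_cost,
            lr_convention=cfg.lr_convention,
        )
        out.append(SyntheticParameterSet(config=cfg, seed=seed + i))
    return out
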