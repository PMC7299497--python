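"""One-way deterministic sensitivity analysis (tornado) on the cost model.

Each perturbation moves a single parameter to a low and a high value —
costs, clinical outcomes and prevalences move identically in both
scenarios, test accuracies target one named scenario — reruns the two
scenarios, and records the net per-patient savings. Entries are ranked by
their swing (largest absolute deviation from the unperturbed savings),
the ordering a tornado diagram plots.

Parameter paths are dotted names into the scenario configuration:
``costs.ward_day``, ``clinical.los_icu``, ``epidemiology.p_viral_only``,
and for accuracies ``base.readouts.mortality.auroc`` /
``alt.readouts.bacterial.auroc``. Perturbing one infection-state prevalence
rescales the other three so the four still sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import pandas as pd

from .cohort_engine import ScenarioConfig, run_scenario
from .decision_rules import ClinicalParams, CostParams
from .roc_banding import ReadoutSpec

__all__ = [
    "ParameterPerturbation",
    "TornadoEntry",
    "set_parameter",
    "one_way_dsa",
    "default_perturbation_set",
    "tornado_table",
]

AUROC_RANGE_HALF_WIDTH = 0.05
AUROC_BOUNDS = (0.501, 0.99)
_INFECTION_STATES = (
    "p_bacterial_only",
    "p_viral_only",
    "p_coinfection",
    "p_no_infection",
)


@dataclass(frozen=True)
class ParameterPerturbation:
    """Low/high values for one dotted parameter path."""

    parameter_path: str
    low_value: float
    high_value: float
    range_source: str = "fixed_fraction_20pct"

    def __post_init__(self) -> None:
        if self.low_value > self.high_value:
            raise ValueError(
                f"{self.parameter_path}: low {self.low_value} > high "
                f"{self.high_value}"
            )


@dataclass(frozen=True)
class TornadoEntry:
    parameter_path: str
    base_net_impact: float
    net_impact_at_low: float
    net_impact_at_high: float

    @property
    def swing(self) -> float:
        return max(
            abs(self.net_impact_at_low - self.base_net_impact),
            abs(self.net_impact_at_high - self.base_net_impact),
        )


def _set_on_config(config: ScenarioConfig, path: list[str], value: float):
    head = path[0]
    if head == "costs":
        (fname,) = path[1:]
        return replace(config, costs=replace(config.costs, **{fname: value}))
    if head == "clinical":
        (fname,) = path[1:]
        return replace(config, clinical=replace(config.clinical, **{fname: value}))
    if head == "epidemiology":
        (fname,) = path[1:]
        epi = config.epidemiology
        if fname in _INFECTION_STATES:
            # rescale the remaining states so the four sum to one
            value = min(max(value, 0.0), 1.0)
            rest = [s for s in _INFECTION_STATES if s != fname]
            rest_sum = sum(getattr(epi, s) for s in rest)
            scale = (1.0 - value) / rest_sum if rest_sum > 0 else 0.0
            updates = {s: getattr(epi, s) * scale for s in rest}
            updates[fname] = value
            return replace(config, epidemiology=replace(epi, **updates))
        return replace(config, epidemiology=replace(epi, **{fname: value}))
    if head == "readouts":
        name, attr = path[1], path[2]
        if name not in config.readout_specs:
            raise KeyError(name)
        spec = config.readout_specs[name]
        specs = dict(config.readout_specs)
        specs[name] = ReadoutSpec(
            spec.name,
            value if attr == "auroc" else spec.auroc,
            spec.n_bands,
            value if attr == "lr_low" else spec.lr_low,
            value if attr == "lr_high" else spec.lr_high,
        )
        if attr not in ("auroc", "lr_low", "lr_high"):
            raise KeyError(attr)
        return replace(config, readout_specs=specs)
    raise KeyError(head)


def set_parameter(
    base: ScenarioConfig,
    alt: ScenarioConfig,
    parameter_path: str,
    value: float,
) -> tuple[ScenarioConfig, ScenarioConfig]:
    """Return new configs with one parameter set; shared paths touch both."""
    parts = parameter_path.split(".")
    try:
        if parts[0] == "base":
            return _set_on_config(base, parts[1:], value), alt
        if parts[0] == "alt":
            return base, _set_on_config(alt, parts[1:], value)
        return (
            _set_on_config(base, parts, value),
            _set_on_config(alt, parts, value),
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise KeyError(
            f"parameter path {parameter_path!r} does not resolve: {exc}"
        ) from exc


def one_way_dsa(
    base_config: ScenarioConfig,
    alt_config: ScenarioConfig,
    perturbations: list[ParameterPerturbation],
) -> list[TornadoEntry]:
    """Run the one-way analysis; entries sorted by swing, descending."""
    def net(b: ScenarioConfig, a: ScenarioConfig) -> float:
        return (
            run_scenario(b, validate=False).cost_per_patient
            - run_scenario(a, validate=False).cost_per_patient
        )

    # validate once up front; perturbed reruns skip revalidation
    base_net = (
        run_scenario(base_config).cost_per_patient
        - run_scenario(alt_config).cost_per_patient
    )
    entries = []
    for pert in perturbations:
        impacts = {}
        for tag, value in (("low", pert.low_value), ("high", pert.high_value)):
            b, a = set_parameter(base_config, alt_config, pert.parameter_path, value)
            impacts[tag] = net(b, a)
        entries.append(
            TornadoEntry(
                parameter_path=pert.parameter_path,
                base_net_impact=base_net,
                net_impact_at_low=impacts["low"],
                net_impact_at_high=impacts["high"],
            )
        )
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def default_perturbation_set(
    base_config: ScenarioConfig,
    alt_config: ScenarioConfig | None = None,
) -> list[ParameterPerturbation]:
    """The shipped roster: +/-20% on every cost and clinical parameter and on
    the prevalences (probabilities clamped to [0, 1]), and +/-0.05 on each
    scenario's three AUROCs clamped inside (0.5, 0.99). Accuracy
    perturbations for the alternative scenario are included when
    ``alt_config`` is given."""
    perts: list[ParameterPerturbation] = []
    for fname in (f.name for f in fields(CostParams)):
        base_val = getattr(base_config.costs, fname)
        if base_val == 0.0:
            continue  # nothing to vary (e.g. an uncosted test)
        perts.append(
            ParameterPerturbation(f"costs.{fname}", 0.8 * base_val, 1.2 * base_val)
        )
    for fname in (f.name for f in fields(ClinicalParams)):
        base_val = getattr(base_config.clinical, fname)
        lo, hi = 0.8 * base_val, 1.2 * base_val
        if fname.startswith("mortality"):
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        perts.append(ParameterPerturbation(f"clinical.{fname}", lo, hi))
    epi = base_config.epidemiology
    for fname in _INFECTION_STATES + ("p_mortality_risk",):
        base_val = getattr(epi, fname)
        perts.append(
            ParameterPerturbation(
                f"epidemiology.{fname}",
                max(0.8 * base_val, 0.0),
                min(1.2 * base_val, 1.0),
            )
        )
    targets = [("base", base_config)]
    if alt_config is not None:
        targets.append(("alt", alt_config))
    for scen, cfg in targets:
        for readout in ("bacterial", "viral", "mortality"):
            auroc = cfg.readout_specs[readout].auroc
            perts.append(
                ParameterPerturbation(
                    f"{scen}.readouts.{readout}.auroc",
                    max(AUROC_BOUNDS[0], auroc - AUROC_RANGE_HALF_WIDTH),
                    min(AUROC_BOUNDS[1], auroc + AUROC_RANGE_HALF_WIDTH),
                    range_source="literature_range",
                )
            )
    return perts


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    """CSV-ready tornado data: one row per parameter, sorted by swing."""
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter_path,
                "base_net_impact": e.base_net_impact,
                "net_impact_low": e.net_impact_at_low,
                "net_impact_high": e.net_impact_at_high,
                "swing": e.swing,
            }
            for e in entries
        ]
    )
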