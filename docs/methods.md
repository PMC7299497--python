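# Methods

## The model

`triage-cim` is a deterministic decision-analytic cost-impact model of
band-reported host-response testing for emergency-department (ED) patients
with suspected acute respiratory tract infection (ARTI), evaluated from a
US-payer perspective over a single episode of care. A test reports three
readouts — likelihood of bacterial infection, likelihood of viral
infection, and 30-day mortality risk — each as a discrete band (bacterial
and mortality: low/moderate/high; viral: low/high, because the only viral
action is test-and-treat). The model asks how much money and utilization a
more accurate test saves, holding the clinical decision rules fixed.

The pipeline has four stages.

### 1. ROC banding

Each readout is an ideal equal-variance binormal ROC curve: scores of
condition-negative patients are N(0, 1), positives are N(d′, 1), with
d′ = √2·Φ⁻¹(AUROC). The score axis is cut where the **band likelihood
ratio** LR(band) = P(band | positive) / P(band | negative) reaches preset
targets: 0.1 for the rule-out (low) band and 10 for the rule-in (high)
band. For the low band this equals the classical negative likelihood ratio
(1 − sens)/spec at the cutoff, and for the high band the positive
likelihood ratio sens/(1 − spec). Cutoffs are found by bracketed Brent
root-finding (the band-LR functions are monotone in the cutoff), to
1e−12 on the cutoff and better than 1e−9 on the achieved LR.

Because the LR targets are fixed while d′ grows, a higher AUROC moves
population mass out of the noninformative moderate band into the
actionable bands. That reallocation is the entire mechanism of the model.

Two conventions exist for "likelihood ratio at a cutoff". The band-LR
convention above is the default; a point (density-ratio) convention,
c = ln(LR)/d′ + d′/2 in closed form, is available via
`solve_band_cutoffs(..., convention="point")` for exploration. The
band-LR low cutoffs imply a rule-out sensitivity above 97% at the modeled
AUROCs; published descriptions of similar banding quote 93–95%, a range
not exactly attainable under either self-consistent convention, so the
solved operating characteristics are exposed as a diagnostic report
(`BandProfile.diagnostic_report`) and not calibrated to.

### 2. Decision rules (the ledger)

The 3×2×3 = 18 prediction combinations map to clinical actions, and the
18×8 = 144 (prediction, ground-truth) cells map to outcome records,
through an editable rule system — the *ledger*. The complete cell-by-cell
assignment behind the published version of this model was never made
public, so the shipped default ledger is a reconstruction from the
printed parameter tables, the in-text worked example, and the aggregate
results; every rule carries a provenance note, and the action map
round-trips through a strict 18-row CSV so a user holding a complete
listing can transcribe it exactly.

Default action map:

* **Disposition** follows the mortality band: high → ICU, moderate →
  ward, low → discharge home (ED observation instead when the bacterial
  band is high). One refinement: an ICU bed requires corroborating
  infection signal (bacterial band ≥ moderate or viral band high); an
  isolated high severity score admits to the ward for monitoring.
  Without this gate, improving the mortality readout floods the ICU with
  false-positive admissions on a scale the published utilization tables
  rule out.
* **Antibiotics** are empiric by care setting (ICU: 6.86-day IV course,
  ward: 5.02-day oral/IV course, observation: 3.18-day oral course,
  discharge: none). The published by-stratum antibiotic-day totals show
  ~4.6 days/patient even in bacterial-negative strata, i.e. antibiotics
  track disposition, not the bacterial band.
* **Viral band high** triggers confirmatory PCR plus oseltamivir.
  **Blood culture** accompanies admission when the bacterial band is not
  low.

Default outcome rules (ordered, first match wins; validated exhaustively
over all 144 cells, with unreachable-rule detection):

1. **Missed severe** — truly high-mortality patient not admitted:
   readmission, costed by the all-in missed-diagnosis composites
   ($51 680.76 with bacterial infection, $37 730.51 without); the
   rehospitalization stay is 8.30 ICU days for survivors and 19.90 days
   for nonsurvivors; the timely-admission mortality benefit is forfeited.
2. **Missed bacterial** — bacterial infection discharged without
   antibiotics (non-severe): readmission with +1 hospital day, a
   3.18-day oral course, and the $2 869.88 composite (the composite is
   all-in; the extra day is counted in utilization but not double-billed).
3. **Standard care** — care as actioned. Setting-specific LOS (ICU 4.85
   days; ward 1.77 days) with one exception: a ward stay extends to 8.30
   days when the patient is truly severe (deterioration, with escalation
   to an ICU-grade antibiotic course) or was admitted on a high mortality
   band (care follows the score). Without this extension, ward-day totals
   undershoot the published utilization by ~30% — 1.77 days × admissions
   cannot reproduce the printed 2 188 ward days per 1 000 patients.

### 3. Mortality

Every patient in the cohort carries a baseline 30-day mortality: these
are ED patients sick enough to be worked up for sepsis, and the
parameter table's 10.0% "ARTI patients" mortality is read as that
all-comers baseline. Modifiers: viral-only non-severe patients treated
with oseltamivir carry the viral-specific 6.7%; truly severe
(high-mortality-risk) patients carry the septic-ICU 23%, multiplied by
(1 − 0.30) when the action admits them to the ICU in time. This is the
one place the reconstruction knowingly departs from the published
accounting, because that accounting is internally impossible: it books
123 deaths per 1 000 patients against at most ~110 patients in the
at-risk stratum, and a −1.67-point mortality difference cannot arise
from a 30% relative reduction applied to a 10%-prevalence stratum under
any per-patient probability model (it would require a baseline mortality
of ≈ 1.4). The model here keeps every probability in [0, 1] and accepts
the resulting smaller mortality contrast (11.0% → 10.2% at the default
parameters, as computed by the test suite).

### 4. Cohort engine, comparison, DSA

Cell occupancy is exact expectation, no sampling:
`cohort × P(truth) × Π_readouts P(band | truth bit)`, with the three
readouts conditionally independent given truth and mortality risk
independent of infection state (an explicit 8-vector joint can be
configured instead). Costs price each cell's event list against the unit
cost catalog; aggregates and an 8-row by-truth table follow by
summation. Scenario comparison reports differences (alternative minus
base) and percent changes on the unrounded values.

One-way deterministic sensitivity analysis perturbs a single parameter
at a time — ±20% for costs and clinical parameters (probabilities
clamped to [0, 1]; perturbing one infection-state prevalence rescales
the other three to keep the simplex), ±0.05 for AUROCs clamped inside
(0.5, 0.99), the ranges being documented assumptions since the published
accuracy/prevalence ranges were not printed. Costs, clinical parameters
and prevalences move in both scenarios; accuracies target one named
scenario. Entries are ranked by swing, max |net impact − base net
impact|. At the defaults the most influential parameter is the ward cost
per day (swing ≈ $425 per patient); net savings stay positive across the
entire default roster.

## Monte Carlo oracle and synthetic data

`simulate_cohort` brute-forces the same model by sampling: truth from
the joint prevalence distribution, one score per readout from the
truth-matched binormal component, banding with the solved cutoffs, the
identical ledger and cost catalog, and a Bernoulli death draw (which
also selects survivor/nonsurvivor stay lengths in missed-severe cells).
One root seed spawns per-variable child streams, so growing `n` extends
the cohort without reshuffling earlier patients. Agreement of the
sampled aggregates with the closed-form expectations — checked over 20
Latin-hypercube parameter sets at n = 10⁵ with a multiplicity-corrected
3-standard-error criterion — validates the expectation algebra end to
end. `generate_parameter_sets` provides those Latin-hypercube scenario
configurations, renormalized and validated.

What the synthetic machinery emulates: the model's own statistical
assumptions (stated prevalences, binormal scores at stated AUROCs,
conditional independence across readouts given truth). What it does not:
correlation between readouts, the marketed assay's actual four-band
score distribution, physician non-adherence, non-respiratory infections.
Passing tests therefore demonstrate internal consistency of the model,
not fidelity to real patients.

## Numerical choices

* Cutoff solver: geometric bracket expansion from [−1, 1] capped at
  |c| = 20 — weak but valid readouts (AUROC ≈ 0.55) place the rule-out
  cutoff near −12.8, and beyond the cap the LR target is genuinely
  unattainable, reported as an explicit error rather than an infinite
  cutoff. AUROC = 0.5 exactly is rejected at construction.
* Band tail masses use `norm.sf` directly; CDF differences underflow
  beyond ~8σ and would corrupt the achieved LRs of extreme bands.
* Money is carried as floats and rounded to cents (or whole dollars for
  aggregate reports) only at report time; every printed figure is exact
  at that precision.
* Rule matching is first-match-wins over an ordered list; the shipped
  rules are mutually exclusive by construction and the validator flags
  shadowed (unreachable) rules.
* Degenerate inputs: a zero-patient cohort yields zero totals and valid
  (empty-mass) reports; infeasible band targets (overlapping cutoffs)
  raise a named error identifying the readout.

## Known limitations

* The default ledger is a calibrated reconstruction, not a transcript.
  Six of the nine published headline aggregates reproduce within ±10%
  (hospital-day and antibiotic-day levels and differences, base-scenario
  cost); the published per-patient savings (≈ $1 974) does not — the
  model here yields ≈ $535 — because a large share of the published
  savings flows through the mortality contrast discussed above and
  through unpublished outcome assignments. All effect directions
  reproduce, including the counterintuitive ICU-day increase under the
  better test.
* Raising the *viral* AUROC slightly increases expected cost: the only
  viral action is test-and-treat, whose mortality benefit is uncosted in
  a payer-perspective episode model. Cost dominance with accuracy holds
  for the bacterial and mortality readouts.
* Correct ICU care is costlier than cheap under-treatment in some severe
  cells, so "the concordant prediction is always cheapest" holds only
  against under-treatment cells that trigger missed-care penalties, and
  for fully healthy patients; for severe patients the better test
  *spends more* to save lives, which is the published pattern as well.
* No discounting, multi-year horizon, QALYs, probabilistic sensitivity
  analysis, or physician-adherence modeling — the model is a one-episode
  payer cost impact.
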