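# triage-cim

Deterministic cost-impact model of band-reported host-response
diagnostics for emergency-department patients with suspected acute
respiratory tract infection (ARTI), from a US-payer perspective.

Multi-readout host-response tests report the likelihood of bacterial
infection, the likelihood of viral infection, and 30-day mortality risk,
each as a discrete band (low / moderate / high) that triggers a defined
clinical action — discharge, ED observation, ward or ICU admission,
antibiotics, viral PCR + oseltamivir, blood culture. `triage-cim` is for
health-economics and diagnostics researchers who want to quantify, and
stress-test, what a more accurate test is worth in that setting.

## The model

Each readout is an ideal equal-variance binormal ROC curve with
separation d′ = √2·Φ⁻¹(AUROC): negatives score N(0, 1), positives
N(d′, 1). The score axis is cut where the band likelihood ratio

    LR(band) = P(band | positive) / P(band | negative)

hits preset rule-out / rule-in targets (low band LR 0.1, high band
LR 10) — equivalently, the classical LR− and LR+ of the two cutoffs. At
fixed targets, a higher AUROC moves patients from the noninformative
moderate band into the actionable bands.

The 3×2×3 = 18 band combinations map to clinical actions, and their
cross with the 2×2×2 = 8 ground-truth states gives 144 decision cells,
each assigned an outcome (ward/ICU days, antibiotic days, death
probability, readmission penalties) by an editable first-match rule
ledger. Cell occupancy is exact expectation — cohort × P(truth) ×
Π P(band | truth) with readouts conditionally independent given truth —
and costs price each cell's events against a unit-cost catalog. Two
scenarios differing only in AUROCs (standard of care with procalcitonin:
0.80/0.80/0.78; host-response assay: 0.85/0.90/0.88) are compared on
cost, hospital days, antibiotic days and 30-day mortality, with one-way
deterministic sensitivity analysis (tornado) on every parameter and a
patient-level Monte Carlo microsimulation as an independent oracle.

See `docs/methods.md` for assumptions, parameter provenance, and known
limitations (the shipped 144-cell ledger is a documented reconstruction).

## Worked example

```python
import triage_cim as tc

base = tc.base_case_config()     # procalcitonin standard of care
host = tc.hostdx_config()        # host-response assay scenario

comp = tc.compare_scenarios(tc.run_scenario(base), tc.run_scenario(host))
print(comp.table[["quantity", "base_case", "hostdx", "difference"]]
      .round(2).to_string(index=False))
print("savings per patient:", round(comp.per_patient_savings, 2))
```

prints

```
        quantity  base_case     hostdx  difference
   hospital_days       2.15       1.30       -0.84
        icu_days       0.11       0.43        0.32
 antibiotic_days       5.23       3.78       -1.45
   mortality_30d      10.97      10.19       -0.78
cost_per_patient    6166.20    5631.58     -534.62
      total_cost 6166202.94 5631582.41  -534620.53
savings per patient: 534.62
```

Per 1000 simulated patients, the more accurate test saves about $535
per patient: it discharges more well patients (0.84 fewer hospital days
each on average), stops more unnecessary antibiotics (1.45 fewer days),
and admits truly severe patients to the ICU earlier — which *raises*
ICU days while lowering 30-day mortality by 0.78 percentage points. If
the assay were priced at the lab-fee reimbursement rate
(`tc.cms_reimbursement()` → 525.81), the remainder is the payer's net
saving (`tc.net_savings_after_reimbursement`).

The same pipeline is scriptable from the shell:

```sh
triage-cim compare --out-dir reports         # Table-style CSV reports
triage-cim dsa --out-dir reports             # tornado CSV
triage-cim simulate --n 100000 --seed 1      # Monte Carlo oracle
triage-cim validate-ledger                   # 144-cell coverage check
```

Scenario parameters live in strict YAML configs (see
`src/triage_cim/data/base_case.yaml`); the action map is editable as a
CSV via `triage-cim export-action-map`.

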