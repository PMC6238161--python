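# apprisk

Parkinsonism-risk scoring for **antipsychotic polypharmacy** (APP): when a
patient is prescribed two antipsychotics concurrently, which combinations and
doses carry the highest risk of drug-induced parkinsonism (an extrapyramidal
side-effect, EPS)?  Chlorpromazine-equivalent dose tables work reasonably for
single drugs, but two antipsychotics interact non-linearly at shared receptor
systems, so summed dose equivalents can mis-rank combinations.

`apprisk` implements and compares four classifiers of EPS liability for
two-drug regimens, for pharmacoepidemiologists and computational
pharmacologists working with prescribing records:

1. **Mechanistic circuit readout** (`qsp_readout`) — competitive receptor
   binding of both drugs plus endogenous dopamine at D₂R and 5-HT₂AR feeds a
   rectified-linear firing-rate model of the cortico-striatal direct/indirect
   pathways; the liability score is the relative elevation of steady-state
   subthalamic-nucleus (STN) activity over the drug-free fixed point
   (STN hyperactivity is the circuit correlate of bradykinesia/rigidity).
2. **Summed D₂R occupancy** (`d2r_sum`) — occ₁ + occ₂ at D₂R under
   competition, with occᵢ = (Cᵢ/Kᵢ)/(1 + ΣⱼCⱼ/Kⱼ).
3. **Summed inverse affinity** (`inv_k_sum`) — 1/K₁ + 1/K₂, dose independent.
4. **Chlorpromazine equivalents** (`cpz_sum`) — dose₁·f₁ + dose₂·f₂ in
   mg/day chlorpromazine.

Doses map linearly to free brain concentration, with each drug's slope
calibrated against a published PET D₂-occupancy anchor (recorded in the
bundled, user-replaceable drug table `src/apprisk/data/drug_table.csv`).

Because real clinical records cannot be redistributed, the package includes a
**synthetic EHR cohort generator** that reproduces the structure of a
published 832-patient two-antipsychotic schizophrenia cohort exactly
(demographic marginals, most frequent drug combinations, 59 combination
types, 24 outcome-positive records ≈ 2.9% prevalence), with outcomes
optionally linked to any predictor, and an **evaluation module** computing
AUROC per classifier with Hanley–McNeil (or DeLong) standard errors, 95% CIs
and a two-sided test against chance (AUC = 0.5).

## Worked example

Score two regimens with comparable chlorpromazine-equivalent exposure:

```python
from apprisk import default_drug_table, default_circuit_params, Regimen
from apprisk.pipeline import score_regimen

table = default_drug_table()
params = default_circuit_params()

typical = Regimen(table["haloperidol"], 4.0, table["sulpiride"], 400.0)
atypical = Regimen(table["quetiapine"], 400.0, table["olanzapine"], 10.0)
for label, reg in [("haloperidol 4 mg + sulpiride 400 mg", typical),
                   ("quetiapine 400 mg + olanzapine 10 mg", atypical)]:
    s = score_regimen(reg, params)
    print(f"{label}:")
    for k, v in s.items():
        print(f"  {k:12s} {v:8.3f}")
```

prints

```
haloperidol 4 mg + sulpiride 400 mg:
  qsp_readout     0.157
  d2r_sum         0.838
  inv_k_sum       0.944
  cpz_sum       540.000
quetiapine 400 mg + olanzapine 10 mg:
  qsp_readout    -0.164
  d2r_sum         0.764
  inv_k_sum       0.056
  cpz_sum       620.000
```

The typical high-potency pair drives STN activity 15.7% above the drug-free
baseline (elevated parkinsonism liability), while the atypical pair — despite
a *higher* chlorpromazine-equivalent total (620 vs 540 mg/day) — scores below
baseline, because its strong 5-HT₂A antagonism damps the indirect pathway.
Dose-equivalence and the circuit readout rank these two regimens in opposite
order; that receptor-level interaction is exactly what summed equivalents
cannot see.

## Command-line pipeline

```bash
apprisk simulate --config run.yaml --seed 1 --out run/   # synthetic cohort CSV
apprisk score    --cohort run/cohort.csv --out run/cohort_scored.csv
apprisk evaluate --cohort run/cohort_scored.csv --out run/
apprisk all      --seed 1 --out run/                     # all three stages
```

`evaluate` writes `roc_comparison.csv` (one row per classifier: AUC, SE, 95%
CI, p versus chance, case/control counts) plus per-classifier ROC-point files
for plotting.  Every stage is deterministic given the config and seed, and
each output carries a provenance sidecar (seed, config hash).  A real cohort
file with the same column schema can replace the synthetic one at the
`score` stage unchanged.

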