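# Methods

## Receptor competition and dose calibration

All four classifiers start from equilibrium competitive binding.  For ligands
with free concentrations `C_i` and affinity constants `K_i` (nM) competing at
one receptor, writing `r_i = C_i/K_i`, the bound fraction of ligand `i` is
`r_i / (1 + Σ_j r_j)` and the free-receptor fraction is `1 / (1 + Σ_j r_j)`.
This is the closed-form steady state of mass-action association/dissociation
kinetics with ligand in excess; the test suite verifies the identity against
direct numerical integration of the kinetic ODEs to 1e-6.

Endogenous dopamine competes at D₂R as a dimensionless **tone**
`r_DA = C_DA/K_DA`.  The mechanistic readout uses tone 1.0 by default (half
of D₂ receptors dopamine-bound in the drug-free state — a conventional
normalization, configurable in `RunConfig`).  The simple summed-occupancy
comparator (`d2r_sum`) is computed with tone 0 by default, i.e. as a pure
two-drug competition, since that score is conventionally reported without an
endogenous term; both tones are exposed as configuration flags.

**Dose → concentration** is linear: `C = conc_per_dose × dose`.  The slope is
back-calculated per drug from one PET occupancy anchor (a reference daily
dose and the striatal D₂ occupancy reported at that dose), inverting the
single-ligand occupancy formula at tone 0 — matching how PET occupancy is
reported, as fractional displacement of baseline radioligand binding:
`conc_per_dose = K_i · occ/(1−occ) / dose_ref`.  Linearity is the minimal
model consistent with single-point calibration; it ignores saturating plasma
kinetics, protein binding and active metabolites, and is transparent to
recalibrate by editing the table.

**Drug table.**  `src/apprisk/data/drug_table.csv` ships 16 antipsychotics
with literature-sourced parameters: D₂ and 5-HT₂A inhibition constants
(receptor-screening-program ranges), intrinsic activity at D₂ (0 for neutral
antagonists; 0.25 for the partial agonist aripiprazole), chlorpromazine-
equivalence factors (international consensus values), licensed maximum daily
doses, tablet steps, and the PET anchors.  Each row's `source` column names
its provenance.  The table is data, not code: replace it to change the
pharmacology.  Loading validates every invariant (positive affinities,
intrinsic activity in [0, 1], unique names) and that `conc_per_dose` is
consistent with the stored anchor.  A drug without measured 5-HT₂A affinity
is treated as non-binding there (warning), not as an error.

## Circuit model

The mechanistic readout is an explicitly simplified, fully specified
rectified-linear firing-rate network — a stand-in of the same mechanism class
as proprietary whole-circuit platforms, not a reimplementation of one.  Six
populations (SMA cortex, D₁⁺ MSN, D₂⁺ MSN, GPe, STN, GPi) are wired with the
canonical direct/indirect anatomy: cortex excites both MSN populations;
D₁⁺ MSNs inhibit GPi (direct); D₂⁺ MSNs inhibit GPe, GPe inhibits STN, and
STN excites GPi (indirect).  Each population relaxes as
`τ·dr/dt = −r + ramp(baseline + Σ w·r_pre + modulation)`.

Two modulations carry the pharmacology:

* the **net drive to D₂⁺ MSNs** is scaled by
  `1 + gain_d2·(baseline_d2_activation − A)` where
  `A = (r_DA + r_a·ε_a + r_b·ε_b)/(1 + r_DA + r_a + r_b)` is
  occupancy-weighted D₂ activation (dopamine a full agonist, each drug its
  intrinsic activity ε).  D₂ receptors are inhibitory on these cells, so
  blockade (lower A) disinhibits them, dampening GPe and releasing STN.  The
  scale factor is clamped at zero so a hypothetical supra-baseline agonist
  cannot produce negative drive; within reachable regimens the clamp is
  inactive.
* the **net STN drive** is scaled by `1 − gain_5ht2a·occ_5HT2A`, a lumped
  serotonergic brake: 5-HT₂A antagonism (the defining atypical property)
  reduces excitatory drive in the subthalamic limb.

**Liability score** = `(STN_drug − STN_baseline)/STN_baseline`, the relative
STN elevation over the drug-free fixed point at the same dopamine tone.  It
is an **ordinal risk index** — the calibration from STN activity to outcome
probability is not recoverable here — which is sufficient for rank-based
(AUROC) evaluation.  A zero-dose regimen scores exactly 0; the score
increases along dose grids of neutral D₂ antagonists, decreases with
intrinsic activity at fixed occupancy, and decreases with 5-HT₂A occupancy
(all covered by tests).  It can be negative when serotonergic damping
outweighs D₂ disinhibition.

**Parameters** (versioned in `data/circuit_params.yaml`): unit baseline
rates for cortex/GPe/STN/GPi, 0.2 for both MSN populations, |w| = 0.5 on all
edges, `gain_d2 = 2.0`, `gain_5ht2a = 0.3`, `baseline_d2_activation = 0.5`
(the drug-free activation at tone 1), τ = 1 for all populations.  They were
chosen so the drug-free fixed point is interior (every population active,
STN = 0.675) and drug effects stay in the rectifier's linear region over the
licensed dose range; only directionality and monotonicity, not the scale,
carry meaning.

**Numerics.**  The network is feedforward, so the fixed point is unique and
available in closed form; the integrator (forward Euler, step 0.1·min τ,
at most 10⁵ steps) is still exercised because the contraction argument is
what generalizes to recurrent variants.  Convergence is declared on the
fixed-point residual `max_p |ramp(drive_p) − r_p| < 1e-10`, a step-size
independent criterion; non-convergence is returned flagged and the readout
refuses to use a flagged state.  Tests check re-substitution residuals and
agreement with the algebraic solution to 1e-8.  A population driven to zero
stays rectified at zero.

## Synthetic cohort generator

The generator emulates the *structure* of a published 832-patient cohort of
people with schizophrenia prescribed two concurrent oral antipsychotics, so
that classifier-evaluation experiments have realistic marginals:

* **Demographics** — exact category counts per axis (age bands 16–25: 207,
  26–35: 223, 36–45: 224, 46–55: 106, 56–65: 47, 66+: 25; gender 320/512;
  six ethnicity categories), allocated exactly and shuffled over records.
  Axes are independent: no joint demographic distribution is published, and
  none is invented.
* **Combinations** — the five most frequent pairs with their published
  counts (aripiprazole+olanzapine 118, olanzapine+risperidone 92,
  amisulpride+clozapine 86, amisulpride+sulpiride 57, aripiprazole+clozapine
  53) plus seeded filler pairs drawn from the drug table to reach 59
  distinct combination types, each filler getting at least one record.  The
  source table prints "Other 430", but its counts then total 836 against a
  cohort of 832 (its percentages are computed on 836) — an internal
  inconsistency of the source; the generator keeps the named counts exact
  and sizes the residual pool at 832 − 406 = 426 so the catalogue partitions
  the cohort.
* **Doses** — uniform in a configurable fraction (default 25–75%) of each
  drug's licensed maximum, rounded to the drug's tablet step; regimens never
  exceed the licensed maximum, mirroring the source cohort's exclusion rule.
* **Outcome** — recorded parkinsonism as a single boolean (24 positives,
  2.9%).  `exact_count` mode flags exactly that many records, sampled
  without replacement with weights `exp(δ·z)` on the standardized linked
  predictor (uniform at δ = 0); `bernoulli_link` mode draws independent
  flags `expit(α + δ·z)` with α solved by root-finding so expected
  prevalence hits the target.  The default link is δ = 0.58 on the circuit
  readout — the separation at which a binormal predictor attains a
  population AUROC of Φ(0.58/√2) ≈ 0.66.

`binormal_predictor_sim` is the matching link-level simulator (controls
N(0,1), cases N(δ,1)) used for desk-scale discrimination experiments where
the full pipeline is unnecessary.

**What passing tests do and do not show.**  The generator reproduces
published marginal structure; it does not emulate free-text extraction
error, time-at-risk/censoring, dose–combination correlation, or joint
demographic–prescription structure.  Classifier performance measured on
linked synthetic cohorts validates the *pipeline and estimators*, not
clinical discrimination on real records.

## Evaluation

AUROC is the Mann–Whitney estimator with midrank ties, computed via the
rank-sum identity; it equals exhaustive pair counting (tested on all small
instances) and the trapezoidal area under the tie-aware ROC curve.  Midranks
matter here: the inverse-affinity and chlorpromazine scores take few distinct
values across 59 combination types.  The standard error is Hanley–McNeil by
default — transparent, and adequate at these sample sizes — with a DeLong
structural-components variance available (`se_method: delong`); both are
checked against a stratified bootstrap in tests.  The 95% CI is Wald,
truncated to [0, 1]; an AUC of exactly 0 or 1 yields a flagged degenerate
interval.  The test against chance is a two-sided normal test of
AUC = 0.5.  No multiple-testing adjustment is applied across the four
classifiers, matching how such comparisons are conventionally reported.  No
paired between-classifier test is provided (out of scope).

## Pipeline and reproducibility

`simulate → score → evaluate` (or `all`) with a YAML config; subcommands are
separable so real cohort files with the same schema can replace synthetic
ones at the scoring stage.  Identical config + seed gives byte-identical
outputs; every output directory carries seed and config hash.  Scoring
caches by unique (drug, dose, drug, dose) regimen, so an 832-record cohort
with ~600 unique dose combinations scores in a few seconds.

**Problem sizes.**  The bundled experiments run at the published cohort
scale (832 records) and use 200 replicates for the link-level AUROC
experiment (replicate-mean standard error ≈ 0.004) and 2000 bootstrap
resamples for SE cross-checks; the kinetic-ODE oracle uses 50 random
instances at tolerance 1e-6.

## Known limitations

* The circuit is a six-population rate model with two lumped drug
  modulations; it omits spiking dynamics, LFP spectra, other receptor
  systems (muscarinic, histaminergic, 5-HT₁A …), genotype effects and
  co-medication.
* Dose→concentration linearity with a single PET anchor per drug ignores
  nonlinear pharmacokinetics and drug–drug PK interactions.
* The liability score is ordinal; absolute values are not calibrated to
  outcome probabilities.
* Synthetic outcomes are generated by the stated link models; AUROC values
  on synthetic cohorts reflect those links, not clinical reality.
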