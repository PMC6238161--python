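"""Synthetic EHR cohort generation for two-drug antipsychotic regimens.

Real secondary-care prescribing records cannot be redistributed, so this
module generates cohorts that reproduce the published structure of a
two-antipsychotic schizophrenia cohort exactly: the demographic marginals
(age band, gender, ethnicity), the most frequent drug combinations with an
"Other" pool spread over filler combinations, dose ranges bounded by the
licensed (BNF) maxima, and a fixed outcome prevalence.  Category counts are
allocated exactly and then shuffled over records, so every marginal matches
its configured count for any seed; only dose draws and the filler-pair
composition vary between seeds.

Demographic axes are sampled independently of each other and of the
prescription — no joint distribution is published to emulate.

Outcome (recorded parkinsonism) assignment supports two modes:

* ``exact_count`` — exactly ``prevalence_count`` records are flagged, drawn
  without replacement with weights ``exp(δ·z)`` on the standardized linked
  predictor (uniform when δ = 0);
* ``bernoulli_link`` — independent flags with probability
  ``expit(α + δ·z)``, the intercept α solved so the expected prevalence
  matches the target.

``binormal_predictor_sim`` is the matching link-level simulator: control
scores are standard normal and case scores are shifted by δ standard
deviations, so the population AUROC is Φ(δ/√2).
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .pharmacology import DrugTable, Regimen

__all__ = [
    "PUBLISHED_AGE_COUNTS",
    "PUBLISHED_GENDER_COUNTS",
    "PUBLISHED_ETHNICITY_COUNTS",
    "TOP5_COMBINATIONS",
    "CohortConfig",
    "PatientRecord",
    "generate_cohort",
    "assign_outcomes",
    "binormal_predictor_sim",
    "build_combination_catalogue",
    "cohort_to_dataframe",
    "dataframe_to_cohort",
    "write_cohort",
    "read_cohort",
]

# Published cohort structure (N = 832): demographic marginals, the five most
# frequent antipsychotic combinations, the size of the residual combination
# pool, the number of distinct combination types, and the outcome count.
PUBLISHED_AGE_COUNTS = {
    "16-25": 207,
    "26-35": 223,
    "36-45": 224,
    "46-55": 106,
    "56-65": 47,
    "66+": 25,
}
PUBLISHED_GENDER_COUNTS = {"Female": 320, "Male": 512}
PUBLISHED_ETHNICITY_COUNTS = {
    "British": 274,
    "Other White": 62,
    "Asian": 56,
    "Black Caribbean": 92,
    "Black African": 268,
    "Other": 80,
}
TOP5_COMBINATIONS = [
    ("aripiprazole", "olanzapine", 118),
    ("olanzapine", "risperidone", 92),
    ("amisulpride", "clozapine", 86),
    ("amisulpride", "sulpiride", 57),
    ("aripiprazole", "clozapine", 53),
]
# The published combination table prints "Other 430", but its counts then sum
# to 836 against a cohort of 832 (its percentages are computed on 836).  The
# named counts are kept exact and the residual pool absorbs the remainder so
# the catalogue partitions the cohort.
OTHER_POOL_COUNT = 832 - sum(c for _, _, c in TOP5_COMBINATIONS)  # = 426
N_COMBINATION_TYPES = 59
PREVALENCE_COUNT = 24


class CohortConfigError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults reproduce the published cohort."""

    n_patients: int = 832
    age_band_counts: dict[str, int] = field(default_factory=lambda: dict(PUBLISHED_AGE_COUNTS))
    gender_counts: dict[str, int] = field(default_factory=lambda: dict(PUBLISHED_GENDER_COUNTS))
    ethnicity_counts: dict[str, int] = field(
        default_factory=lambda: dict(PUBLISHED_ETHNICITY_COUNTS)
    )
    named_combinations: list[tuple[str, str, int]] = field(
        default_factory=lambda: list(TOP5_COMBINATIONS)
    )
    other_pool_count: int = OTHER_POOL_COUNT
    n_combination_types: int = N_COMBINATION_TYPES
    #: doses drawn uniformly in [min, max] × bnf_max_dose, then rounded to
    #: the drug's tablet step.
    dose_min_frac: float = 0.25
    dose_max_frac: float = 0.75
    prevalence_count: int = PREVALENCE_COUNT
    outcome_mode: str = "exact_count"  # or "bernoulli_link"
    link_predictor: str = "qsp_readout"
    link_delta: float = 0.58
    seed: int = 0

    def __post_init__(self) -> None:
        for axis, counts in (
            ("age_band_counts", self.age_band_counts),
            ("gender_counts", self.gender_counts),
            ("ethnicity_counts", self.ethnicity_counts),
        ):
            if any(c < 0 for c in counts.values()):
                raise CohortConfigError(f"{axis}: negative category count")
            if sum(counts.values()) != self.n_patients:
                raise CohortConfigError(
                    f"{axis} sums to {sum(counts.values())}, expected {self.n_patients}"
                )
        named_total = sum(c for _, _, c in self.named_combinations)
        if named_total + self.other_pool_count != self.n_patients:
            raise CohortConfigError(
                f"combination counts ({named_total} named + {self.other_pool_count} other) "
                f"do not sum to {self.n_patients}"
            )
        n_filler = self.n_combination_types - len(self.named_combinations)
        if n_filler < 0:
            raise CohortConfigError("n_combination_types smaller than the named list")
        if self.other_pool_count > 0 and n_filler == 0:
            raise CohortConfigError("other pool is non-empty but no filler combinations allowed")
        if self.other_pool_count < n_filler:
            raise CohortConfigError(
                f"other pool ({self.other_pool_count}) cannot populate {n_filler} filler types"
            )
        if not 0 <= self.prevalence_count <= self.n_patients:
            raise CohortConfigError("prevalence_count must lie in [0, n_patients]")
        if not 0 <= self.dose_min_frac <= self.dose_max_frac <= 1:
            raise CohortConfigError("dose fractions must satisfy 0 <= min <= max <= 1")
        if self.outcome_mode not in ("exact_count", "bernoulli_link"):
            raise CohortConfigError(f"unknown outcome_mode {self.outcome_mode!r}")
        if self.link_delta < 0:
            raise CohortConfigError("link_delta must be >= 0")

    def config_hash(self) -> str:
        payload = {
            k: (sorted(v.items()) if isinstance(v, dict) else v)
            for k, v in self.__dict__.items()
        }
        blob = json.dumps(payload, sort_keys=True, default=list).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PatientRecord:
    """One synthetic patient: demographics, regimen, outcome, scores."""

    id: str
    age_band: str
    gender: str
    ethnicity: str
    regimen: Regimen
    outcome: bool | None = None
    predictor_scores: dict[str, float] = field(default_factory=dict)


def build_combination_catalogue(
    config: CohortConfig, drug_table: DrugTable, rng: np.random.Generator
) -> list[tuple[str, str, int]]:
    """Named combinations plus seeded filler pairs absorbing the Other pool.

    Filler pairs are drawn without replacement from the unordered drug pairs
    of the table not already named; each receives at least one record and the
    remainder of the pool is spread multinomially.  The named counts and the
    pool total are preserved for every seed; filler composition varies.
    """
    for a, b, _ in config.named_combinations:
        for name in (a, b):
            if name not in drug_table:
                raise CohortConfigError(f"catalogue drug {name!r} not in drug table")
    named_keys = {frozenset((a, b)) for a, b, _ in config.named_combinations}
    candidates = [
        (a, b)
        for a, b in itertools.combinations(sorted(drug_table.names), 2)
        if frozenset((a, b)) not in named_keys
    ]
    n_filler = config.n_combination_types - len(config.named_combinations)
    if n_filler > len(candidates):
        raise CohortConfigError(
            f"need {n_filler} filler pairs but only {len(candidates)} distinct "
            "drug pairs are available in the table"
        )
    catalogue = list(config.named_combinations)
    if n_filler:
        chosen = [candidates[i] for i in rng.choice(len(candidates), size=n_filler, replace=False)]
        extra = rng.multinomial(config.other_pool_count - n_filler, [1.0 / n_filler] * n_filler)
        catalogue.extend((a, b, 1 + int(k)) for (a, b), k in zip(chosen, extra))
    return catalogue


def _sample_dose(drug, rng: np.random.Generator, lo_frac: float, hi_frac: float) -> float:
    """Uniform draw in the configured fraction of the licensed maximum,
    rounded to the drug's tablet step and clipped into (0, max]."""
    raw = rng.uniform(lo_frac, hi_frac) * drug.bnf_max_dose
    step = drug.dose_step_mg or drug.bnf_max_dose / 20.0
    dose = round(raw / step) * step
    return float(min(max(dose, step), drug.bnf_max_dose))


def generate_cohort(config: CohortConfig, drug_table: DrugTable) -> list[PatientRecord]:
    """Generate a cohort with exact configured marginals; seeded, reproducible.

    Every category count (each demographic axis, each named combination, the
    Other pool) is allocated exactly and the assignment to records is a
    seeded shuffle.  Doses are sampled per record.  Outcomes are left unset;
    see :func:`assign_outcomes`.
    """
    rng = np.random.default_rng([config.seed, 0xC0])
    catalogue = build_combination_catalogue(config, drug_table, rng)

    def shuffled(counts: dict[str, int]) -> list[str]:
        pool = [cat for cat, n in counts.items() for _ in range(n)]
        rng.shuffle(pool)
        return pool

    ages = shuffled(config.age_band_counts)
    genders = shuffled(config.gender_counts)
    ethnicities = shuffled(config.ethnicity_counts)
    combos = [(a, b) for a, b, n in catalogue for _ in range(n)]
    rng.shuffle(combos)

    width = max(4, len(str(config.n_patients)))
    records = []
    for i in range(config.n_patients):
        a, b = combos[i]
        drug_a, drug_b = drug_table[a], drug_table[b]
        regimen = Regimen(
            drug_a=drug_a,
            dose_a=_sample_dose(drug_a, rng, config.dose_min_frac, config.dose_max_frac),
            drug_b=drug_b,
            dose_b=_sample_dose(drug_b, rng, config.dose_min_frac, config.dose_max_frac),
        )
        records.append(
            PatientRecord(
                id=f"P{i + 1:0{width}d}",
                age_band=ages[i],
                gender=genders[i],
                ethnicity=ethnicities[i],
                regimen=regimen,
            )
        )
    return records


def _link_z(records: list[PatientRecord], predictor: str) -> np.ndarray:
    try:
        scores = np.array([r.predictor_scores[predictor] for r in records], dtype=float)
    except KeyError:
        raise ValueError(
            f"linked predictor {predictor!r} not scored on every record; "
            "score the cohort before assigning linked outcomes"
        ) from None
    sd = scores.std()
    return (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)


def assign_outcomes(
    records: list[PatientRecord], config: CohortConfig
) -> list[PatientRecord]:
    """Flag outcome-positive records in place (and return the list).

    ``exact_count``: exactly ``prevalence_count`` positives, sampled without
    replacement with weights ``exp(δ·z)`` on the standardized linked
    predictor (uniform when δ = 0).  ``bernoulli_link``: independent flags
    with probability ``expit(α + δ·z)``, α solved numerically so the
    expected prevalence equals ``prevalence_count / n_patients``.
    """
    n = len(records)
    if config.prevalence_count > n:
        raise CohortConfigError("prevalence_count exceeds cohort size")
    rng = np.random.default_rng([config.seed, 0x0D])
    delta = config.link_delta
    z = _link_z(records, config.link_predictor) if delta > 0 else np.zeros(n)

    if config.outcome_mode == "exact_count":
        flags = np.zeros(n, dtype=bool)
        if config.prevalence_count > 0:
            w = np.exp(delta * z)
            idx = rng.choice(n, size=config.prevalence_count, replace=False, p=w / w.sum())
            flags[idx] = True
    else:
        target = config.prevalence_count / n
        if delta == 0 or np.allclose(z, 0):
            p = np.full(n, target)
        else:
            alpha = brentq(lambda a: expit(a + delta * z).mean() - target, -50, 50)
            p = expit(alpha + delta * z)
        flags = rng.random(n) < p

    for rec, flag in zip(records, flags):
        rec.outcome = bool(flag)
    return records


def binormal_predictor_sim(
    n_cases: int, n_controls: int, delta: float, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Case/control score vectors under the binormal separation model.

    Controls ~ N(0, 1), cases ~ N(δ, 1).  Returns ``(scores, labels)`` with
    labels True for cases.  Population AUROC is Φ(δ/√2).
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    controls = rng.standard_normal(n_controls)
    cases = rng.standard_normal(n_cases) + delta
    scores = np.concatenate([controls, cases])
    labels = np.concatenate([np.zeros(n_controls, dtype=bool), np.ones(n_cases, dtype=bool)])
    return scores, labels


# ---------------------------------------------------------------------------
# Delimited-text I/O

_BASE_COLUMNS = [
    "id",
    "age_band",
    "gender",
    "ethnicity",
    "drug_a",
    "dose_a_mg",
    "drug_b",
    "dose_b_mg",
    "outcome",
]


def cohort_to_dataframe(records: list[PatientRecord]) -> pd.DataFrame:
    score_cols: list[str] = []
    for r in records:
        for k in r.predictor_scores:
            if k not in score_cols:
                score_cols.append(k)
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "age_band": r.age_band,
            "gender": r.gender,
            "ethnicity": r.ethnicity,
            "drug_a": r.regimen.drug_a.name,
            "dose_a_mg": r.regimen.dose_a,
            "drug_b": r.regimen.drug_b.name,
            "dose_b_mg": r.regimen.dose_b,
            "outcome": "" if r.outcome is None else int(r.outcome),
        }
        for c in score_cols:
            row[c] = r.predictor_scores.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=_BASE_COLUMNS + score_cols)


def dataframe_to_cohort(df: pd.DataFrame, drug_table: DrugTable) -> list[PatientRecord]:
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    unknown = sorted(
        {d for d in pd.concat([df["drug_a"], df["drug_b"]]).unique() if d not in drug_table}
    )
    if unknown:
        bad = df[df["drug_a"].isin(unknown) | df["drug_b"].isin(unknown)]["id"].tolist()
        raise ValueError(f"unknown drugs {unknown} in records {bad}")
    score_cols = [c for c in df.columns if c not in _BASE_COLUMNS]
    records = []
    for _, row in df.iterrows():
        outcome = row["outcome"]
        records.append(
            PatientRecord(
                id=str(row["id"]),
                age_band=str(row["age_band"]),
                gender=str(row["gender"]),
                ethnicity=str(row["ethnicity"]),
                regimen=Regimen(
                    drug_a=drug_table[row["drug_a"]],
                    dose_a=float(row["dose_a_mg"]),
                    drug_b=drug_table[row["drug_b"]],
                    dose_b=float(row["dose_b_mg"]),
                ),
                outcome=None if pd.isna(outcome) or outcome == "" else bool(int(outcome)),
                predictor_scores={
                    c: float(row[c]) for c in score_cols if not pd.isna(row[c])
                },
            )
        )
    return records


def write_cohort(
    path: str | Path, records: list[PatientRecord], config: CohortConfig | None = None
) -> None:
    """Write the cohort as comma-separated text plus a provenance sidecar."""
    path = Path(path)
    cohort_to_dataframe(records).to_csv(path, index=False, float_format="%.10g")
    sidecar = {"n_records": len(records), "generator": "apprisk-0.1.0"}
    if config is not None:
        sidecar.update(seed=config.seed, config_hash=config.config_hash())
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_cohort(path: str | Path, drug_table: DrugTable) -> list[PatientRecord]:
    return dataframe_to_cohort(pd.read_csv(path), drug_table)
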