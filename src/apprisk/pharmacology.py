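"""Drug parameters, dose→concentration mapping, competitive receptor occupancy,
and the three simple polypharmacy risk scores.

The central quantity is equilibrium fractional occupancy under multi-ligand
competition at a single receptor.  With free concentrations ``C_i`` and
affinity constants ``K_i`` (nM), write ``r_i = C_i / K_i``.  At equilibrium

    occ_i = r_i / (1 + Σ_j r_j)

where the sum runs over every competing ligand, including (at D₂R) endogenous
dopamine expressed as a dimensionless tone ``r_DA = C_DA / K_DA``.  The free
receptor fraction is ``1 / (1 + Σ_j r_j)``, so all fractions sum to one.

Dose is mapped to free brain concentration linearly, ``C = conc_per_dose ×
dose``, with ``conc_per_dose`` back-calculated per drug from a single PET
occupancy anchor (reference daily dose, reference D₂ occupancy) recorded in
the drug table.  Inverting the single-ligand occupancy formula at the anchor
gives ``conc_per_dose = K_i · occ / (1 − occ) / dose_ref``.

Three scalar risk scores for a two-drug regimen are provided:

* ``sum_d2_occupancy`` — occ_a + occ_b at D₂R from the competition model;
* ``inv_k_sum``        — 1/K₁ + 1/K₂, dose independent;
* ``cpz_equivalent_sum`` — summed chlorpromazine-equivalent daily dose.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "DrugRecord",
    "DrugTable",
    "Regimen",
    "OccupancySet",
    "DrugTableError",
    "load_drug_table",
    "default_drug_table",
    "concentration_from_dose",
    "competitive_occupancy",
    "sum_d2_occupancy",
    "inv_k_sum",
    "cpz_equivalent_sum",
]

#: Receptor labels understood by the competition model.
TARGETS = ("D2R", "5HT2AR")

_REQUIRED_COLUMNS = (
    "name",
    "ki_d2",
    "ki_5ht2a",
    "intrinsic_activity_d2",
    "cpz_eq_factor",
    "conc_per_dose",
    "bnf_max_dose",
)
_OPTIONAL_COLUMNS = ("ref_dose_mg", "ref_occupancy", "dose_step_mg", "source")


class DrugTableError(ValueError):
    """Raised when a drug table row violates a field invariant."""


@dataclass(frozen=True)
class DrugRecord:
    """Binding, equivalence and calibration parameters for one antipsychotic.

    Affinities are inhibition constants in nM; ``intrinsic_activity_d2`` is
    the fraction of full-agonist signalling elicited when bound (0 for a
    neutral antagonist, ~0.25 for the partial agonist aripiprazole);
    ``cpz_eq_factor`` converts mg/day of the drug to mg/day of
    chlorpromazine; ``conc_per_dose`` is effective free brain concentration
    per unit daily dose (nM per mg/day); ``bnf_max_dose`` is the maximum
    licensed daily dose (mg/day).
    """

    name: str
    ki_d2: float
    ki_5ht2a: float | None
    intrinsic_activity_d2: float
    cpz_eq_factor: float
    conc_per_dose: float
    bnf_max_dose: float
    ref_dose_mg: float | None = None
    ref_occupancy: float | None = None
    dose_step_mg: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.name or self.name != self.name.strip().lower():
            raise DrugTableError(f"drug name must be lowercase and non-empty: {self.name!r}")
        if not self.ki_d2 > 0:
            raise DrugTableError(f"{self.name}: ki_d2 must be > 0, got {self.ki_d2}")
        if self.ki_5ht2a is not None and not self.ki_5ht2a > 0:
            raise DrugTableError(f"{self.name}: ki_5ht2a must be > 0 or absent")
        if not 0.0 <= self.intrinsic_activity_d2 <= 1.0:
            raise DrugTableError(f"{self.name}: intrinsic_activity_d2 outside [0, 1]")
        for fname in ("cpz_eq_factor", "conc_per_dose", "bnf_max_dose"):
            if not getattr(self, fname) > 0:
                raise DrugTableError(f"{self.name}: {fname} must be > 0")

    def ki(self, target: str) -> float | None:
        """Affinity constant at ``target``; None when the drug has no
        measurable affinity there (only possible at 5-HT₂AR)."""
        if target == "D2R":
            return self.ki_d2
        if target == "5HT2AR":
            return self.ki_5ht2a
        raise ValueError(f"unknown receptor target {target!r}; expected one of {TARGETS}")


class DrugTable:
    """Collection of :class:`DrugRecord` with case-insensitive name lookup."""

    def __init__(self, records: Iterable[DrugRecord]):
        self._records: dict[str, DrugRecord] = {}
        for rec in records:
            if rec.name in self._records:
                raise DrugTableError(f"duplicate drug name {rec.name!r}")
            self._records[rec.name] = rec

    def __getitem__(self, name: str) -> DrugRecord:
        key = name.strip().lower()
        try:
            return self._records[key]
        except KeyError:
            raise KeyError(f"drug {name!r} not in table") from None

    def __contains__(self, name: str) -> bool:
        return name.strip().lower() in self._records

    def __iter__(self) -> Iterator[DrugRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    @property
    def names(self) -> list[str]:
        return list(self._records)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f.name for f in fields(DrugRecord)]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self])

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _parse_row(row: pd.Series, idx: int) -> DrugRecord:
    def opt_float(col: str) -> float | None:
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col])

    try:
        return DrugRecord(
            name=str(row["name"]).strip().lower(),
            ki_d2=float(row["ki_d2"]),
            ki_5ht2a=opt_float("ki_5ht2a"),
            intrinsic_activity_d2=float(row["intrinsic_activity_d2"]),
            cpz_eq_factor=float(row["cpz_eq_factor"]),
            conc_per_dose=float(row["conc_per_dose"]),
            bnf_max_dose=float(row["bnf_max_dose"]),
            ref_dose_mg=opt_float("ref_dose_mg"),
            ref_occupancy=opt_float("ref_occupancy"),
            dose_step_mg=opt_float("dose_step_mg"),
            source=None if "source" not in row or pd.isna(row["source"]) else str(row["source"]),
        )
    except DrugTableError as exc:
        raise DrugTableError(f"row {idx}: {exc}") from None
    except (TypeError, ValueError) as exc:
        raise DrugTableError(f"row {idx}: {exc}") from None


def load_drug_table(path: str | Path) -> DrugTable:
    """Read a comma-separated drug table (UTF-8, header row) and validate it.

    Raises :class:`DrugTableError` naming the offending row and field for a
    missing column, an invariant violation or a duplicate name.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DrugTableError(f"drug table {path}: missing columns {missing}")
    return DrugTable(_parse_row(row, i) for i, (_, row) in enumerate(df.iterrows()))


def default_drug_table() -> DrugTable:
    """The bundled literature-sourced default table (user-replaceable)."""
    with resources.as_file(resources.files("apprisk.data") / "drug_table.csv") as p:
        return load_drug_table(p)


@dataclass(frozen=True)
class Regimen:
    """An ordered pair of (drug, daily dose mg) prescriptions.

    Doses must be non-negative and within the licensed (BNF) maximum; the
    two drugs must differ.  A zero dose represents absence of that drug.
    """

    drug_a: DrugRecord
    dose_a: float
    drug_b: DrugRecord
    dose_b: float

    def __post_init__(self) -> None:
        if self.drug_a.name == self.drug_b.name:
            raise ValueError("regimen requires two distinct drugs")
        for drug, dose, lbl in ((self.drug_a, self.dose_a, "a"), (self.drug_b, self.dose_b, "b")):
            if dose < 0:
                raise ValueError(f"dose_{lbl} must be >= 0, got {dose}")
            if dose > drug.bnf_max_dose:
                raise ValueError(
                    f"dose_{lbl} {dose} mg/day exceeds licensed maximum "
                    f"{drug.bnf_max_dose} mg/day for {drug.name}"
                )


@dataclass(frozen=True)
class OccupancySet:
    """Fractional occupancies at one receptor for a two-drug regimen.

    ``occ_endogenous`` is the fraction bound by endogenous dopamine (zero at
    5-HT₂AR); ``free_fraction`` is the unbound receptor fraction.  The four
    fractions partition the receptor pool and must sum to one.
    """

    target: str
    occ_a: float
    occ_b: float
    occ_endogenous: float
    free_fraction: float

    def __post_init__(self) -> None:
        for fname in ("occ_a", "occ_b", "occ_endogenous", "free_fraction"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{fname} = {v} outside [0, 1]")
        total = self.occ_a + self.occ_b + self.occ_endogenous + self.free_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancy fractions sum to {total}, not 1")

    @property
    def total_drug_occupancy(self) -> float:
        return self.occ_a + self.occ_b


def concentration_from_dose(drug: DrugRecord, dose: float) -> float:
    """Effective free brain concentration (nM) at a daily dose (mg/day).

    Linear in dose: ``conc_per_dose × dose``; the slope is calibrated per
    drug against a PET occupancy anchor at table-build time.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    return drug.conc_per_dose * dose


def _conc_over_ki(drug: DrugRecord, dose: float, target: str) -> float:
    ki = drug.ki(target)
    if ki is None:
        if dose > 0:
            warnings.warn(
                f"{drug.name} has no recorded 5-HT2A affinity; treating as non-binding",
                stacklevel=3,
            )
        return 0.0
    return concentration_from_dose(drug, dose) / ki


def competitive_occupancy(
    regimen: Regimen, target: str = "D2R", dopamine_tone: float = 0.0
) -> OccupancySet:
    """Equilibrium occupancies at ``target`` under two-drug competition.

    ``dopamine_tone`` is the endogenous dopamine concentration over its own
    affinity constant (dimensionless); it competes only at D₂R and is
    ignored at 5-HT₂AR, where dopamine does not bind appreciably.
    """
    if target not in TARGETS:
        raise ValueError(f"unknown receptor target {target!r}; expected one of {TARGETS}")
    if dopamine_tone < 0:
        raise ValueError("dopamine_tone must be >= 0")
    r_a = _conc_over_ki(regimen.drug_a, regimen.dose_a, target)
    r_b = _conc_over_ki(regimen.drug_b, regimen.dose_b, target)
    r_da = dopamine_tone if target == "D2R" else 0.0
    denom = 1.0 + r_a + r_b + r_da
    return OccupancySet(
        target=target,
        occ_a=r_a / denom,
        occ_b=r_b / denom,
        occ_endogenous=r_da / denom,
        free_fraction=1.0 / denom,
    )


def sum_d2_occupancy(regimen: Regimen, dopamine_tone: float = 0.0) -> float:
    """Summed D₂R occupancy of the two antipsychotics (the "D₂R" score)."""
    occ = competitive_occupancy(regimen, "D2R", dopamine_tone)
    return occ.total_drug_occupancy


def inv_k_sum(regimen: Regimen) -> float:
    """Summed inverse D₂ affinity, 1/K₁ + 1/K₂ (nM⁻¹); dose independent."""
    return 1.0 / regimen.drug_a.ki_d2 + 1.0 / regimen.drug_b.ki_d2


def cpz_equivalent_sum(regimen: Regimen) -> float:
    """Total chlorpromazine-equivalent daily dose (mg/day) of the regimen."""
    return (
        regimen.dose_a * regimen.drug_a.cpz_eq_factor
        + regimen.dose_b * regimen.drug_b.cpz_eq_factor
    )


def occupancy_at_reference(drug: DrugRecord) -> float | None:
    """Single-drug D₂ occupancy at the drug's PET anchor dose (tone 0).

    Returns None when the table carries no anchor.  Used to audit that
    ``conc_per_dose`` is consistent with the recorded anchor.
    """
    if drug.ref_dose_mg is None or drug.ref_occupancy is None:
        return None
    c = concentration_from_dose(drug, drug.ref_dose_mg)
    return c / (drug.ki_d2 + c)


def calibrate_conc_per_dose(ki_d2: float, ref_dose_mg: float, ref_occupancy: float) -> float:
    """Invert the single-ligand occupancy formula at a PET anchor.

    occ = C/(K+C) with C = slope·dose  ⇒  slope = K·occ/(1−occ)/dose.
    """
    if not 0 < ref_occupancy < 1:
        raise ValueError("reference occupancy must lie strictly in (0, 1)")
    if ref_dose_mg <= 0:
        raise ValueError("reference dose must be > 0")
    return ki_d2 * ref_occupancy / (1.0 - ref_occupancy) / ref_dose_mg


def _check_anchor_consistency(table: DrugTable, tol: float = 1e-6) -> None:
    for rec in table:
        occ = occupancy_at_reference(rec)
        if occ is not None and not math.isclose(occ, rec.ref_occupancy, abs_tol=tol):
            raise DrugTableError(
                f"{rec.name}: conc_per_dose inconsistent with PET anchor "
                f"(predicted occupancy {occ:.6f}, anchor {rec.ref_occupancy})"
            )
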