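"""Drug table handling, dose→concentration calibration, competitive
occupancy (against a mass-action kinetics oracle) and the simple risk scores."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from apprisk.pharmacology import (
    DrugTableError,
    Regimen,
    competitive_occupancy,
    concentration_from_dose,
    cpz_equivalent_sum,
    inv_k_sum,
    load_drug_table,
    occupancy_at_reference,
    sum_d2_occupancy,
)

from conftest import make_drug, make_regimen


# --- drug table -----------------------------------------------------------

REQUIRED_DRUGS = (
    "aripiprazole", "olanzapine", "risperidone", "amisulpride",
    "clozapine", "sulpiride", "chlorpromazine", "haloperidol",
)


def test_default_table_covers_study_drugs(table):
    assert len(table) >= 10
    for name in REQUIRED_DRUGS:
        assert name in table
    # case-insensitive lookup
    assert table["Olanzapine"].name == "olanzapine"


@pytest.mark.parametrize(
    "mutation, match",
    [
        ({"ki_d2": 0.0}, "ki_d2"),
        ({"intrinsic_activity_d2": 1.5}, "intrinsic_activity_d2"),
        ({"cpz_eq_factor": -1.0}, "cpz_eq_factor"),
    ],
)
def test_invalid_rows_rejected_with_row_and_field(tmp_path, table, mutation, match):
    df = table.to_dataframe()
    for col, val in mutation.items():
        df.loc[2, col] = val
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(DrugTableError, match=match) as exc:
        load_drug_table(path)
    assert "row 2" in str(exc.value)


def test_missing_column_rejected(tmp_path, table):
    df = table.to_dataframe().drop(columns=["ki_d2"])
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(DrugTableError, match="ki_d2"):
        load_drug_table(path)


def test_duplicate_name_rejected(tmp_path, table):
    df = table.to_dataframe()
    df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
    path = tmp_path / "dup.csv"
    df.to_csv(path, index=False)
    with pytest.raises(DrugTableError, match="duplicate"):
        load_drug_table(path)


def test_table_round_trip_identity(tmp_path, table):
    path = tmp_path / "copy.csv"
    table.write_csv(path)
    reread = load_drug_table(path)
    assert reread.names == table.names
    for rec in table:
        assert reread[rec.name] == rec


# --- dose → concentration -------------------------------------------------

def test_concentration_is_linear_in_dose():
    drug = make_drug("x", conc_per_dose=0.5)
    assert concentration_from_dose(drug, 0.0) == 0.0
    assert concentration_from_dose(drug, 10.0) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        concentration_from_dose(drug, -1.0)


def test_pet_anchor_reproduced_for_every_bundled_drug(table):
    """conc_per_dose must invert to the recorded PET occupancy anchor."""
    for rec in table:
        occ = occupancy_at_reference(rec)
        assert occ is not None, f"{rec.name} has no calibration anchor"
        assert occ == pytest.approx(rec.ref_occupancy, abs=1e-6)


# --- competitive occupancy ------------------------------------------------

def test_half_saturation_single_ligand():
    occ = competitive_occupancy(make_regimen(dose_a=1.0, ki_a=1.0), "D2R", 0.0)
    assert occ.occ_a == pytest.approx(0.5)
    assert occ.occ_b == 0.0
    assert occ.free_fraction == pytest.approx(0.5)


def test_symmetric_competition_thirds():
    occ = competitive_occupancy(make_regimen(dose_a=1.0, dose_b=2.0, ki_a=1.0, ki_b=2.0), "D2R", 0.0)
    assert occ.occ_a == pytest.approx(1 / 3)
    assert occ.occ_b == pytest.approx(1 / 3)
    assert occ.free_fraction == pytest.approx(1 / 3)


def test_unknown_target_rejected():
    with pytest.raises(ValueError, match="unknown receptor"):
        competitive_occupancy(make_regimen(dose_a=1.0), "D3R")


def test_missing_5ht2a_affinity_is_nonbinding_with_warning():
    reg = make_regimen(dose_a=5.0, dose_b=5.0, ki5_a=2.0, ki5_b=None)
    with pytest.warns(UserWarning, match="5-HT2A"):
        occ = competitive_occupancy(reg, "5HT2AR")
    assert occ.occ_b == 0.0
    assert occ.occ_a > 0.0
    assert occ.occ_endogenous == 0.0  # dopamine does not compete here


def _ode_equilibrium_occupancy(c_a, c_b, k_a, k_b, tone):
    """Mass-action binding kinetics integrated to equilibrium.

    dB_i/dt = kon·C_i·(1 − ΣB) − koff_i·B_i with kon = 1, koff_i = K_i and
    ligands in excess.  Independent of the analytic competition formula.
    """
    concs = np.array([c_a, c_b, tone])  # tone expressed as C_DA with K_DA = 1
    koffs = np.array([k_a, k_b, 1.0])

    def rhs(_, b):
        free = 1.0 - b.sum()
        return concs * free - koffs * b

    sol = solve_ivp(
        rhs, (0.0, 400.0), np.zeros(3), method="LSODA",
        rtol=1e-11, atol=1e-12, t_eval=[400.0],
    )
    return sol.y[:, -1]


def test_occupancy_matches_mass_action_ode_oracle(rng):
    """Analytic equilibrium occupancies agree with integrated kinetics to 1e-6."""
    for _ in range(50):
        c_a, c_b = rng.uniform(0.0, 20.0, 2)
        k_a, k_b = rng.uniform(0.1, 30.0, 2)
        tone = rng.uniform(0.0, 3.0)
        reg = make_regimen(dose_a=c_a, dose_b=c_b, ki_a=k_a, ki_b=k_b)
        occ = competitive_occupancy(reg, "D2R", tone)
        b_a, b_b, b_da = _ode_equilibrium_occupancy(c_a, c_b, k_a, k_b, tone)
        assert occ.occ_a == pytest.approx(b_a, abs=1e-6)
        assert occ.occ_b == pytest.approx(b_b, abs=1e-6)
        assert occ.occ_endogenous == pytest.approx(b_da, abs=1e-6)


@settings(max_examples=200, deadline=None)
@given(
    dose_a=st.floats(0.0, 1e3),
    dose_b=st.floats(0.0, 1e3),
    ki_a=st.floats(0.01, 1e3),
    ki_b=st.floats(0.01, 1e3),
    tone=st.floats(0.0, 10.0),
)
def test_occupancy_fractions_partition_the_receptor_pool(dose_a, dose_b, ki_a, ki_b, tone):
    occ = competitive_occupancy(
        make_regimen(dose_a=dose_a, dose_b=dose_b, ki_a=ki_a, ki_b=ki_b), "D2R", tone
    )
    total = occ.occ_a + occ.occ_b + occ.occ_endogenous + occ.free_fraction
    assert abs(total - 1.0) < 1e-9


@settings(max_examples=100, deadline=None)
@given(
    dose=st.floats(0.1, 100.0),
    bump=st.floats(0.1, 100.0),
    other=st.floats(0.1, 100.0),
    tone=st.floats(0.1, 5.0),
)
def test_own_occupancy_monotone_in_own_dose_and_competitors(dose, bump, other, tone):
    base = competitive_occupancy(make_regimen(dose_a=dose, dose_b=other), "D2R", tone)
    more_self = competitive_occupancy(make_regimen(dose_a=dose + bump, dose_b=other), "D2R", tone)
    more_other = competitive_occupancy(make_regimen(dose_a=dose, dose_b=other + bump), "D2R", tone)
    more_tone = competitive_occupancy(make_regimen(dose_a=dose, dose_b=other), "D2R", tone + bump)
    assert more_self.occ_a > base.occ_a
    assert more_other.occ_a < base.occ_a
    assert more_tone.occ_a < base.occ_a


# --- simple risk scores ---------------------------------------------------

def test_summed_occupancy_identities():
    reg = make_regimen(dose_a=1.0, dose_b=2.0, ki_a=1.0, ki_b=2.0)
    assert sum_d2_occupancy(reg, 0.0) == pytest.approx(2 / 3)
    assert sum_d2_occupancy(make_regimen(), 0.0) == 0.0
    occ = competitive_occupancy(reg, "D2R", 1.3)
    assert sum_d2_occupancy(reg, 1.3) == pytest.approx(
        1.0 - occ.free_fraction - occ.occ_endogenous, abs=1e-12
    )


def test_summed_occupancy_saturates_to_one():
    huge = make_regimen(dose_a=1e6, dose_b=1e6)
    assert sum_d2_occupancy(huge, 1.0) == pytest.approx(1.0, abs=1e-6)
    assert 0.0 <= sum_d2_occupancy(huge, 1.0) <= 1.0


def test_inverse_affinity_sum_is_dose_independent():
    assert inv_k_sum(make_regimen(ki_a=1.0, ki_b=1.0)) == pytest.approx(2.0)
    assert inv_k_sum(make_regimen(ki_a=2.0, ki_b=4.0)) == pytest.approx(0.75)
    lo = make_regimen(dose_a=1.0, dose_b=2.0, ki_a=2.0, ki_b=4.0)
    hi = make_regimen(dose_a=50.0, dose_b=80.0, ki_a=2.0, ki_b=4.0)
    assert inv_k_sum(lo) == inv_k_sum(hi)


def test_cpz_equivalent_sum_arithmetic(table):
    a = make_drug("a", cpz_eq_factor=1.0)
    b = make_drug("b", cpz_eq_factor=1.0)
    assert cpz_equivalent_sum(Regimen(a, 100.0, b, 200.0)) == pytest.approx(300.0)
    assert cpz_equivalent_sum(Regimen(a, 0.0, b, 0.0)) == 0.0
    # hand-multiplied from the bundled conversion factors
    reg = Regimen(table["olanzapine"], 10.0, table["risperidone"], 2.0)
    expected = 10.0 * table["olanzapine"].cpz_eq_factor + 2.0 * table["risperidone"].cpz_eq_factor
    assert cpz_equivalent_sum(reg) == pytest.approx(expected)
    assert expected == pytest.approx(500.0)  # 10×30 + 2×100


# --- regimen invariants ---------------------------------------------------

def test_regimen_rejects_dose_above_licensed_maximum(table):
    with pytest.raises(ValueError, match="exceeds licensed maximum"):
        Regimen(table["olanzapine"], 25.0, table["risperidone"], 2.0)


def test_regimen_rejects_identical_drugs(table):
    with pytest.raises(ValueError, match="distinct"):
        Regimen(table["olanzapine"], 5.0, table["olanzapine"], 5.0)


def test_regimen_rejects_negative_dose(table):
    with pytest.raises(ValueError, match="dose_b"):
        Regimen(table["olanzapine"], 5.0, table["risperidone"], -1.0)
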