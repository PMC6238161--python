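import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from apprisk.circuit import default_circuit_params
from apprisk.pharmacology import DrugRecord, DrugTable, Regimen, default_drug_table


@pytest.fixture(scope="session")
def table():
    return default_drug_table()


@pytest.fixture(scope="session")
def params():
    return default_circuit_params()


def make_drug(
    name,
    ki_d2=1.0,
    ki_5ht2a=None,
    intrinsic_activity_d2=0.0,
    cpz_eq_factor=1.0,
    conc_per_dose=1.0,
    bnf_max_dose=1e6,
    **kw,
):
    """Synthetic drug record with permissive dose ceiling for constructed tests."""
    return DrugRecord(
        name=name,
        ki_d2=ki_d2,
        ki_5ht2a=ki_5ht2a,
        intrinsic_activity_d2=intrinsic_activity_d2,
        cpz_eq_factor=cpz_eq_factor,
        conc_per_dose=conc_per_dose,
        bnf_max_dose=bnf_max_dose,
        **kw,
    )


def make_regimen(dose_a=0.0, dose_b=0.0, ki_a=1.0, ki_b=1.0, eps_a=0.0, eps_b=0.0,
                 ki5_a=None, ki5_b=None):
    """Two synthetic drugs with conc_per_dose 1, so dose is concentration in nM."""
    return Regimen(
        drug_a=make_drug("druga", ki_d2=ki_a, intrinsic_activity_d2=eps_a, ki_5ht2a=ki5_a),
        dose_a=dose_a,
        drug_b=make_drug("drugb", ki_d2=ki_b, intrinsic_activity_d2=eps_b, ki_5ht2a=ki5_b),
        dose_b=dose_b,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort_config_dict():
    """A 40-patient configuration for fast pipeline tests."""
    return {
        "n_patients": 40,
        "age_band_counts": {"16-25": 22, "26-35": 18},
        "gender_counts": {"Female": 19, "Male": 21},
        "ethnicity_counts": {"British": 40},
        "named_combinations": [
            ("haloperidol", "olanzapine", 12),
            ("risperidone", "quetiapine", 8),
        ],
        "other_pool_count": 20,
        "n_combination_types": 7,
        "prevalence_count": 5,
        "link_delta": 0.58,
        "seed": 3,
    }
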