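import pytest

from twinstest.cohort_model import build_analysis_table
from twinstest.synthetic_cohort import (
    Delivery,
    FamilyHistory,
    full_control_scenario,
    scenario_presets,
    simulate_cohort,
)

NF_SEED = 20260101
FC_SEED = 20260102


def make_family(fid, sizes, survive=None, unit="union", mother_death=None, father_death=None,
                start_month=0, spacing=24, start_age=24):
    """Hand-build a family from delivery sizes (1 or 2) and survival flags."""
    fam = FamilyHistory(
        family_id=fid,
        unit=unit,
        mother_age_at_death=mother_death,
        father_age_at_death=father_death,
    )
    for i, size in enumerate(sizes):
        month = start_month + i * spacing
        surv = survive[i] if survive is not None else tuple([True] * size)
        fam.deliveries.append(
            Delivery(
                delivery_index=i,
                mother_age=start_age + month // 12,
                months_since_marriage=month,
                n_children=size,
                sexes=("M",) if size == 1 else ("M", "F"),
                survives_to_14=surv,
            )
        )
    return fam


@pytest.fixture(scope="session")
def natural_cohort_50k():
    """Natural-fertility cohort at the study scale (England pre-1880 regime)."""
    return simulate_cohort(scenario_presets("england_pre1880", n_families=50_000, seed=NF_SEED))


@pytest.fixture(scope="session")
def natural_table_50k(natural_cohort_50k):
    return build_analysis_table(natural_cohort_50k)


@pytest.fixture(scope="session")
def control_cohort_50k():
    """Complete-control cohort: every couple targets surviving children and
    the marriage lasts to the end of planned births."""
    return simulate_cohort(full_control_scenario("england_pre1880", n_families=50_000, seed=FC_SEED))


@pytest.fixture(scope="session")
def control_table_50k(control_cohort_50k):
    return build_analysis_table(control_cohort_50k)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick observational-scale cohort for module-level tests."""
    return simulate_cohort(scenario_presets("quebec", n_families=2_000, seed=42))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return build_analysis_table(small_cohort)
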