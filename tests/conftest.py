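import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cadcost import (  # noqa: E402
    AnalysisOptions,
    BranchProbabilities,
    UnitCostSchedule,
    generate_cohort,
    registry_default_params,
)


@pytest.fixture
def demo_schedule() -> UnitCostSchedule:
    """Round-number illustrative tariff schedule (invasive CXA above CMR)."""
    return UnitCostSchedule(
        system_label="demo",
        currency="EUR",
        c_cmr=500,
        c_cxa=800,
        c_ffr_addon=150,
        c_pci=3000,
        c_cabg=12000,
        c_nonfatal_mi=4000,
        c_stroke=5000,
        c_aborted_scd=7000,
        c_dual_antiplatelet_year=350,
        c_rehab_post_mi=3000,
        c_cardiologist_visit=40,
    )


@pytest.fixture
def toy_probs() -> BranchProbabilities:
    """Hand-checkable tree: 20% prevalence, 50% revasc among positives."""
    return BranchProbabilities(
        p_ischemia_pos=0.2,
        p_revasc_given_pos=0.5,
        p_revasc_given_neg=0.0,
        revasc_type_mix=(1.0, 0.0, 0.0),
        p_ffr_eligible=0.35,
        p_ffr_positive=0.062,
    )


@pytest.fixture
def bare_options() -> AnalysisOptions:
    """Options stripping all optional cost items."""
    return AnalysisOptions(include_rehab=False, include_cardiologist_visit=False)


@pytest.fixture(scope="session")
def registry_records():
    """One registry-sized synthetic cohort, shared across tests."""
    return generate_cohort(registry_default_params(3647, seed=11))
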