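import pytest

from lepmel import simulate
from lepmel.growth import GrowthReference
from lepmel.simulate import LMSCurveSpec, SimulationConfig
from lepmel.variants import (
    build_carrier_matrix,
    classify_variants,
    filter_rare_deleterious,
)


@pytest.fixture(scope="session")
def reference():
    """Default synthetic LMS reference over 24-228 months, both sexes."""
    return simulate.generate_lms_reference(seed=7)


@pytest.fixture(scope="session")
def flat_reference():
    """Constant-curve reference (L=1, M_bmi=20, S=0.1, M_height=1.5 m) for
    closed-form checks."""
    params = {}
    for sex in ("F", "M"):
        params[(sex, "bmi")] = LMSCurveSpec(L=(1.0, 0.0), M=(20.0, 0.0), S=(0.1, 0.0))
        params[(sex, "height")] = LMSCurveSpec(L=(1.0, 0.0), M=(1.5, 0.0), S=(0.1, 0.0))
        params[(sex, "weight")] = LMSCurveSpec(L=(1.0, 0.0), M=(45.0, 0.0), S=(0.1, 0.0))
    return simulate.generate_lms_reference(curve_params=params, seed=0)


@pytest.fixture(scope="session")
def default_cohort(reference):
    """(cohort, variants) at the default study conditions (Bernoulli carriers)."""
    return simulate.generate_cohort(SimulationConfig(seed=11), reference)


@pytest.fixture(scope="session")
def exact_cohort(reference):
    """(cohort, variants) with exact disjoint carrier counts."""
    return simulate.generate_cohort(
        SimulationConfig(seed=11, carrier_mode="exact"), reference
    )


@pytest.fixture(scope="session")
def exact_matrix(exact_cohort):
    cohort, variants = exact_cohort
    classified = classify_variants(filter_rare_deleterious(variants))
    return build_carrier_matrix(classified, cohort)
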