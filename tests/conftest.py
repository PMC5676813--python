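import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def unit_icosphere():
    from cortmorph.synthetic import icosphere

    return icosphere(level=4, radius=1.0)


@pytest.fixture(scope="session")
def icosphere_r10():
    from cortmorph.synthetic import icosphere

    return icosphere(level=4, radius=10.0)


@pytest.fixture(scope="session")
def eggcrate():
    from cortmorph.synthetic import ParametricSurfaceSpec, make_surface

    spec = ParametricSurfaceSpec(kind="eggcrate_sheet", amplitude=2.0, wavelength=10.0,
                                 extent=20.0, spacing=0.25)
    return spec, make_surface(spec)


@pytest.fixture(scope="session")
def cohort_table():
    """One default simulated cohort, shared across statistics tests."""
    from cortmorph.synthetic import CohortSpec, simulate_cohort

    table, truth = simulate_cohort(CohortSpec(seed=0))
    return table, truth


@pytest.fixture(scope="session")
def synthetic_subject_lvl4():
    from cortmorph.synthetic import make_synthetic_subject

    return make_synthetic_subject(level=4, amplitude=2.0, thickness=2.5)
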