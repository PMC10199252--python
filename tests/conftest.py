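import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from modulearn import NoiseSpec, default_design, default_panel, generate
from modulearn.design import Cohort, CohortDesign
from modulearn.panel import PanelVariable

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def design():
    return default_design()


def _small_panel():
    """12 facets over 4 instruments; one wellbeing-coded block."""
    rows = []
    for q, n_vars, direction in (
        ("QA", 4, 1),
        ("QB", 3, 1),
        ("QC", 3, 1),
        ("QW", 2, -1),
    ):
        for i in range(n_vars):
            rows.append(
                PanelVariable(
                    variable_id=f"{q.lower()}_{i}",
                    questionnaire=q,
                    subscale_name=f"{q} facet {i}",
                    is_total_score=(i == 0),
                    improvement_direction=direction,
                )
            )
    return rows


@pytest.fixture(scope="session")
def small_panel():
    return _small_panel()


@pytest.fixture(scope="session")
def small_design():
    return CohortDesign(
        (
            Cohort("RCC", 20, ()),
            Cohort("TC1", 18, ("Presence", "Affect", "Perspective")),
            Cohort("TC2", 18, ("Presence", "Perspective", "Affect")),
            Cohort("TC3", 18, ("Affect",)),
        )
    )


@pytest.fixture(scope="session")
def iid_noise():
    """Independent facets: the planted set is the whole discriminative set."""
    return NoiseSpec(
        within_questionnaire_correlation=0.0, between_questionnaire_correlation=0.0
    )


@pytest.fixture(scope="session")
def small_null_dataset(small_design, small_panel):
    return generate(small_design, small_panel, None, NoiseSpec(), seed=0)


@pytest.fixture(scope="session")
def full_null_dataset(design, panel):
    return generate(design, panel, None, NoiseSpec(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
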