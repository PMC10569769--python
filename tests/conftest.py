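import numpy as np
import pytest

import navfair as nf
from navfair.cohort import CohortConfig, EncounterModel, SpecialtySpec
from navfair.preprocessing import build_model_table


@pytest.fixture(scope="session")
def small_cohort():
    """A compact two-specialty cohort used across tests (40 weeks)."""
    cfg = CohortConfig(
        n_weeks=40,
        specialties=(
            SpecialtySpec("gi", 3, 20.1),
            SpecialtySpec("gu", 2, 13.4),
        ),
        seed=7,
    )
    return nf.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return build_model_table(small_cohort)
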