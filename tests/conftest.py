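import numpy as np
import pandas as pd
import pytest

from flavopipe.synth import CohortSpec, generate_cohort
from flavopipe.types import AnalysisConfig, OtuTable, SampleRecord


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced paired cohort (8 v 8 subjects, 60 taxa) for fast tests."""
    spec = CohortSpec(
        n_subjects_cranberry=8,
        n_subjects_placebo=8,
        n_taxa=60,
        depth_range=(3000, 10_000),
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort at the study's design point (18 v 16 subjects, 219 taxa)."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        [[5, 3, 0, 2], [0, 8, 1, 1], [4, 0, 6, 0]],
        index=["s1", "s2", "s3"],
        columns=["o1", "o2", "o3", "o4"],
    )
    return OtuTable(counts)


@pytest.fixture
def default_config():
    return AnalysisConfig()
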