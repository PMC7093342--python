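import numpy as np
import pandas as pd
import pytest

from glimpse import (
    ExperimentDesign,
    Trial,
    build_design,
    select_stimuli,
    simulate_cohort,
    synthetic_rating_table,
)


@pytest.fixture(scope="session")
def rating_table() -> pd.DataFrame:
    return synthetic_rating_table(900, seed=1)


@pytest.fixture(scope="session")
def catalog(rating_table):
    return select_stimuli(rating_table)


@pytest.fixture(scope="session")
def design0(catalog):
    return build_design(catalog, participant_index=0, seed=1)


@pytest.fixture(scope="session")
def faithful_cohort(catalog) -> pd.DataFrame:
    """Six faithful observers under the study's late-noise conditions."""
    return simulate_cohort(
        6, catalog, model_name="faithful", late_noise_sd=1.4, seed=5, discretize=False
    )


def manual_design(trials: list[Trial], participant: int = 0) -> ExperimentDesign:
    """A bare design wrapper for hand-built trial lists."""
    return ExperimentDesign(
        participant_index=participant,
        side_mapping="A_left",
        seed=0,
        trials=trials,
        catalog=None,
    )
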