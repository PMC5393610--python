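import numpy as np
import pandas as pd
import pytest

from thrombomet import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Small, fully paired cohort: every subject has Q, T0, T6."""
    return SimConfig(
        n_per_group=(6, 6, 6),
        n_paired=(6, 6, 6),
        n_metabolites=40,
        n_specific=4,
        n_procedural=3,
        effect_log2fc_range=(2.0, 3.0),
        censor_quantile=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def study_sized_cohort():
    """Study-shaped cohort: 11/12/15 subjects, 9/9/14 paired, planted effects."""
    return generate_cohort(
        SimConfig(
            n_metabolites=120,
            n_specific=8,
            n_procedural=5,
            effect_log2fc_range=(2.0, 2.0),
            seed=5,
        )
    )


@pytest.fixture()
def toy_abundance():
    return pd.DataFrame(
        [[4.0, 1.0, 8.0], [np.nan, 2.0, 4.0], [2.0, 4.0, 2.0]],
        index=["s1", "s2", "s3"],
        columns=["m1", "m2", "m3"],
    )
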