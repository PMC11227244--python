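import dataclasses

import numpy as np
import pytest

from phagefmt.simulate import SimConfig, simulate_cohort

#: small cohort used across tests: 2 donors/sex, 2 FMT + 2 placebo/sex
SMALL_SIM = SimConfig(
    seed=11,
    n_donors_per_sex=2,
    donor_richness_range=(6, 10),
    recipient_richness=6,
    n_fmt=2,
    n_placebo=2,
    genome_length_range=(3000, 5000),
    n_distractors=2,
    novel_rate_fmt=2.0,
    novel_rate_placebo=2.0,
    background_per_subject=3,
    n_junk_contigs=6,
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_SIM)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def small_config():
    return dataclasses.replace(SMALL_SIM)
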