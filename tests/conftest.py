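import numpy as np
import pytest

from hipgwas.io_formats import case_control_status
from hipgwas.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A mid-sized stratified cohort with one protective and one risk locus."""
    cfg = SimConfig(
        n_dogs=400,
        n_snps=300,
        n_chromosomes=2,
        causal_loci=[(50, 0.4, 0.3), (250, 2.3, 0.2)],
        seed=11,
    )
    gm, cohort, truth = simulate_cohort(cfg)
    return cfg, gm, cohort, truth


@pytest.fixture(scope="session")
def small_case_status(small_cohort):
    _cfg, gm, cohort, _truth = small_cohort
    coh = cohort.set_index("dog_id").loc[gm.samples]
    y = np.array(
        [case_control_status(l, r) for l, r in zip(coh["hip_left"], coh["hip_right"])]
    )
    return y
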