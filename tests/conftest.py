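import numpy as np
import pytest

import mpraloc as m
from mpraloc.design import AlterationSpec


@pytest.fixture(scope="session")
def design_config():
    return m.DesignConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_study():
    """Small wildtype-only simulated study reused by read-level and
    profile-level tests."""
    cfg = m.SimConfig(n_genes=4, utr_length_range=(700, 1000), depth=5_000.0, seed=5)
    return m.simulate_study(cfg, with_decay=True)


@pytest.fixture(scope="session")
def insertion_study():
    """Study with motif insertion/mutation arms for paired-effect tests."""
    plan = [
        AlterationSpec(kind="wildtype", n_barcodes=3),
        AlterationSpec(
            kind="motif_insertion", motif="TCTTCT", positions=(50,), copies=1
        ),
        AlterationSpec(
            kind="motif_insertion", motif="AGGTAA", positions=(50, 100), copies=2
        ),
    ]
    cfg = m.SimConfig(n_genes=6, seed=11)
    sim = m.simulate_study(cfg, alteration_plan=plan)
    design_df = m.design.design_to_frame(sim.variants, sim.design_config)
    enrichment = m.glm_lrt(sim.localization)
    return sim, design_df, enrichment
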