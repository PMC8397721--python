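import numpy as np
import pytest

import metaclone as mc


@pytest.fixture(scope="session")
def small_cohort():
    """Three-patient default-template cohort shared across tests (fixed seed)."""
    cfg = mc.SimulationConfig(n_patients=3, seed=42)
    return cfg, mc.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_call(t_alt, t_depth, purity=1.0, cn_major=1, cn_minor=1, pos=1000):
    return mc.MutationCall(
        patient="P1",
        sample="P1_P",
        lesion="primary",
        gene="KRAS",
        chrom="12",
        pos=pos,
        ref="C",
        alt="T",
        t_alt=t_alt,
        t_depth=t_depth,
        n_alt=0,
        n_depth=150,
        cn_major=cn_major,
        cn_minor=cn_minor,
        purity=purity,
    )
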